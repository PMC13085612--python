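import pytest

from cuvigil.case_store import CaseReport, CaseSet, DrugEntry


def report(case_id, *, version=1, year=2019, ingredient="PENICILLAMINE",
           role="primary suspect", indications=("HEPATO-LENTICULAR DEGENERATION",),
           reactions=("NAUSEA",), sex="female", age=40.0, serious=True,
           outcomes=("hospitalization",), country="US", extra_drugs=()):
    drugs = [DrugEntry(ingredient, role, frozenset(indications))]
    drugs.extend(extra_drugs)
    return CaseReport(case_id=case_id, version=version, receipt_year=year,
                      age_years=age, sex=sex, country=country,
                      reporter_type="healthcare professional", serious=serious,
                      outcomes=frozenset(outcomes), drugs=drugs,
                      reactions=frozenset(reactions))


@pytest.fixture
def funnel_fixture():
    """Six reports: 2 qualify (target indication + primary suspect), 4 drop
    at distinct funnel stages (missing indication; two excluded indications;
    concomitant-only role)."""
    reports = [
        report("K1"),
        report("K2", ingredient="TRIENTINE HYDROCHLORIDE", reactions=("TREMOR",)),
        report("D_CONCOMITANT", role="concomitant"),
        report("D_RHEUMATOID", indications=("RHEUMATOID ARTHRITIS",)),
        report("D_NO_INDICATION", indications=()),
        report("D_CYSTINURIA", indications=("CYSTINURIA",)),
    ]
    return CaseSet(reports, provenance="funnel-fixture")


@pytest.fixture
def faers_dir(tmp_path):
    """Tiny FAERS-style '$'-delimited quarterly tables: 3 cases, one orphan
    DRUG row, one malformed REAC line."""
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occr_country$occp_cod\n"
        "101$C1$1$20190315$42$YR$F$US$MD\n"
        "102$C2$1$20200101$24$MON$M$DE$CN\n"
        "103$C3$2$20211201$3$DEC$UNK$BR$LW\n")
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$drug_seq$role_cod$prod_ai\n"
        "101$1$PS$PENICILLAMINE\n"
        "101$2$C$PARACETAMOL\n"
        "102$1$PS$TRIENTINE HYDROCHLORIDE\n"
        "103$1$SS$ZINC ACETATE\n"
        "999$1$PS$GHOST DRUG\n")
    (tmp_path / "REAC.txt").write_text(
        "primaryid$pt\n"
        "101$ nausea \n"
        "101$TREMOR\n"
        "102$Rash\n"
        "102$bad$line$too$many$fields\n"
        "103$DYSTONIA\n")
    (tmp_path / "INDI.txt").write_text(
        "primaryid$indi_drug_seq$indi_pt\n"
        "101$1$Hepato-lenticular degeneration\n"
        "101$2$PAIN\n"
        "102$1$HEPATO-LENTICULAR DEGENERATION\n")
    (tmp_path / "OUTC.txt").write_text(
        "primaryid$outc_cod\n"
        "101$HO\n"
        "101$OT\n"
        "102$DE\n")
    return tmp_path


@pytest.fixture
def small_cohort():
    """4 exposed reports (2 with NAUSEA) for contingency examples."""
    return CaseSet([
        report("A1", reactions=("NAUSEA", "TREMOR")),
        report("A2", reactions=("NAUSEA",)),
        report("A3", reactions=("RASH",)),
        report("A4", reactions=("TREMOR",)),
    ], provenance="cohort")


@pytest.fixture
def small_background():
    """6 comparator reports (1 with NAUSEA)."""
    return CaseSet([
        report(f"B{i}", ingredient="OTHER DRUG",
               reactions=("NAUSEA",) if i == 0 else ("HEADACHE",))
        for i in range(6)
    ], provenance="background")
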