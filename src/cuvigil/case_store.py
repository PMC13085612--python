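"""Individual case safety reports: data model, FAERS-style readers, deduplication.

The canonical in-memory unit is the :class:`CaseReport` — one deduplicated
individual case safety report (ICSR) carrying demographics, reporter and
seriousness information, outcome codes, drug entries with role codes and
indications, and the set of reaction preferred terms.  The canonical on-disk
store is JSON-lines (one report object per line); the FAERS quarterly
"$"-delimited ASCII tables are supported as a reader dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger(__name__)

SEXES = ("female", "male", "unspecified")
ROLES = ("primary suspect", "secondary suspect", "concomitant", "interacting")
REPORTER_TYPES = ("healthcare professional", "consumer", "other/unknown")
CONTINENTS = ("Africa", "Americas", "Asia", "Europe", "Oceania", "Unknown")
OUTCOMES = (
    "death",
    "life-threatening",
    "hospitalization",
    "disability",
    "congenital anomaly",
    "required intervention",
    "other",
    "non-serious",
)

#: FAERS role_cod → canonical role
_ROLE_CODES = {"PS": "primary suspect", "SS": "secondary suspect",
               "C": "concomitant", "I": "interacting"}
#: FAERS outc_cod → canonical outcome
_OUTC_CODES = {"DE": "death", "LT": "life-threatening", "HO": "hospitalization",
               "DS": "disability", "CA": "congenital anomaly",
               "RI": "required intervention", "OT": "other"}
#: FAERS occp_cod → reporter type
_OCCP_CODES = {"MD": "healthcare professional", "PH": "healthcare professional",
               "OT": "healthcare professional", "RN": "healthcare professional",
               "HP": "healthcare professional", "CN": "consumer"}

#: age-unit → divisor (Julian-year conventions: 365.25-day year, 52.1775-week year)
_AGE_UNIT_FACTORS = {"DEC": 0.1, "YR": 1.0, "MON": 12.0, "WK": 52.1775,
                     "DY": 365.25, "HR": 8766.0}

MAX_PLAUSIBLE_AGE = 130.0

_SERIOUS_OUTCOMES = frozenset(OUTCOMES) - {"other", "non-serious"}


@dataclass(frozen=True)
class DrugEntry:
    """One drug line of a report: normalized ingredient, role code, indications."""

    ingredient: str
    role: str
    indications: frozenset = frozenset()

    def __post_init__(self):
        if not self.ingredient:
            raise ValueError("ingredient must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "indications", frozenset(self.indications))


@dataclass
class CaseReport:
    """One individual case safety report (possibly one of several versions)."""

    case_id: str
    version: int = 0
    receipt_year: Optional[int] = None
    age_years: Optional[float] = None
    sex: str = "unspecified"
    country: Optional[str] = None
    continent: str = "Unknown"
    reporter_type: str = "other/unknown"
    serious: Optional[bool] = None
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reactions: frozenset = frozenset()

    def __post_init__(self):
        if self.version < 0:
            raise ValueError("version must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_years is not None and not (0 <= self.age_years <= MAX_PLAUSIBLE_AGE):
            raise ValueError("age_years out of [0, 130]")
        self.outcomes = frozenset(self.outcomes)
        self.reactions = frozenset(_norm_term(r) for r in self.reactions)
        # derived seriousness: any regulatory-serious outcome present, unless
        # an explicit flag was supplied (which then wins)
        if self.serious is None and self.outcomes:
            self.serious = bool(self.outcomes & _SERIOUS_OUTCOMES)


@dataclass
class CaseSet:
    """An ordered collection of case reports with a provenance label."""

    reports: list
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __len__(self):
        return len(self.reports)


def _norm_term(s: str) -> str:
    """Uppercase + trim a preferred-term string."""
    return str(s).strip().upper()


# ---------------------------------------------------------------------------
# demographic harmonization

def harmonize_demographics(raw_age, age_unit, raw_sex):
    """Convert a raw (age, unit) pair to years and map a sex code.

    Unknown units or implausible results (> 130 years) yield a missing age
    with a logged warning; the function is total — it never raises.

    Returns
    -------
    (age_years, sex) : (float or None, str)
    """
    sex_code = _norm_term(raw_sex) if raw_sex is not None else ""
    sex = {"F": "female", "FEMALE": "female", "M": "male", "MALE": "male"}.get(
        sex_code, "unspecified")

    age_years = None
    if raw_age is not None and str(raw_age).strip() != "":
        try:
            value = float(raw_age)
        except (TypeError, ValueError):
            log.warning("unparseable age %r; set to missing", raw_age)
            return None, sex
        unit = _norm_term(age_unit) if age_unit else "YR"
        factor = _AGE_UNIT_FACTORS.get(unit)
        if factor is None:
            log.warning("unknown age unit %r; age set to missing", age_unit)
            return None, sex
        age_years = value * 10.0 if unit == "DEC" else value / factor
        if not (0 <= age_years <= MAX_PLAUSIBLE_AGE):
            log.warning("implausible age %.1f years; set to missing", age_years)
            age_years = None
    return age_years, sex


# ---------------------------------------------------------------------------
# ISO-3166 alpha-2 → continent (UN M49 regions; North and South America
# collapsed into a single Americas group)

_CONTINENT_OF = {}
for _codes, _cont in [
    ("DZ AO BJ BW BF BI CM CV CF TD KM CG CD CI DJ EG GQ ER SZ ET GA GM GH GN GW KE "
     "LS LR LY MG MW ML MR MU YT MA MZ NA NE NG RE RW SH ST SN SC SL SO ZA SS SD TZ "
     "TG TN UG EH ZM ZW", "Africa"),
    ("AI AG AR AW BS BB BZ BM BO BQ BR VG CA KY CL CO CR CU CW DM DO EC SV FK GF GD "
     "GP GT GY HT HN JM MQ MX MS NI PA PY PE PR BL KN LC MF PM VC SR TT TC US UY VE "
     "VI GL", "Americas"),
    ("AF AM AZ BH BD BT BN KH CN CY GE HK IN ID IR IQ IL JP JO KZ KW KG LA LB MO MY "
     "MV MN MM NP KP OM PK PS PH QA SA SG KR LK SY TW TJ TH TL TR TM AE UZ VN YE", "Asia"),
    ("AX AL AD AT BY BE BA BG HR CZ DK EE FO FI FR DE GI GR GG HU IS IE IM IT JE XK "
     "LV LI LT LU MT MD MC ME NL MK NO PL PT RO RU SM RS SK SI ES SJ SE CH UA GB VA", "Europe"),
    ("AS AU CK FJ PF GU KI MH FM NR NC NZ NU NF MP PW PG PN WS SB TK TO TV UM VU WF", "Oceania"),
]:
    for _c in _codes.split():
        _CONTINENT_OF[_c] = _cont


def map_continent(country) -> str:
    """Deterministic ISO alpha-2 → continent; unknown or missing → ``Unknown``."""
    if not country:
        return "Unknown"
    return _CONTINENT_OF.get(_norm_term(country), "Unknown")


# ---------------------------------------------------------------------------
# FAERS "$"-delimited quarterly tables

_REQUIRED = {
    "demo": ["primaryid"],
    "drug": ["primaryid", "role_cod"],
    "reac": ["primaryid", "pt"],
    "indi": ["primaryid", "indi_pt"],
    "outc": ["primaryid", "outc_cod"],
}


def _read_dollar_table(path, table, skip_counter):
    """Parse one "$"-delimited FAERS table into a list of row dicts.

    First line is the header.  Lines with the wrong field count are skipped
    and logged with their line number; duplicate column headers are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing FAERS table: {path}")
    rows = []
    with path.open(encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            return [], []
        columns = [c.strip().lower() for c in header_line.split("$")]
        if len(set(columns)) != len(columns):
            raise ValueError(f"{path}: duplicate column headers {columns}")
        for name in _REQUIRED[table]:
            if name not in columns:
                raise ValueError(f"{path}: required column {name!r} not found")
        width = len(columns)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != width:
                skip_counter["malformed"] += 1
                log.warning("%s:%d malformed line (%d fields, expected %d); skipped",
                            path, lineno, len(fields), width)
                continue
            rows.append(dict(zip(columns, fields)))
    return columns, rows


def read_faers_tables(demo_path, drug_path, reac_path, indi_path, outc_path) -> CaseSet:
    """Assemble case reports from the five FAERS quarterly ASCII tables.

    One :class:`CaseReport` is produced per DEMO row; DRUG/REAC/INDI/OUTC rows
    are joined on the ``primaryid`` case key.  Rows keyed to a case absent from
    DEMO are counted (``meta['orphan_rows']``) and skipped.  Reaction and
    indication strings are uppercased and trimmed.
    """
    skip = {"malformed": 0, "orphan_rows": 0, "joined_reactions": 0}
    _, demo_rows = _read_dollar_table(demo_path, "demo", skip)
    _, drug_rows = _read_dollar_table(drug_path, "drug", skip)
    _, reac_rows = _read_dollar_table(reac_path, "reac", skip)
    _, indi_rows = _read_dollar_table(indi_path, "indi", skip)
    _, outc_rows = _read_dollar_table(outc_path, "outc", skip)

    known = {r["primaryid"] for r in demo_rows}

    def _keyed(rows):
        out = {}
        for r in rows:
            pid = r["primaryid"]
            if pid not in known:
                skip["orphan_rows"] += 1
                continue
            out.setdefault(pid, []).append(r)
        return out

    drugs_by, reacs_by, indis_by, outcs_by = map(
        _keyed, (drug_rows, reac_rows, indi_rows, outc_rows))

    # INDI links to a drug sequence within the case when drug_seq is present;
    # otherwise indications attach to every drug entry of the case.
    reports = []
    for row in demo_rows:
        pid = row["primaryid"]
        age_years, sex = harmonize_demographics(
            row.get("age"), row.get("age_cod"), row.get("sex"))
        country = _norm_term(row.get("occr_country", "")) or None
        year = None
        for datefield in ("fda_dt", "event_dt"):
            raw = (row.get(datefield) or "").strip()
            if len(raw) >= 4 and raw[:4].isdigit():
                year = int(raw[:4])
                break
        indi_rows_case = indis_by.get(pid, [])
        drugs = []
        for d in drugs_by.get(pid, []):
            ingredient = _norm_term(d.get("prod_ai") or d.get("drugname") or "")
            if not ingredient:
                continue
            seq = d.get("drug_seq")
            inds = set()
            for ir in indi_rows_case:
                if seq is None or "indi_drug_seq" not in ir or ir["indi_drug_seq"] == seq:
                    term = _norm_term(ir["indi_pt"])
                    if term:
                        inds.add(term)
            drugs.append(DrugEntry(
                ingredient=ingredient,
                role=_ROLE_CODES.get(_norm_term(d.get("role_cod", "")), "concomitant"),
                indications=frozenset(inds)))
        reactions = {_norm_term(r["pt"]) for r in reacs_by.get(pid, []) if r["pt"].strip()}
        skip["joined_reactions"] += len(reactions)
        outcomes = {_OUTC_CODES[c] for c in
                    (_norm_term(r["outc_cod"]) for r in outcs_by.get(pid, []))
                    if c in _OUTC_CODES}
        try:
            version = int(row.get("caseversion", 0) or 0)
        except ValueError:
            version = 0
        reporter = _OCCP_CODES.get(_norm_term(row.get("occp_cod", "")), "other/unknown")
        reports.append(CaseReport(
            case_id=row.get("caseid") or pid, version=version,
            receipt_year=year, age_years=age_years, sex=sex,
            country=country, continent=map_continent(country),
            reporter_type=reporter, serious=None,
            outcomes=frozenset(outcomes), drugs=drugs,
            reactions=frozenset(reactions)))
    return CaseSet(reports, provenance=f"faers:{Path(demo_path).name}", meta=skip)


# ---------------------------------------------------------------------------
# deduplication

def dedupe_cases(cases: CaseSet) -> CaseSet:
    """Keep one report per ``case_id``: highest version, ties broken by latest
    receipt year, then by last occurrence in input order."""
    best = {}
    for idx, rep in enumerate(cases.reports):
        year = rep.receipt_year if rep.receipt_year is not None else -1
        key = (rep.version, year, idx)
        cur = best.get(rep.case_id)
        if cur is None or key >= cur[0]:
            best[rep.case_id] = (key, rep)
    kept = [rep for _, rep in sorted(best.values(), key=lambda kv: kv[0][2])]
    removed = cases.n - len(kept)
    return CaseSet(kept, provenance=f"{cases.provenance}|dedupe(-{removed})",
                   meta={**cases.meta, "dedupe_removed": removed})


# ---------------------------------------------------------------------------
# JSON-lines canonical store

def write_jsonl(cases: CaseSet, path) -> None:
    """Write one CaseReport JSON object per line (UTF-8)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rep in cases.reports:
            obj = {
                "case_id": rep.case_id, "version": rep.version,
                "receipt_year": rep.receipt_year, "age_years": rep.age_years,
                "sex": rep.sex, "country": rep.country,
                "continent": rep.continent, "reporter_type": rep.reporter_type,
                "serious": rep.serious,
                "outcomes": sorted(rep.outcomes),
                "drugs": [{"ingredient": d.ingredient, "role": d.role,
                           "indications": sorted(d.indications)} for d in rep.drugs],
                "reactions": sorted(rep.reactions),
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_jsonl(path, provenance=None) -> CaseSet:
    """Read the JSON-lines canonical store back into a CaseSet."""
    reports = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            reports.append(CaseReport(
                case_id=obj["case_id"], version=obj["version"],
                receipt_year=obj["receipt_year"], age_years=obj["age_years"],
                sex=obj["sex"], country=obj["country"],
                continent=obj["continent"], reporter_type=obj["reporter_type"],
                serious=obj["serious"],
                outcomes=frozenset(obj["outcomes"]),
                drugs=[DrugEntry(d["ingredient"], d["role"],
                                 frozenset(d["indications"])) for d in obj["drugs"]],
                reactions=frozenset(obj["reactions"])))
    return CaseSet(reports, provenance=provenance or f"jsonl:{Path(path).name}")
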