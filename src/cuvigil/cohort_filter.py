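"""Indication-restricted, primary-suspect cohort construction with audit trail.

Spontaneous-report extracts for a drug contain substantial clinical noise:
reports where the drug was a co-medication, reports for other approved
indications (rheumatoid arthritis, cystinuria, lead poisoning for
D-penicillamine), and reports with no indication recorded at all.  The
filtration funnel applies a fixed sequence of restrictions and records, per
canonical drug and per stage, how many reports entered, were kept, and were
dropped — so that cohort construction is fully auditable.

Stages (fixed order):

1. ``mapped-ingredient``   keep reports with ≥1 drug entry mapping to a
   canonical chelator label;
2. ``has-indication``      drop reports where every mapped entry lacks any
   recorded indication;
3. ``not-excluded``        drop reports whose mapped entries carry only
   explicitly excluded indications;
4. ``target+primary``      keep reports where a mapped entry carries the
   target indication and (by default) the primary-suspect role.

Indications are evaluated per drug entry, not per report, so indications of
co-medications never qualify a report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .case_store import CaseReport, CaseSet

STAGE_NAMES = ("mapped-ingredient", "has-indication", "not-excluded", "target+primary")

TARGET_INDICATION = "HEPATO-LENTICULAR DEGENERATION"

#: default raw-ingredient → canonical chelator synonym map (keys are
#: normalized by :func:`_norm_key` before lookup)
DEFAULT_SYNONYMS = {
    "d-penicillamine": "D-PENICILLAMINE",
    "penicillamine": "D-PENICILLAMINE",
    "penicillamine hydrochloride": "D-PENICILLAMINE",
    "penicillamine hcl": "D-PENICILLAMINE",
    "trientine": "TRIENTINE",
    "trientine hydrochloride": "TRIENTINE",
    "trientine hcl": "TRIENTINE",
    "trientine tetrahydrochloride": "TRIENTINE",
    "triethylenetetramine": "TRIENTINE",
}

DEFAULT_EXCLUDED = frozenset({
    "RHEUMATOID ARTHRITIS", "CYSTINURIA", "LEAD POISONING",
})

_PUNCT = re.compile(r"[^a-z0-9]+")


def _norm_key(raw: str) -> str:
    """Case- and punctuation-insensitive normal form for ingredient matching."""
    return _PUNCT.sub(" ", str(raw).lower()).strip()


@dataclass
class FilterConfig:
    """Configuration of the filtration funnel."""

    ingredient_synonyms: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYMS))
    target_indication: str = TARGET_INDICATION
    excluded_indications: Set[str] = field(default_factory=lambda: set(DEFAULT_EXCLUDED))
    require_primary_suspect: bool = True
    #: a report naming both chelators as qualifying primary suspects enters
    #: both cohorts by default; set False to drop such reports entirely
    allow_double_assignment: bool = True

    def __post_init__(self):
        self.ingredient_synonyms = {_norm_key(k): v
                                    for k, v in self.ingredient_synonyms.items()}
        self.target_indication = self.target_indication.strip().upper()
        self.excluded_indications = {s.strip().upper()
                                     for s in self.excluded_indications}
        if self.target_indication in self.excluded_indications:
            raise ValueError("target indication cannot also be excluded")

    @property
    def canonical_drugs(self) -> Tuple[str, ...]:
        return tuple(sorted(set(self.ingredient_synonyms.values())))


def normalize_ingredient(raw: str, config: FilterConfig) -> Optional[str]:
    """Map a raw ingredient string to its canonical drug label, or ``None``.

    Matching is case-insensitive and punctuation-insensitive
    ("Trientine Tetrahydrochloride" and "PENICILLAMINE HCL" both resolve).
    """
    return config.ingredient_synonyms.get(_norm_key(raw))


@dataclass
class FunnelAudit:
    """Per-stage, per-drug counts of reports entering / kept / dropped."""

    stage_names: Tuple[str, ...] = STAGE_NAMES
    drugs: Tuple[str, ...] = ()
    counts_in: Dict[str, List[int]] = field(default_factory=dict)
    counts_out: Dict[str, List[int]] = field(default_factory=dict)

    def dropped(self, drug: str) -> List[int]:
        return [i - o for i, o in zip(self.counts_in[drug], self.counts_out[drug])]

    def validate(self) -> None:
        for drug in self.drugs:
            cin, cout = self.counts_in[drug], self.counts_out[drug]
            for k, (i, o) in enumerate(zip(cin, cout)):
                if o > i:
                    raise AssertionError(f"{drug} stage {k}: kept {o} > entered {i}")
                if k + 1 < len(cin) and cin[k + 1] != o:
                    raise AssertionError(f"{drug} stage chain broken at {k}")


def _mapped_entries(report: CaseReport, config: FilterConfig):
    """(canonical_drug, entry) pairs for entries naming a canonical chelator."""
    out = []
    for entry in report.drugs:
        canon = normalize_ingredient(entry.ingredient, config)
        if canon is not None:
            out.append((canon, entry))
    return out


def apply_filtration_funnel(cases: CaseSet, config: FilterConfig
                            ) -> Tuple[Dict[str, CaseSet], FunnelAudit]:
    """Run the four-stage funnel; returns per-drug cohorts and the audit.

    The input must already be deduplicated.  A report qualifying for both
    chelators is assigned to both cohorts (counted once per drug) unless
    ``allow_double_assignment`` is off.
    """
    drugs = config.canonical_drugs
    audit = FunnelAudit(drugs=drugs,
                        counts_in={d: [0, 0, 0, 0] for d in drugs},
                        counts_out={d: [0, 0, 0, 0] for d in drugs})
    survivors: Dict[str, list] = {d: [] for d in drugs}

    for report in cases.reports:
        mapped = _mapped_entries(report, config)
        per_drug: Dict[str, list] = {}
        for canon, entry in mapped:
            per_drug.setdefault(canon, []).append(entry)

        qualified = []
        for drug in drugs:
            audit.counts_in[drug][0] += 1
            entries = per_drug.get(drug)
            # stage 1: an entry maps to this chelator
            if not entries:
                continue
            audit.counts_out[drug][0] += 1
            audit.counts_in[drug][1] += 1
            # stage 2: at least one mapped entry carries some indication
            with_ind = [e for e in entries if e.indications]
            if not with_ind:
                continue
            audit.counts_out[drug][1] += 1
            audit.counts_in[drug][2] += 1
            # stage 3: not all indications explicitly excluded
            all_inds = set().union(*(e.indications for e in with_ind))
            if all_inds <= config.excluded_indications:
                continue
            audit.counts_out[drug][2] += 1
            audit.counts_in[drug][3] += 1
            # stage 4: target indication on a (primary-suspect) mapped entry
            ok = any(config.target_indication in e.indications
                     and (not config.require_primary_suspect
                          or e.role == "primary suspect")
                     for e in entries)
            if not ok:
                continue
            audit.counts_out[drug][3] += 1
            qualified.append(drug)

        if len(qualified) > 1 and not config.allow_double_assignment:
            for drug in qualified:  # retract the stage-4 keep
                audit.counts_out[drug][3] -= 1
            continue
        for drug in qualified:
            survivors[drug].append(report)

    audit.validate()
    cohorts = {d: CaseSet(survivors[d], provenance=f"{cases.provenance}|funnel:{d}")
               for d in drugs}
    return cohorts, audit


def reports_without_drug(cases: CaseSet, config: FilterConfig,
                         drug: str) -> CaseSet:
    """Comparator population: every report with no entry naming *drug*.

    This is the classical disproportionality background ("all other reports
    in the database"): excluding every report that mentions the study drug —
    not merely the indication-restricted cohort — keeps drug-exposed reports
    out of the comparator's event counts.
    """
    keep = [r for r in cases.reports
            if not any(normalize_ingredient(e.ingredient, config) == drug
                       for e in r.drugs)]
    return CaseSet(keep, provenance=f"reports-without-{drug}")


def funnel_audit_report(audit: FunnelAudit) -> str:
    """Render the audit as an aligned text table (one row per stage)."""
    drugs = audit.drugs
    header = ["stage"] + [f"{d} in/out/drop" for d in drugs]
    rows = [header]
    for k, stage in enumerate(audit.stage_names):
        row = [stage]
        for d in drugs:
            i = audit.counts_in[d][k]
            o = audit.counts_out[d][k]
            row.append(f"{i}/{o}/{i - o}")
        rows.append(row)
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
             for r in rows]
    return "\n".join(lines)
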