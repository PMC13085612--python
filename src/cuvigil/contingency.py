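"""Per drug–event 2×2 contingency tables and frequency-based event selection.

The counting unit is the report: each report contributes at most one to any
cell regardless of how many times an event term appears in its reaction set.
The comparator ("background") is an explicit CaseSet supplied by the caller —
typically the rest of the database after removing the drug's own cohort —
and every table carries its label so downstream outputs always state which
comparator produced them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .case_store import CaseSet


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event table with margins and expected count.

    a: drug reports with the event;    b: drug reports without it;
    c: comparator reports with it;     d: comparator reports without it.
    E = (a+b)(a+c)/N is the count expected under independence and is the
    common baseline for both the information component and EBGM shrinkage.
    """

    drug: str
    event: str
    a: int
    b: int
    c: int
    d: int
    comparator: str = "rest-of-background"

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        n = self.N
        return (self.a + self.b) * (self.a + self.c) / n if n else 0.0


def build_contingency(cohort: CaseSet, background: CaseSet, drug: str,
                      event: str) -> ContingencyTable:
    """Count the 2×2 table for one drug–event pair against a comparator.

    The comparator must share no ``case_id`` with the cohort (the drug's own
    reports are excluded from the background before calling).
    """
    if cohort.n == 0:
        raise ValueError("empty exposure cohort")
    cohort_ids = {r.case_id for r in cohort.reports}
    for rep in background.reports:
        if rep.case_id in cohort_ids:
            raise ValueError(
                f"cohort and background overlap: case_id {rep.case_id!r}")
    ev = event.strip().upper()
    a = sum(1 for r in cohort.reports if ev in r.reactions)
    c = sum(1 for r in background.reports if ev in r.reactions)
    return ContingencyTable(drug=drug, event=ev, a=a, b=cohort.n - a,
                            c=c, d=background.n - c,
                            comparator=background.provenance or "rest-of-background")


def rest_of_background(all_cases: CaseSet, cohort: CaseSet) -> CaseSet:
    """Comparator = every report in *all_cases* not in the drug's cohort."""
    cohort_ids = {r.case_id for r in cohort.reports}
    rest = [r for r in all_cases.reports if r.case_id not in cohort_ids]
    return CaseSet(rest, provenance="rest-of-background")


def top_k_events(cohort: CaseSet, k: int) -> List[Tuple[str, int]]:
    """The cohort's *k* most-reported event terms, with report counts.

    Each report counts once per distinct event; ordering is by descending
    count with lexicographic tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict = {}
    for rep in cohort.reports:
        for ev in rep.reactions:
            counts[ev] = counts.get(ev, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


def contingency_frame(tables: List[ContingencyTable]):
    """Export tables as a pandas DataFrame (drug,event,a,b,c,d,N,E)."""
    import pandas as pd

    return pd.DataFrame([{"drug": t.drug, "event": t.event, "a": t.a, "b": t.b,
                          "c": t.c, "d": t.d, "N": t.N, "E": t.E,
                          "comparator": t.comparator} for t in tables])
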