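"""Synthetic FAERS-like cohort generator with planted statistical structure.

The generator draws individual case safety reports whose every property is
controlled by a :class:`SyntheticTruth`: report counts per drug, a yearly
log-linear reporting intensity (per-year IRR), demographic mixes, indication
mixes including the target Wilson's-disease term and decoys, seriousness
probabilities, and — central for estimator validation — planted relative
reporting rates λ per drug–event pair multiplying the baseline event
probabilities.  A background pseudo-drug provides the comparator population.

Events are sampled independently per report (no co-occurrence correlation);
that is adequate for validating per-event disproportionality and is a
documented simplification.  A configurable fraction of reports is emitted
twice with differing versions to exercise deduplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .case_store import CaseReport, CaseSet, DrugEntry, map_continent
from .cohort_filter import TARGET_INDICATION

log = logging.getLogger(__name__)

BACKGROUND_DRUG = "OTHER DRUG"

DEFAULT_EVENTS: Dict[str, float] = {
    "NAUSEA": 0.12, "DIARRHOEA": 0.08, "VOMITING": 0.06, "HEADACHE": 0.07,
    "FATIGUE": 0.09, "RASH": 0.07, "PRURITUS": 0.04, "ALOPECIA": 0.02,
    "PYREXIA": 0.05, "DIZZINESS": 0.06, "TREMOR": 0.02, "DYSTONIA": 0.005,
    "ARTHRITIS": 0.008, "ARTHRALGIA": 0.05, "MYALGIA": 0.04,
    "ABDOMINAL PAIN": 0.06, "HEPATIC FAILURE": 0.004,
    "THROMBOCYTOPENIA": 0.01, "ALBUMINURIA": 0.003,
    "NEPHROTIC SYNDROME": 0.003, "MYASTHENIC SYNDROME": 0.002,
    "ANAEMIA": 0.03, "DRUG INEFFECTIVE": 0.10, "OFF LABEL USE": 0.05,
}

_COUNTRIES = ["CN", "JP", "IN", "KR", "US", "BR", "CA", "DE", "FR", "GB",
              "IT", "TR", "AU", "ZA", None]
_COUNTRY_W = [0.16, 0.10, 0.08, 0.04, 0.20, 0.05, 0.03, 0.07, 0.05, 0.05,
              0.04, 0.04, 0.02, 0.01, 0.06]

_SERIOUS_OUTCOME_W = {"hospitalization": 0.45, "other": 0.30, "death": 0.12,
                      "life-threatening": 0.06, "disability": 0.04,
                      "required intervention": 0.02, "congenital anomaly": 0.01}

#: raw ingredient spellings emitted per canonical drug (exercises the
#: synonym-map normalization of the funnel)
_RAW_SPELLINGS = {
    "D-PENICILLAMINE": ["D-PENICILLAMINE", "PENICILLAMINE",
                        "PENICILLAMINE HYDROCHLORIDE"],
    "TRIENTINE": ["TRIENTINE", "TRIENTINE HYDROCHLORIDE",
                  "TRIENTINE TETRAHYDROCHLORIDE"],
    BACKGROUND_DRUG: [BACKGROUND_DRUG],
}


def _default_indication_mix() -> Dict[str, float]:
    return {TARGET_INDICATION: 0.75, "RHEUMATOID ARTHRITIS": 0.06,
            "CYSTINURIA": 0.04, "": 0.15}  # "" = no indication recorded


@dataclass
class SyntheticTruth:
    """Everything the generator needs, and everything recovery tests check."""

    n_reports: Dict[str, int] = field(default_factory=lambda: {
        "D-PENICILLAMINE": 250, "TRIENTINE": 400, BACKGROUND_DRUG: 2000})
    baseline_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENTS))
    planted_rr: Dict[Tuple[str, str], float] = field(default_factory=dict)
    seriousness_prob: Dict[str, float] = field(default_factory=lambda: {
        "D-PENICILLAMINE": 0.95, "TRIENTINE": 0.55, BACKGROUND_DRUG: 0.50})
    sex_weights: Dict[str, float] = field(default_factory=lambda: {
        "female": 0.43, "male": 0.40, "unspecified": 0.17})
    age_group_weights: Dict[str, float] = field(default_factory=lambda: {
        "<18": 0.10, "18-64": 0.68, ">=65": 0.12, "unknown": 0.10})
    reporter_weights: Dict[str, float] = field(default_factory=lambda: {
        "healthcare professional": 0.60, "consumer": 0.30,
        "other/unknown": 0.10})
    indication_mix: Dict[str, Dict[str, float]] = field(default_factory=dict)
    primary_suspect_prob: float = 0.85
    year_range: Tuple[int, int] = (1990, 2025)
    irr_per_year: Dict[str, float] = field(default_factory=lambda: {
        "D-PENICILLAMINE": 1.035, "TRIENTINE": 1.119, BACKGROUND_DRUG: 1.05})
    duplicate_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.indication_mix:
            self.indication_mix = {
                d: ({"": 1.0} if d == BACKGROUND_DRUG
                    else _default_indication_mix())
                for d in self.n_reports}

    @property
    def event_vocabulary(self) -> List[str]:
        return sorted(self.baseline_rates)

    def rate(self, drug: str, event: str) -> float:
        """Effective per-report event probability baseline × λ, clipped to 1."""
        lam = self.planted_rr.get((drug, event), 1.0)
        p = self.baseline_rates[event] * lam
        if p > 1.0:
            log.warning("infeasible probability %.3f for (%s, %s); clipped to 1",
                        p, drug, event)
        return min(1.0, p)


def _choice(rng, items, weights):
    w = np.asarray(weights, dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def generate_cohort(truth: SyntheticTruth) -> CaseSet:
    """Draw the raw (pre-funnel, pre-dedupe) synthetic report set.

    Deterministic for a fixed seed: drugs are generated in sorted order and
    all sampling runs off one seeded generator.  Effective event
    probabilities above 1 after λ-multiplication are clipped (with a logged
    warning inside :meth:`SyntheticTruth.rate`).
    """
    rng = np.random.default_rng(truth.seed)
    events = truth.event_vocabulary
    reports: List[CaseReport] = []
    uid = 0

    for drug in sorted(truth.n_reports):
        n = truth.n_reports[drug]
        y0, y1 = truth.year_range
        years = np.arange(y0, y1 + 1)
        irr = truth.irr_per_year.get(drug, 1.0)
        yw = irr ** (years - y0).astype(float)
        yw = yw / yw.sum()
        probs = np.array([truth.rate(drug, ev) for ev in events])
        ind_items = sorted(truth.indication_mix[drug])
        ind_w = [truth.indication_mix[drug][i] for i in ind_items]
        sex_items = sorted(truth.sex_weights)
        sex_w = [truth.sex_weights[s] for s in sex_items]
        age_items = sorted(truth.age_group_weights)
        age_w = [truth.age_group_weights[g] for g in age_items]
        rep_items = sorted(truth.reporter_weights)
        rep_w = [truth.reporter_weights[r] for r in rep_items]

        event_draws = rng.random((n, len(events))) < probs[None, :]

        for i in range(n):
            uid += 1
            year = int(rng.choice(years, p=yw))
            sex = _choice(rng, sex_items, sex_w)
            group = _choice(rng, age_items, age_w)
            if group == "unknown":
                age = None
            elif group == "<18":
                age = float(rng.uniform(2, 17.9))
            elif group == "18-64":
                age = float(rng.uniform(18, 64.9))
            else:
                age = float(rng.uniform(65, 90))
            country = _choice(rng, _COUNTRIES, _COUNTRY_W)
            reporter = _choice(rng, rep_items, rep_w)
            indication = _choice(rng, ind_items, ind_w)
            role = ("primary suspect"
                    if rng.random() < truth.primary_suspect_prob
                    else "concomitant")
            raw_name = _choice(rng, _RAW_SPELLINGS.get(drug, [drug]),
                               [1.0] * len(_RAW_SPELLINGS.get(drug, [drug])))
            entry = DrugEntry(ingredient=raw_name, role=role,
                              indications=frozenset({indication} - {""}))
            drugs = [entry]
            if rng.random() < 0.3:  # co-medication with its own indication
                drugs.append(DrugEntry("PARACETAMOL", "concomitant",
                                       frozenset({"PAIN"})))
            hit = [events[j] for j in np.flatnonzero(event_draws[i])]
            if not hit:
                # every report carries >= 1 reaction term; a filler outside
                # the analysis vocabulary keeps vocabulary marginals exact
                hit = ["PRODUCT USE ISSUE"]
            serious = bool(rng.random() < truth.seriousness_prob.get(drug, 0.5))
            if serious:
                k = 1 + int(rng.random() < 0.3)
                oc_items = sorted(_SERIOUS_OUTCOME_W)
                oc_w = np.array([_SERIOUS_OUTCOME_W[o] for o in oc_items])
                picks = rng.choice(len(oc_items), size=k, replace=False,
                                   p=oc_w / oc_w.sum())
                outcomes = frozenset(oc_items[j] for j in picks)
            else:
                outcomes = frozenset(
                    {"non-serious"} if rng.random() < 0.7 else {"other"})
            base = CaseReport(
                case_id=f"SYN{uid:07d}", version=2, receipt_year=year,
                age_years=age, sex=sex, country=country,
                continent=map_continent(country), reporter_type=reporter,
                serious=serious, outcomes=outcomes, drugs=drugs,
                reactions=frozenset(hit))
            if rng.random() < truth.duplicate_fraction:
                # an earlier version differing in one mutated field, so the
                # dedupe winner is defined
                stale_year = year - 1 if year > truth.year_range[0] else year + 1
                reports.append(CaseReport(
                    case_id=base.case_id, version=1, receipt_year=stale_year,
                    age_years=age, sex=sex, country=country,
                    continent=base.continent, reporter_type=reporter,
                    serious=serious, outcomes=outcomes, drugs=drugs,
                    reactions=frozenset(hit)))
            reports.append(base)
    return CaseSet(reports, provenance=f"synthetic(seed={truth.seed})",
                   meta={"truth_seed": truth.seed})


def planted_truth_report(truth: SyntheticTruth, signals) -> dict:
    """Compare estimated signal strengths with the planted ground truth.

    For every planted (drug, event) pair the raw estimate a/E and the shrunk
    EBGM are reported against the true λ; flag decisions are summarised as a
    confusion matrix against the λ ≠ 1 ground truth.
    """
    by_pair = {(row.drug, row.event): row for row in signals}
    pairs = []
    tp = fp = fn = tn = 0
    for row in signals:
        lam = truth.planted_rr.get((row.drug, row.event), 1.0)
        flagged = bool(row.flags)
        if lam != 1.0 and flagged:
            tp += 1
        elif lam != 1.0:
            fn += 1
        elif flagged:
            fp += 1
        else:
            tn += 1
    for (drug, event), lam in sorted(truth.planted_rr.items()):
        row = by_pair.get((drug, event))
        if row is None:
            continue
        pairs.append({"drug": drug, "event": event, "true_lambda": lam,
                      "raw_lambda_hat": row.a / row.E if row.E > 0 else float("nan"),
                      "ebgm": row.EBGM, "flags": sorted(row.flags)})
    n_null = fp + tn
    return {"pairs": pairs,
            "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
            "false_positive_rate": fp / n_null if n_null else float("nan")}
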