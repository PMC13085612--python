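"""End-to-end pipeline orchestration and paper-style table rendering."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .case_store import CaseSet, dedupe_cases, read_faers_tables, read_jsonl, write_jsonl
from .cohort_filter import (FilterConfig, apply_filtration_funnel,
                            funnel_audit_report, reports_without_drug)
from .contingency import build_contingency, rest_of_background, top_k_events
from .disprop import (DEFAULT_PRIOR, MgpsPrior, SignalRow, Thresholds,
                      compute_signal_row, fit_mgps_prior)
from .simulate import SyntheticTruth, generate_cohort
from .trends import (aggregate_yearly_counts, fit_logistic_glm, fit_poisson_glm,
                     tabulate_descriptives)

log = logging.getLogger(__name__)

FOOTNOTE = ("ROR = Reporting Odds Ratio; PRR = Proportional Reporting Ratio; "
            "IC = Information Component; IC025 = lower 95% credibility bound; "
            "EBGM = Empirical Bayes Geometric Mean; EB05/EB95 = 90% interval bounds")


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, filtering, thresholds."""

    input_jsonl: Optional[str] = None
    faers_paths: Optional[Dict[str, str]] = None  # demo/drug/reac/indi/outc
    scenario_seed: Optional[int] = None           # synthetic scenario
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    comparator: str = "reports-without-drug"
    top_k: int = 5
    thresholds: Thresholds = field(default_factory=Thresholds)
    fit_prior: bool = True
    out_dir: str = "cuvigil-out"

    def __post_init__(self):
        sources = sum(x is not None for x in
                      (self.input_jsonl, self.faers_paths, self.scenario_seed))
        if sources != 1:
            raise ValueError("exactly one input source must be given")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def render_signal_table(rows: List[SignalRow], fmt: str = "text") -> str:
    """Render signal rows in the published column order and rounding.

    Rows are ordered by descending report count ``a`` (ties lexicographic by
    event).  ROR/PRR/IC at 2 decimals, EBGM and its interval at 3.  Every
    table names its comparator and states the report-level counting unit and
    the absence of multiplicity adjustment.
    """
    rows = sorted(rows, key=lambda r: (-r.a, r.event))
    header = ["event", "ROR (95% CI)", "PRR", "IC", "IC025",
              "EBGM (EB05-EB95)", "a", "E", "flags"]
    table = [header]
    for r in rows:
        mark = "*" if r.corrected else ""
        table.append([
            r.event + mark,
            f"{_fmt(r.ROR, 2)} ({_fmt(r.ROR_CI[0], 2)}-{_fmt(r.ROR_CI[1], 2)})",
            _fmt(r.PRR, 2), _fmt(r.IC, 2), _fmt(r.IC025, 2),
            f"{_fmt(r.EBGM, 3)} ({_fmt(r.EB05, 3)}-{_fmt(r.EB95, 3)})",
            str(r.a), _fmt(r.E, 2), ",".join(sorted(r.flags)) or "-"])
    comparator = rows[0].comparator if rows else "unspecified"
    notes = [FOOTNOTE,
             f"Comparator: {comparator}. Counting unit: report. "
             "* = Haldane-Anscombe 0.5 correction applied. "
             "No multiple-testing adjustment."]
    if fmt == "csv":
        out = [",".join(header)]
        out += [",".join(f'"{c}"' if "," in c else c for c in row)
                for row in table[1:]]
        out += [f"# {n}" for n in notes]
        return "\n".join(out) + "\n"
    widths = [max(len(row[c]) for row in table) for c in range(len(header))]
    lines = ["  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
             for row in table]
    return "\n".join(lines + notes) + "\n"


def load_cases(config: RunConfig) -> CaseSet:
    if config.input_jsonl is not None:
        return read_jsonl(config.input_jsonl)
    if config.faers_paths is not None:
        p = config.faers_paths
        return read_faers_tables(p["demo"], p["drug"], p["reac"],
                                 p["indi"], p["outc"])
    return generate_cohort(SyntheticTruth(seed=config.scenario_seed))


def run_pipeline(config: RunConfig) -> dict:
    """ingest → dedupe → funnel → top-k → contingency → statistics → models.

    Writes the funnel audit, per-drug signal tables, descriptive tables,
    model summaries and a run log under ``config.out_dir``; returns the main
    objects for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw = load_cases(config)
    cases = dedupe_cases(raw)
    cohorts, audit = apply_filtration_funnel(cases, config.filter_config)
    (out / "funnel_audit.txt").write_text(funnel_audit_report(audit) + "\n")

    signal_rows: Dict[str, List[SignalRow]] = {}
    all_tables = []
    per_drug_tables: Dict[str, list] = {}
    for drug, cohort in cohorts.items():
        if cohort.n == 0:
            log.warning("empty cohort for %s; skipping signals", drug)
            signal_rows[drug] = []
            continue
        if config.comparator == "supplied-set":
            background = rest_of_background(cases, cohort)
        else:  # default: all reports not naming the drug
            background = reports_without_drug(cases, config.filter_config, drug)
        tables = [build_contingency(cohort, background, drug, ev)
                  for ev, _ in top_k_events(cohort, config.top_k)]
        per_drug_tables[drug] = tables
        all_tables.extend(tables)

    prior = DEFAULT_PRIOR
    if config.fit_prior and len(all_tables) >= 50:
        try:
            prior = fit_mgps_prior(all_tables)
        except (ValueError, RuntimeError) as exc:
            log.warning("MGPS prior fit unavailable (%s); using default prior", exc)
    for drug, tables in per_drug_tables.items():
        rows = [compute_signal_row(t, prior, config.thresholds) for t in tables]
        signal_rows[drug] = rows
        slug = drug.lower().replace(" ", "_")
        (out / f"signals_{slug}.txt").write_text(render_signal_table(rows))
        (out / f"signals_{slug}.csv").write_text(render_signal_table(rows, "csv"))

    for dim in ("continent", "reporter_type", "age_group", "sex",
                "seriousness", "outcomes"):
        frame = tabulate_descriptives(cohorts, dim)
        frame.to_csv(out / f"descriptives_{dim.replace('/', '_')}.csv")

    trend = None
    series = [aggregate_yearly_counts(c, d) for d, c in cohorts.items()
              if c.n > 0 and len({r.receipt_year for r in c.reports
                                  if r.receipt_year is not None}) >= 3]
    if len(series) >= 1:
        try:
            trend = fit_poisson_glm(series[:2], with_interaction=len(series) == 2)
        except (ValueError, RuntimeError) as exc:
            log.warning("trend model unavailable: %s", exc)

    logistic = None
    pooled = CaseSet([r for c in cohorts.values() for r in c.reports],
                     provenance="pooled-cohorts")
    try:
        logistic = fit_logistic_glm(pooled, outcome="serious")
    except (ValueError, RuntimeError) as exc:
        log.warning("logistic model unavailable: %s", exc)

    run_log = {
        "cuvigil_version": __version__,
        "input": config.input_jsonl or (config.faers_paths and "faers")
                 or f"synthetic(seed={config.scenario_seed})",
        "n_raw": raw.n, "n_deduped": cases.n,
        "cohort_sizes": {d: c.n for d, c in cohorts.items()},
        "comparator": config.comparator,
        "top_k": config.top_k,
        "thresholds": vars(config.thresholds),
        "prior": {k: getattr(prior, k)
                  for k in ("alpha1", "beta1", "alpha2", "beta2", "P")},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    write_jsonl(cases, out / "cases.jsonl")
    return {"cases": cases, "cohorts": cohorts, "audit": audit,
            "signals": signal_rows, "trend": trend, "logistic": logistic,
            "prior": prior, "run_log": run_log}
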