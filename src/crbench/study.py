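"""Experiment driver: the simulation grid and the null type-I-error study.

One replicate = simulate a dataset under a scenario, run a 5x2-fold
cross-validated comparison of the Fine-Gray model against the
competing-risks random survival forest under the integrated Brier score,
and apply the paired t-test and the combined F-test at level alpha.
``run_grid`` aggregates replicates into a per-(scenario, n) summary:
percent significant tests and mean cross-validated IBS per model.
``run_null_study`` runs the all-effects-zero scenario, where neither model
can have a real advantage, and reports empirical rejection rates (type-I
error) plus the full p-value samples for uniformity checks.

Replicate streams are derived from (seed, replicate, scenario, n) via
numpy SeedSequence, so any cell of the grid is reproducible in isolation
and the whole study is deterministic byte-for-byte.  Per-replicate records
are persisted before aggregation; rerunning with an existing record file
skips completed replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cv52
from .adapters import FineGrayAdapter, ForestAdapter
from .finegray import ConvergenceError
from .forest import ForestConfig
from .simulate import CensoringSpec, ScenarioSpec, simulate_dataset

__all__ = ["StudyConfig", "run_replicate", "run_cell", "run_grid",
           "run_null_study", "summarize_records", "write_summary",
           "RECORD_COLUMNS", "SUMMARY_COLUMNS"]

log = logging.getLogger("crbench")

_SCENARIO_CODE = {"linear": 1, "quadratic": 2, "interaction": 3, "null": 4}

RECORD_COLUMNS = (
    ["scenario", "n", "seed", "rep"]
    + [f"p{i}{j}" for i in range(1, 6) for j in (1, 2)]
    + ["ibs_fg", "ibs_rsf", "t_stat", "t_pvalue", "t_significant",
       "f_stat", "f_pvalue", "f_significant"]
)

SUMMARY_COLUMNS = ["scenario", "n", "pct_sig_t", "pct_sig_f", "ibs_fg",
                   "ibs_rsf", "se_pct_sig_t", "se_pct_sig_f", "se_ibs_fg",
                   "se_ibs_rsf", "n_replicates", "n_excluded"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run (the full grid is scenarios x sizes x
    seeds x reps_per_seed replicates)."""

    scenarios: Sequence[str] = ("linear", "quadratic", "interaction")
    sizes: Sequence[int] = (200, 300, 400, 500, 2000, 3000)
    seeds: Sequence[int] = tuple(range(10))
    reps_per_seed: int = 100
    forest: ForestConfig = field(default_factory=ForestConfig)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    alpha: float = 0.05
    grid_quantile: float = 1.0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.scenarios or not self.sizes or not self.seeds:
            raise ValueError("need at least one scenario, size and seed")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _replicate_streams(scenario: str, n: int, seed: int, rep: int):
    """Independent (data, cv, forest) integer seeds for one replicate."""
    root = np.random.SeedSequence([int(seed), int(rep), int(n),
                                   _SCENARIO_CODE[scenario]])
    data_ss, cv_ss, forest_ss = root.spawn(3)
    as_int = lambda ss: int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    return data_ss, as_int(cv_ss), as_int(forest_ss)


def run_replicate(scenario: str, n: int, seed: int, rep: int,
                  config: StudyConfig) -> dict:
    """One simulated dataset, one 5x2-cv FG-vs-RSF comparison, both tests.

    Raises :class:`~crbench.finegray.ConvergenceError` or
    :class:`~crbench.cv52.FoldingError` on replicate-level model failure.
    """
    data_ss, cv_seed, forest_seed = _replicate_streams(scenario, n, seed, rep)
    spec = ScenarioSpec(kind=scenario, n=n, censoring=config.censoring)
    sample = simulate_dataset(spec, np.random.default_rng(data_ss))

    fg = FineGrayAdapter()
    rsf = ForestAdapter(config=replace(config.forest, seed=forest_seed))
    scorer = cv52.ibs_scorer(config.grid_quantile)

    table = cv52.run_5x2cv(sample, fg, rsf, scorer, seed=cv_seed)
    t_res = cv52.paired_t_5x2(table, config.alpha)
    f_res = cv52.combined_f_5x2(table, config.alpha)

    rec = {"scenario": scenario, "n": n, "seed": seed, "rep": rep}
    for i in range(5):
        for j in range(2):
            rec[f"p{i + 1}{j + 1}"] = table.p[i, j]
    rec.update(ibs_fg=float(table.metric_a.mean()),
               ibs_rsf=float(table.metric_b.mean()),
               t_stat=t_res.statistic, t_pvalue=t_res.p_value,
               t_significant=bool(t_res.significant),
               f_stat=f_res.statistic, f_pvalue=f_res.p_value,
               f_significant=bool(f_res.significant))
    return rec


def run_cell(scenario: str, n: int, config: StudyConfig,
             records_path: Optional[Path] = None) -> pd.DataFrame:
    """All replicates of one (scenario, n) cell; failures logged & excluded."""
    done: set[tuple[int, int]] = set()
    rows: list[dict] = []
    if records_path is not None and records_path.exists():
        prev = pd.read_csv(records_path)
        prev = prev[(prev["scenario"] == scenario) & (prev["n"] == n)]
        done = set(zip(prev["seed"].astype(int), prev["rep"].astype(int)))
        rows = prev.to_dict("records")

    excluded = 0
    for seed in config.seeds:
        for rep in range(config.reps_per_seed):
            if (seed, rep) in done:
                continue
            try:
                rec = run_replicate(scenario, n, seed, rep, config)
            except (ConvergenceError, cv52.FoldingError,
                    cv52.DegenerateVarianceError) as e:
                excluded += 1
                log.warning("excluded %s n=%d seed=%d rep=%d: %s",
                            scenario, n, seed, rep, e)
                continue
            rows.append(rec)
            if records_path is not None:
                pd.DataFrame([rec])[RECORD_COLUMNS].to_csv(
                    records_path, mode="a", index=False,
                    header=not records_path.exists())
            log.debug("done %s n=%d seed=%d rep=%d", scenario, n, seed, rep)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.attrs["n_excluded"] = excluded
    return df


def summarize_records(records: pd.DataFrame, n_excluded: int | None = None) -> pd.DataFrame:
    """Aggregate per-replicate records to the summary-table layout."""
    if n_excluded is None:
        n_excluded = records.attrs.get("n_excluded", 0)
    out = []
    for (scenario, n), grp in records.groupby(["scenario", "n"], sort=False):
        m = len(grp)
        pt = grp["t_significant"].mean() * 100
        pf = grp["f_significant"].mean() * 100
        out.append({
            "scenario": scenario, "n": n,
            "pct_sig_t": pt, "pct_sig_f": pf,
            "ibs_fg": grp["ibs_fg"].mean(), "ibs_rsf": grp["ibs_rsf"].mean(),
            "se_pct_sig_t": np.sqrt(pt * (100 - pt) / m) if m else np.nan,
            "se_pct_sig_f": np.sqrt(pf * (100 - pf) / m) if m else np.nan,
            "se_ibs_fg": grp["ibs_fg"].std(ddof=1) / np.sqrt(m) if m > 1 else np.nan,
            "se_ibs_rsf": grp["ibs_rsf"].std(ddof=1) / np.sqrt(m) if m > 1 else np.nan,
            "n_replicates": m, "n_excluded": n_excluded,
        })
    return pd.DataFrame(out, columns=SUMMARY_COLUMNS)


def run_grid(config: StudyConfig) -> pd.DataFrame:
    """Run the whole scenario x size grid; returns the summary table.

    When ``config.out_dir`` is set, per-replicate records stream to
    ``replicates.csv`` (making the run resumable) and the summary is written
    to ``summary.csv``.
    """
    records_path = summary_path = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_path = out / "replicates.csv"
        summary_path = out / "summary.csv"

    frames = []
    excluded = 0
    for scenario in config.scenarios:
        for n in config.sizes:
            log.info("cell %s n=%d", scenario, n)
            cell = run_cell(scenario, n, config, records_path)
            excluded += cell.attrs.get("n_excluded", 0)
            frames.append(cell)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize_records(records, excluded)
    if summary_path is not None:
        write_summary(summary, summary_path)
    return summary


def run_null_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type-I-error study under the all-effects-zero scenario.

    Returns ``(summary, pvalues)``: the summary carries empirical rejection
    rates at alpha (as percentages) and the mean cv IBS of both models; the
    p-value frame holds every replicate's t and F p-values and statistics
    for distributional checks.
    """
    cfg = replace(config, scenarios=("null",))
    records_path = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_path = out / "null_replicates.csv"

    frames = []
    excluded = 0
    for n in cfg.sizes:
        log.info("null cell n=%d", n)
        cell = run_cell("null", n, cfg, records_path)
        excluded += cell.attrs.get("n_excluded", 0)
        frames.append(cell)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize_records(records, excluded)
    pvalues = records[["scenario", "n", "seed", "rep", "t_stat", "t_pvalue",
                       "f_stat", "f_pvalue", "t_significant",
                       "f_significant"]].copy()
    if cfg.out_dir is not None:
        write_summary(summary, Path(cfg.out_dir) / "null_summary.csv")
        pvalues.to_csv(Path(cfg.out_dir) / "null_pvalues.csv", index=False)
    return summary, pvalues


def write_summary(summary: pd.DataFrame, path) -> None:
    """Deterministic CSV with the documented summary schema."""
    summary.reindex(columns=SUMMARY_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")
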