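"""5x2-fold cross-validated paired t-test and combined F-test.

Five independent random halvings of one dataset; within each halving both
halves serve once as training set and once as test set, so training sets
never overlap their test sets and successive replications differ only in the
random split.  With p_i^(j) the performance difference (model A minus
model B) on the held-out half of fold j in replication i,

    p_bar_i = (p_i^(1) + p_i^(2)) / 2
    s_i^2   = (p_i^(1) - p_bar_i)^2 + (p_i^(2) - p_bar_i)^2

    t_tilde = p_1^(1) / sqrt( (1/5) sum_i s_i^2 )          ~ t with 5 df
    f       = sum_i sum_j (p_i^(j))^2 / (2 sum_i s_i^2)    ~ F with 10, 5 df

The t statistic keeps the original single-cell numerator p_1^(1) — a known
fragility of the construction (the result depends on which replication is
labelled first); the combined F statistic pools all ten cells and is the
more conservative of the two.  Both are used two-sided / upper-tailed at
alpha = 0.05 by default; the F critical value at that level is 4.74.

Models enter as opaque adapters with ``fit(train) -> predict(X, times)``
semantics so the same machinery compares any pair of CIF predictors under
any scalar metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy import stats

from . import metrics
from .simulate import CompetingRisksSample

__all__ = ["DifferenceTable", "TestResult", "ModelAdapter", "ibs_scorer",
           "run_5x2cv", "paired_t_5x2", "combined_f_5x2", "f_critical_value",
           "F_TEST_DF", "T_TEST_DF"]

T_TEST_DF = 5
F_TEST_DF = (10, 5)


class DegenerateVarianceError(RuntimeError):
    """All replication variances are zero while the numerator is not."""


class FoldingError(RuntimeError):
    """Could not produce folds containing target-cause events."""


class ModelAdapter(Protocol):
    """Opaque fit/predict pair: ``fit`` returns a predictor mapping
    (X, times) to a :class:`~crbench.metrics.CifCurve`."""

    name: str

    def fit(self, train: CompetingRisksSample):  # -> Callable[[X, times], CifCurve]
        ...


@dataclass
class DifferenceTable:
    """Fold-wise metric differences p_i^(j) = metric_A - metric_B (5 x 2),
    with the raw per-cell metric values of both models."""

    p: np.ndarray            # (5, 2)
    metric_a: np.ndarray     # (5, 2)
    metric_b: np.ndarray     # (5, 2)
    fold_seeds: np.ndarray   # (5,) seeds that determined each halving

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, float)
        if self.p.shape != (5, 2):
            raise ValueError("difference table must be 5 x 2")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("difference table entries must be finite")

    def replication_variances(self) -> np.ndarray:
        """s_i^2 per replication."""
        pbar = self.p.mean(axis=1, keepdims=True)
        return ((self.p - pbar) ** 2).sum(axis=1)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: str
    significant: bool
    alpha: float
    name: str


def _halves(n: int, replication: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random halving; with odd n the extra subject joins the training
    half, alternating across replications."""
    perm = rng.permutation(n)
    half = n // 2
    if n % 2 and replication % 2:
        half += 1  # n odd: extra subject alternates between the halves
    return perm[:half], perm[half:]


def ibs_scorer(grid_quantile: float = 1.0) -> Callable:
    """Scorer: IPCW integrated Brier score of a CIF predictor on a test fold."""

    def score(predictor, test: CompetingRisksSample) -> float:
        grid = metrics.default_grid(test, grid_quantile)
        G = metrics.censoring_km(test)
        pred = predictor(test.X, grid)
        return metrics.ibs(pred, test, grid, G)

    return score


def run_5x2cv(sample: CompetingRisksSample, model_a: ModelAdapter,
              model_b: ModelAdapter, scorer: Callable, seed: int,
              cause: int = 1, max_refolds: int = 20) -> DifferenceTable:
    """Five 2-fold cross-validations of two models on one dataset.

    Each replication splits the sample into two halves; each half is used
    once for training (both models) and once for testing, and
    p_i^(j) = scorer(A) - scorer(B) on the held-out half.  A halving that
    leaves either half without target-cause events is redrawn with a fresh
    sub-seed (up to ``max_refolds`` times).
    """
    n = len(sample)
    ss = np.random.SeedSequence(seed)
    p = np.zeros((5, 2))
    ma = np.zeros((5, 2))
    mb = np.zeros((5, 2))
    fold_seeds = np.zeros(5, dtype=np.uint32)

    for i in range(5):
        child = ss.spawn(1)[0]
        for attempt in range(max_refolds):
            rng = np.random.default_rng(child)
            idx1, idx2 = _halves(n, i, rng)
            ok = all(np.any(sample.event[idx] == cause) for idx in (idx1, idx2))
            if ok:
                break
            child = child.spawn(1)[0]
        else:
            raise FoldingError(f"no cause-{cause} events in a half after "
                               f"{max_refolds} refolds")
        fold_seeds[i] = child.generate_state(1)[0]

        halves = (sample.subset(idx1), sample.subset(idx2))
        for j, (train, test) in enumerate(((halves[0], halves[1]),
                                           (halves[1], halves[0]))):
            pred_a = model_a.fit(train)
            pred_b = model_b.fit(train)
            ma[i, j] = scorer(pred_a, test)
            mb[i, j] = scorer(pred_b, test)
            p[i, j] = ma[i, j] - mb[i, j]

    return DifferenceTable(p=p, metric_a=ma, metric_b=mb, fold_seeds=fold_seeds)


def paired_t_5x2(table: DifferenceTable, alpha: float = 0.05) -> TestResult:
    """Two-sided 5x2-cv paired t-test (statistic t_tilde, 5 df)."""
    s2 = table.replication_variances()
    numer = table.p[0, 0]
    denom_sq = s2.sum() / 5.0
    if denom_sq == 0.0:
        if numer == 0.0:
            return TestResult(0.0, 1.0, "t(5)", False, alpha, "5x2cv paired t")
        raise DegenerateVarianceError("zero replication variances with "
                                      "nonzero numerator cell")
    stat = numer / np.sqrt(denom_sq)
    pval = 2.0 * stats.t.sf(abs(stat), T_TEST_DF)
    return TestResult(float(stat), float(pval), "t(5)", pval < alpha, alpha,
                      "5x2cv paired t")


def combined_f_5x2(table: DifferenceTable, alpha: float = 0.05) -> TestResult:
    """Combined 5x2-cv F-test (statistic f, F(10, 5), upper-tailed)."""
    s2 = table.replication_variances()
    ss_cells = float((table.p ** 2).sum())
    denom = 2.0 * s2.sum()
    if denom == 0.0:
        if ss_cells == 0.0:
            return TestResult(0.0, 1.0, "F(10,5)", False, alpha, "5x2cv combined F")
        raise DegenerateVarianceError("zero replication variances with "
                                      "nonzero cells")
    stat = ss_cells / denom
    pval = stats.f.sf(stat, *F_TEST_DF)
    return TestResult(float(stat), float(pval), "F(10,5)", pval < alpha, alpha,
                      "5x2cv combined F")


def f_critical_value(alpha: float = 0.05) -> float:
    """Upper-tail critical value of F(10, 5) at ``alpha`` (4.74 at 0.05)."""
    return float(stats.f.ppf(1.0 - alpha, *F_TEST_DF))
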