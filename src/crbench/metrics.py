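"""Censoring-weighted Brier score and integrated Brier score for CIF predictions.

Both compared models predict the cumulative incidence of cause 1,
CIF1(t|x) = P(T <= t, cause = 1 | x).  The Brier score at horizon t is the
inverse-probability-of-censoring-weighted (IPCW) mean squared residual

    BS(t) = 1/n * sum_l w_l(t) * ( I(T_l <= t, delta_l = 1) - CIF1_hat(t|x_l) )^2

with weights w_l(t) = I(T_l <= t, delta_l >= 1) / G_hat(T_l-)
                    + I(T_l > t) / G_hat(t),

where G_hat is the Kaplan-Meier estimate of the censoring-time survival
function (censoring is the "event"; real events are censorings for G).
Subjects censored before t contribute nothing; subjects with a competing
event by t count as cause-1-event-free with the weight taken at their own
event time.  An uninformative predictor CIF1 = 0.5 on uncensored data scores
exactly 0.25 at every t.

The integrated Brier score is the trapezoidal time-average of BS(t) over an
evaluation grid — by default the unique event times of the scored sample up
to its largest event time, matching the 0-to-max(t) integration window of
the definition.  A lower grid quantile can be configured to keep the IPCW
weights away from the tail of G_hat at the cost of down-weighting the late
time region (where an uninformative CIF scores near 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CompetingRisksSample

__all__ = ["StepSurvival", "CifCurve", "censoring_km", "default_grid",
           "brier_score", "ibs"]


class DegenerateWeightsError(RuntimeError):
    """G_hat is 0 where an IPCW weight is required."""


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous nonincreasing step function with S(0) = 1.

    ``times`` are the (sorted, unique) jump times; ``values[i]`` is the value
    on [times[i], times[i+1]).  Evaluable at t and at the left limit t-.
    """

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        if len(self.times) == 0:
            return np.ones_like(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        return np.where(idx == 0, 1.0, self.values[np.maximum(idx - 1, 0)])

    def left(self, t) -> np.ndarray:
        """Left limit S(t-)."""
        if len(self.times) == 0:
            return np.ones_like(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="left")
        return np.where(idx == 0, 1.0, self.values[np.maximum(idx - 1, 0)])


@dataclass
class CifCurve:
    """Predicted cause-1 cumulative incidence on a common time grid.

    ``values`` has one row per subject, one column per grid time; each row is
    nondecreasing with values in [0, 1].
    """

    times: np.ndarray           # (m,) sorted
    values: np.ndarray          # (n_subjects, m)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.times):
            raise ValueError("values must have one column per grid time")

    def at(self, t: float) -> np.ndarray:
        """Per-subject CIF at time t (step interpolation, 0 before the grid)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return np.zeros(self.values.shape[0])
        return self.values[:, idx]


def km_step(time: np.ndarray, died: np.ndarray) -> StepSurvival:
    """Kaplan-Meier survival step function for indicator ``died``.

    Product-limit estimate over the unique times with at least one ``died``
    event; ties between events and censorings at the same time follow the
    standard convention (censorings stay in the risk set at their own time).
    """
    time = np.asarray(time, float)
    died = np.asarray(died, bool)
    order = np.argsort(time, kind="stable")
    t, d = time[order], died[order]
    ut, start = np.unique(t, return_index=True)
    n = len(t)
    # events and at-risk counts per unique time
    d_counts = np.add.reduceat(d.astype(int), start)
    at_risk = n - start
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d_counts / at_risk
    surv = np.cumprod(frac)
    keep = d_counts > 0
    return StepSurvival(ut[keep], surv[keep])


def censoring_km(sample: CompetingRisksSample) -> StepSurvival:
    """Marginal KM estimate G_hat of the censoring-time survival function.

    Censoring (event == 0) is the "event"; any real event is treated as a
    censoring of the censoring process.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    return km_step(sample.time, sample.event == 0)


def default_grid(sample: CompetingRisksSample, quantile: float = 1.0) -> np.ndarray:
    """Unique event times of ``sample`` up to its ``quantile`` observed time."""
    tmax = np.quantile(sample.time, quantile)
    times = np.unique(sample.time[(sample.event > 0) & (sample.time <= tmax)])
    if len(times) < 2:  # degenerate folds: fall back to all event times
        times = np.unique(sample.time[sample.event > 0])
    return times


def brier_score(pred: CifCurve, sample: CompetingRisksSample, t: float,
                G: StepSurvival) -> float:
    """IPCW Brier score of the cause-1 CIF prediction at horizon t."""
    cif_t = pred.at(t)
    status = (sample.time <= t) & (sample.event == 1)
    past_event = (sample.time <= t) & (sample.event > 0)
    future = sample.time > t

    w = np.zeros(len(sample))
    if past_event.any():
        g_left = G.left(sample.time[past_event])
        if np.any(g_left <= 0):
            raise DegenerateWeightsError("G_hat(T-) = 0 at an observed event time")
        w[past_event] = 1.0 / g_left
    if future.any():
        g_t = float(G(t))
        if g_t <= 0:
            raise DegenerateWeightsError(f"G_hat({t}) = 0 with subjects still at risk")
        w[future] = 1.0 / g_t

    return float(np.mean(w * (status.astype(float) - cif_t) ** 2))


def _brier_curve(pred: CifCurve, sample: CompetingRisksSample,
                 grid: np.ndarray, G: StepSurvival) -> np.ndarray:
    """BS(t) for every grid time, vectorised over the grid."""
    n, m = len(sample), len(grid)
    # per-subject CIF on the grid, step-aligned to pred.times
    idx = np.searchsorted(pred.times, grid, side="right") - 1
    cif = np.where(idx >= 0, pred.values[:, np.maximum(idx, 0)], 0.0)  # (n, m)

    time = sample.time[:, None]
    status1 = ((time <= grid) & (sample.event[:, None] == 1)).astype(float)
    past_event = (time <= grid) & (sample.event[:, None] > 0)
    future = time > grid

    g_left = G.left(sample.time)            # (n,)
    g_grid = np.asarray(G(grid), float)     # (m,)
    if np.any(past_event & (g_left[:, None] <= 0)):
        raise DegenerateWeightsError("G_hat(T-) = 0 at an observed event time")
    if np.any(future.any(axis=0) & (g_grid <= 0)):
        raise DegenerateWeightsError("G_hat(t) = 0 with subjects still at risk")

    with np.errstate(divide="ignore"):
        w = past_event / g_left[:, None] + future / g_grid
    return np.mean(w * (status1 - cif) ** 2, axis=0)


def ibs(pred: CifCurve, sample: CompetingRisksSample, grid: np.ndarray,
        G: StepSurvival) -> float:
    """Trapezoidal time-average of BS(t) over ``grid`` (a value in [0, 1])."""
    grid = np.asarray(grid, float)
    if len(grid) < 2:
        raise ValueError("IBS grid needs at least 2 points")
    bs = _brier_curve(pred, sample, grid, G)
    span = grid[-1] - grid[0]
    return float(np.trapezoid(bs, grid) / span)
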