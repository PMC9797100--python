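"""Random survival forest for competing risks.

Trees are grown on bootstrap samples (with replacement, size n).  At each
node, for each of ``mtry`` candidate covariates, ``nsplit`` random cutpoints
are drawn from the in-node unique covariate values, and the (covariate,
cutpoint) pair maximising the absolute generalised log-rank statistic for
the target cause is chosen.  The statistic standardises the excess of
cause-k events in the left daughter over its expectation under the null of
equal cause-specific hazards:

    i_k(x, s) = sum_j [ d_{k,L}(t_j) - d_k(t_j) R_L(t_j) / R(t_j) ] / sigma_hat

    sigma_hat^2 = sum_j d_k(t_j) (R_L/R) (1 - R_L/R) (R - d_k(t_j)) / (R - 1)

summed over the distinct cause-k event times t_j <= tau in the node, with
unit time weights.  Splitting stops when no admissible cutpoint leaves both
daughters with at least ``nodesize`` subjects, when no cause-k events remain,
or when no candidate discriminates (statistic 0).

Terminal nodes store Aalen-Johansen cumulative incidence curves for both
causes computed from the in-node bootstrap rows; the ensemble prediction for
a subject is the average of its terminal CIFs across trees, evaluated on a
common time grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .metrics import CifCurve
from .simulate import CompetingRisksSample

__all__ = ["ForestConfig", "CRTree", "crlogrank_split_stat", "grow_tree",
           "grow_forest", "predict_cif_forest"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters (defaults follow the simulation-study protocol)."""

    ntree: int = 500
    nodesize: int = 15
    nsplit: Optional[int] = 2    # None = exhaustive over all cutpoints
    mtry: Optional[int] = None   # None = all covariates
    tau: Optional[float] = None  # None = largest observed time in the node
    cause: int = 1               # cause whose statistic drives splits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1 or self.nodesize < 1:
            raise ValueError("ntree and nodesize must be >= 1")
        if self.nsplit is not None and self.nsplit < 1:
            raise ValueError("nsplit must be >= 1 (or None for exhaustive)")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1 (or None for all covariates)")


try:  # compiled fast path; the numpy implementations below stay the reference
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _split_stats_numpy(ts: np.ndarray, es: np.ndarray, Ls: np.ndarray,
                       cause: int, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Generalised log-rank statistics for many candidate splits at once.

    ``ts``/``es`` must be sorted by time; ``Ls`` is (n_node, n_candidates)
    left-daughter membership (float).  Returns ``(i_k, variance)`` per
    candidate; a candidate with zero variance gets statistic 0.
    """
    n, C = Ls.shape
    ev = (es == cause) & (ts <= tau)
    if not ev.any():
        z = np.zeros(C)
        return z, z.copy()
    ev_times = ts[ev]
    first = np.searchsorted(ts, ev_times, side="left")
    last = np.searchsorted(ts, ev_times, side="right")
    keep = np.empty(len(ev_times), dtype=bool)   # one entry per distinct time
    keep[:1] = True
    np.not_equal(ev_times[1:], ev_times[:-1], out=keep[1:])
    ev_times, first, last = ev_times[keep], first[keep], last[keep]
    m = len(ev_times)

    # at-risk counts: all rows with T >= t_j
    R = (n - first).astype(float)                          # (m,)
    rev = np.empty((n + 1, C))
    rev[n] = 0.0
    np.cumsum(Ls[::-1], axis=0, out=rev[:n][::-1])
    R_left = rev[first]                                    # (m, C)

    # cause-k event counts at each distinct event time, total and left
    codes = np.searchsorted(ev_times, ts[ev])
    d = np.bincount(codes, minlength=m).astype(float)      # (m,)
    cs = np.empty((n + 1, C))
    cs[0] = 0.0
    np.cumsum(Ls * ev[:, None], axis=0, out=cs[1:])
    d_left = cs[last] - cs[first]                          # (m, C)

    frac = R_left / R[:, None]
    numer = np.sum(d_left - d[:, None] * frac, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = d[:, None] * frac * (1.0 - frac) * ((R[:, None] - d[:, None])
                                                    / (R[:, None] - 1.0))
    vterm[R <= 1.0] = 0.0
    var = np.sum(vterm, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, numer / np.sqrt(var), 0.0)
    return stat, var


def _split_stats_loops(ts, es, Ls, cause, tau):
    """Loop form of the split statistic (compiled with numba when present)."""
    n, C = Ls.shape
    num = np.zeros(C)
    var = np.zeros(C)
    stat = np.zeros(C)
    rev = np.zeros(C)              # left-daughter at-risk counts, built
    revs = np.zeros((n, C))        # backwards over the sorted rows
    for i in range(n - 1, -1, -1):
        for c in range(C):
            rev[c] += Ls[i, c]
            revs[i, c] = rev[c]
    i = 0
    while i < n:
        j = i
        d = 0.0
        dl = np.zeros(C)
        while j < n and ts[j] == ts[i]:
            if es[j] == cause and ts[j] <= tau:
                d += 1.0
                for c in range(C):
                    dl[c] += Ls[j, c]
            j += 1
        if d > 0.0:
            R = float(n - i)
            for c in range(C):
                fr = revs[i, c] / R
                num[c] += dl[c] - d * fr
                if R > 1.0:
                    var[c] += d * fr * (1.0 - fr) * (R - d) / (R - 1.0)
        i = j
    for c in range(C):
        stat[c] = num[c] / np.sqrt(var[c]) if var[c] > 0.0 else 0.0
    return stat, var


if _njit is not None:
    _split_stats_loops = _njit(cache=True)(_split_stats_loops)

    def _split_stats_sorted(ts, es, Ls, cause, tau):
        return _split_stats_loops(ts, es, Ls, int(cause), float(tau))
else:  # pragma: no cover
    _split_stats_sorted = _split_stats_numpy


def _split_stats(time: np.ndarray, event: np.ndarray, left: np.ndarray,
                 cause: int, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`_split_stats_sorted` for unsorted input."""
    order = np.argsort(time, kind="stable")
    return _split_stats_sorted(time[order], event[order],
                               left[order].astype(float), cause, tau)


def crlogrank_split_stat(time: np.ndarray, event: np.ndarray, x: np.ndarray,
                         split_point: float, cause: int = 1,
                         tau: Optional[float] = None) -> float:
    """Generalised log-rank statistic i_k for the split {x <= s} vs {x > s}.

    Both daughters must be nonempty; returns 0 when the variance estimate is
    zero (no discriminating information).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    left = x <= split_point
    if not left.any() or left.all():
        raise ValueError("split leaves an empty daughter")
    if tau is None:
        tau = float(time.max())
    stat, _ = _split_stats(time, event, left[:, None], cause, tau)
    return float(stat[0])


def _aj_loops(ts, es):
    """Loop form of the two-cause Aalen-Johansen estimator (numba-compiled
    when available); expects time-sorted input."""
    n = len(ts)
    m = 0
    i = 0
    while i < n:                   # count distinct times carrying events
        j = i
        has = False
        while j < n and ts[j] == ts[i]:
            if es[j] > 0:
                has = True
            j += 1
        if has:
            m += 1
        i = j
    times = np.empty(m)
    cif = np.zeros((2, m))
    surv = 1.0
    c1 = 0.0
    c2 = 0.0
    k = 0
    i = 0
    while i < n:
        j = i
        d1 = 0.0
        d2 = 0.0
        while j < n and ts[j] == ts[i]:
            if es[j] == 1:
                d1 += 1.0
            elif es[j] == 2:
                d2 += 1.0
            j += 1
        d = d1 + d2
        if d > 0.0:
            R = float(n - i)
            c1 += surv * d1 / R
            c2 += surv * d2 / R
            surv *= 1.0 - d / R
            times[k] = ts[i]
            cif[0, k] = c1
            cif[1, k] = c2
            k += 1
        i = j
    return times, cif


if _njit is not None:
    _aj_loops = _njit(cache=True)(_aj_loops)


def _aalen_johansen(time: np.ndarray, event: np.ndarray,
                    presorted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Aalen-Johansen CIFs for causes 1 and 2.

    Returns ``(times, cif)`` with ``cif`` of shape (2, m):
    CIF_k(t) = sum_{t_j <= t} S(t_j-) d_k(t_j) / R(t_j), with S the all-cause
    Kaplan-Meier survival.
    """
    if presorted:
        ts, es = np.asarray(time), np.asarray(event)
    else:
        order = np.argsort(time, kind="stable")
        ts, es = time[order], event[order]
    if _njit is not None:
        return _aj_loops(ts, es.astype(np.int64))
    n = len(ts)
    ev = es > 0
    if not ev.any():
        return np.empty(0), np.zeros((2, 0))
    ut = np.unique(ts[ev])
    first = np.searchsorted(ts, ut, side="left")
    R = (n - first).astype(float)
    codes = np.searchsorted(ut, ts[ev])
    d1 = np.bincount(codes[es[ev] == 1], minlength=len(ut)).astype(float)
    d2 = np.bincount(codes[es[ev] == 2], minlength=len(ut)).astype(float)
    d = d1 + d2
    surv = np.cumprod(1.0 - d / R)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    cif1 = np.cumsum(s_minus * d1 / R)
    cif2 = np.cumsum(s_minus * d2 / R)
    return ut, np.vstack([cif1, cif2])


@dataclass
class CRTree:
    """One competing-risks tree: flat arrays of split records plus terminal
    Aalen-Johansen CIF curves.  ``feature[i] == -1`` marks a terminal; its
    curves live at index ``terminal[i]``."""

    feature: np.ndarray            # (n_nodes,) int, -1 for terminals
    threshold: np.ndarray          # (n_nodes,) float
    children: np.ndarray           # (n_nodes, 2) int node ids
    terminal: np.ndarray           # (n_nodes,) int id into leaf curves, -1 inside
    leaf_times: list               # per terminal: (m,) event-time array
    leaf_cif: list                 # per terminal: (2, m) CIF values
    bootstrap_index: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_times)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal-curve index for every row of X (vectorised descent)."""
        out = np.empty(len(X), dtype=int)
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, rows = stack.pop()
            if self.feature[node] < 0:
                out[rows] = self.terminal[node]
                continue
            go_left = X[rows, self.feature[node]] <= self.threshold[node]
            stack.append((self.children[node, 0], rows[go_left]))
            stack.append((self.children[node, 1], rows[~go_left]))
        return out

    def leaf_cif_on_grid(self, grid: np.ndarray, cause: int = 1) -> np.ndarray:
        """(n_leaves, len(grid)) CIF values of each terminal on ``grid``."""
        out = np.zeros((self.n_leaves, len(grid)))
        k = cause - 1
        for i, (lt, lc) in enumerate(zip(self.leaf_times, self.leaf_cif)):
            if len(lt) == 0:
                continue
            idx = np.searchsorted(lt, grid, side="right") - 1
            out[i] = np.where(idx >= 0, lc[k][np.maximum(idx, 0)], 0.0)
        return out

    def to_json(self) -> str:
        """Debug dump of the tree structure."""
        nodes = []
        for i in range(len(self.feature)):
            if self.feature[i] < 0:
                nodes.append({"id": i, "terminal": int(self.terminal[i]),
                              "n_times": int(len(self.leaf_times[self.terminal[i]]))})
            else:
                nodes.append({"id": i, "feature": int(self.feature[i]),
                              "threshold": float(self.threshold[i]),
                              "left": int(self.children[i, 0]),
                              "right": int(self.children[i, 1])})
        return json.dumps({"nodes": nodes})


class _TreeBuilder:
    """Recursive growth over row sets kept in time-sorted order (children of
    a sorted node are sorted, so nodes never re-sort)."""

    def __init__(self, time, event, X, config: ForestConfig, rng: np.random.Generator):
        self.time, self.event, self.X = time, event, X
        self.cfg = config
        self.rng = rng
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.children: list[list[int]] = []
        self.terminal: list[int] = []
        self.leaf_times: list[np.ndarray] = []
        self.leaf_cif: list[np.ndarray] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.children.append([-1, -1])
        self.terminal.append(-1)
        return len(self.feature) - 1

    def _make_leaf(self, node: int, rows: np.ndarray) -> None:
        lt, lc = _aalen_johansen(self.time[rows], self.event[rows],
                                 presorted=True)
        self.leaf_times.append(lt)
        self.leaf_cif.append(lc)
        self.terminal[node] = len(self.leaf_times) - 1

    def _best_split(self, rows: np.ndarray):
        cfg = self.cfg
        t, e = self.time[rows], self.event[rows]
        n = len(rows)
        tau = cfg.tau if cfg.tau is not None else float(t[-1])
        if not np.any((e == cfg.cause) & (t <= tau)):
            return None
        p = self.X.shape[1]
        mtry = p if cfg.mtry is None else min(cfg.mtry, p)
        cov_order = range(p) if mtry == p else np.sort(
            self.rng.choice(p, size=mtry, replace=False))

        Xn = self.X[rows][:, cov_order] if mtry != p else self.X[rows]
        lo, hi = cfg.nodesize - 1, n - cfg.nodesize  # admissible cut positions
        if lo > hi:
            return None
        xs = np.sort(Xn, axis=0)
        # a cut at sorted position q (value xs[q]) is admissible when both
        # daughters reach nodesize and the value changes at q -> q+1
        seg = xs[lo:hi + 1]
        valid = seg[:-1] != seg[1:]                       # (hi-lo, mtry)

        if cfg.nsplit is None:
            pick_pos, pick_col = np.nonzero(valid.T)   # covariate-major order
            pick_pos, pick_col = pick_col, pick_pos
            ok = np.ones(len(pick_pos), dtype=bool)
        else:
            # nsplit random admissible cuts per covariate, without
            # replacement: smallest random keys among the valid positions
            keys = self.rng.random(valid.shape)
            keys[~valid] = np.inf
            k = min(cfg.nsplit, valid.shape[0])
            picks = np.sort(np.argpartition(keys, k - 1, axis=0)[:k], axis=0)
            pick_pos = picks.T.ravel()                 # covariate-major order
            pick_col = np.repeat(np.arange(valid.shape[1]), k)
            ok = valid[pick_pos, pick_col]
        pick_pos, pick_col = pick_pos[ok], pick_col[ok]
        if len(pick_pos) == 0:
            return None
        cand_feat = cov_order[pick_col] if mtry != p else pick_col
        cand_thr = xs[pick_pos + lo, pick_col]
        left = Xn[:, pick_col] <= cand_thr
        stat, _ = _split_stats_sorted(t, e, left.astype(float), cfg.cause, tau)
        best = int(np.argmax(np.abs(stat)))  # argmax keeps first on ties
        if abs(stat[best]) <= 0.0:
            return None
        return int(cand_feat[best]), float(cand_thr[best]), left[:, best]

    def build(self, rows: np.ndarray) -> int:
        node = self._new_node()
        if len(rows) < 2 * self.cfg.nodesize:
            self._make_leaf(node, rows)
            return node
        found = self._best_split(rows)
        if found is None:
            self._make_leaf(node, rows)
            return node
        f, s, go_left = found
        self.feature[node] = int(f)
        self.threshold[node] = s
        self.children[node][0] = self.build(rows[go_left])
        self.children[node][1] = self.build(rows[~go_left])
        return node


def grow_tree(sample: CompetingRisksSample, bootstrap_rows: np.ndarray,
              config: ForestConfig, rng: np.random.Generator) -> CRTree:
    """Grow one competing-risks tree on the given bootstrap rows."""
    if len(bootstrap_rows) == 0:
        raise ValueError("empty bootstrap sample")
    bootstrap_rows = np.asarray(bootstrap_rows)
    order = np.argsort(sample.time[bootstrap_rows], kind="stable")
    bootstrap_rows = bootstrap_rows[order]  # builder relies on sorted times
    b = _TreeBuilder(sample.time[bootstrap_rows], sample.event[bootstrap_rows],
                     sample.X[bootstrap_rows], config, rng)
    b.build(np.arange(len(bootstrap_rows)))
    return CRTree(feature=np.asarray(b.feature),
                  threshold=np.asarray(b.threshold),
                  children=np.asarray(b.children),
                  terminal=np.asarray(b.terminal),
                  leaf_times=b.leaf_times,
                  leaf_cif=b.leaf_cif,
                  bootstrap_index=np.asarray(bootstrap_rows))


def grow_forest(sample: CompetingRisksSample, config: ForestConfig) -> list[CRTree]:
    """Grow the full ensemble (bootstrap with replacement, size n, per tree)."""
    rng = np.random.default_rng(config.seed)
    n = len(sample)
    trees = []
    for _ in range(config.ntree):
        rows = rng.integers(0, n, size=n)
        trees.append(grow_tree(sample, rows, config, rng))
    return trees


def predict_cif_forest(forest: list[CRTree], X: np.ndarray,
                       times: np.ndarray, cause: int = 1) -> CifCurve:
    """Ensemble cause-``cause`` CIF: average of terminal-node curves over trees."""
    if not forest:
        raise ValueError("empty forest")
    X = np.atleast_2d(np.asarray(X, float))
    times = np.asarray(times, float)
    acc = np.zeros((X.shape[0], len(times)))
    for tree in forest:
        leaf_vals = tree.leaf_cif_on_grid(times, cause)   # (n_leaves, m)
        acc += leaf_vals[tree.apply(X)]
    return CifCurve(times, acc / len(forest))
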