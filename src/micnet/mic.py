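"""Maximal Information Coefficient (MIC) estimation.

MIC measures dependence between two real variables by gridding the scatter
plot, computing mutual information of the induced discrete distribution,
and maximizing over grid resolutions (s columns, t rows) subject to the
budget ``s * t <= floor(n ** b_exponent)``, with each grid's mutual
information normalized by ``log2(min(s, t))``. The result lies in [0, 1]:
0 for independence, 1 for any noiseless functional relationship.

Two estimation paths are provided:

* an **exhaustive** search over all grid cut placements, feasible for small
  n where the budget only admits coarse grids (used automatically for
  n <= 25);
* the standard **approximation** that equipartitions one axis and places
  the other axis's cuts by dynamic programming over x-clumps, run in both
  orientations and maximized.

Ties share grid cells: a cut can never separate equal values, so the
estimate is invariant under strictly monotone transforms of either
argument.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MICMatrix", "mic_pair", "mic_matrix"]

_EXACT_N_MAX = 25  # budget floor(25**0.6) = 6 admits only 2x2 and 2x3 grids


# ---------------------------------------------------------------------------
# pairwise estimator
# ---------------------------------------------------------------------------

def mic_pair(
    x,
    y,
    b_exponent: float = 0.6,
    method: str = "auto",
    clump_factor: int = 5,
) -> float:
    """MIC between two equal-length samples.

    Parameters
    ----------
    x, y
        Paired observations, length n >= 4.
    b_exponent
        Grid budget exponent: grids satisfy ``s*t <= floor(n**b_exponent)``
        (never below 4, so a 2x2 grid is always admissible).
    method
        ``"auto"`` (exhaustive for n <= 25, else approximate),
        ``"exact"`` or ``"approx"``.
    clump_factor
        Approximation granularity: the optimized axis is pre-coarsened to
        at most ``clump_factor * max_columns`` superclumps.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"MIC needs at least 4 samples, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("MIC input contains NaN")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("MIC of a constant variable is undefined; returning 0", stacklevel=2)
        return 0.0
    budget = max(int(np.floor(n**b_exponent)), 4)
    if method == "auto":
        method = "exact" if n <= _EXACT_N_MAX else "approx"
    if method == "exact":
        return _mic_exact(x, y, budget)
    if method == "approx":
        return max(
            _mic_one_orientation(x, y, budget, clump_factor),
            _mic_one_orientation(y, x, budget, clump_factor),
        )
    raise ValueError(f"unknown method {method!r}")


def _grid_shapes(budget: int):
    for s in range(2, budget // 2 + 1):
        for t in range(2, budget // s + 1):
            yield s, t


def _mic_exact(x: np.ndarray, y: np.ndarray, budget: int) -> float:
    """Maximize normalized grid mutual information over all cut placements."""
    xcuts = _allowed_cuts(x)
    ycuts = _allowed_cuts(y)
    best = 0.0
    for s, t in _grid_shapes(budget):
        if s - 1 > len(xcuts) or t - 1 > len(ycuts):
            continue
        denom = np.log2(min(s, t))
        for xc in itertools.combinations(xcuts, s - 1):
            col = _bin_by_cuts(x, xc)
            for yc in itertools.combinations(ycuts, t - 1):
                row = _bin_by_cuts(y, yc)
                mi = _mutual_information(col, row, s, t)
                best = max(best, mi / denom)
    return min(best, 1.0)


def _allowed_cuts(v: np.ndarray) -> list[float]:
    """Midpoints between consecutive distinct sorted values (ties unsplittable)."""
    u = np.unique(v)
    return list((u[:-1] + u[1:]) / 2.0)


def _bin_by_cuts(v: np.ndarray, cuts) -> np.ndarray:
    return np.searchsorted(np.asarray(cuts), v)


def _mutual_information(col: np.ndarray, row: np.ndarray, s: int, t: int) -> float:
    joint = np.zeros((s, t))
    np.add.at(joint, (col, row), 1.0)
    joint /= joint.sum()
    pc = joint.sum(axis=1, keepdims=True)
    pr = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pc * pr))
    return float(np.nansum(terms))


# -- approximation: equipartition rows, DP-optimize columns -----------------

def _mic_one_orientation(
    x: np.ndarray, y: np.ndarray, budget: int, clump_factor: int
) -> float:
    best = 0.0
    max_t = budget // 2
    for t in range(2, max_t + 1):
        rows = _equipartition(y, t)
        t_eff = len(np.unique(rows))
        if t_eff < 2:
            continue
        max_s = budget // t
        if max_s < 2:
            break
        cum = _clump_cumulants(x, rows, t, max_s, clump_factor)
        k = cum.shape[0] - 1
        if k < 2:
            continue
        # H of the full row distribution (log2)
        p_full = cum[-1] / cum[-1].sum()
        h_rows = -np.sum(p_full[p_full > 0] * np.log2(p_full[p_full > 0]))
        cond = _dp_min_conditional_entropy(cum, min(max_s, k))
        for s in range(2, min(max_s, k) + 1):
            mi = h_rows - cond[s]
            best = max(best, mi / np.log2(min(s, t_eff)))
    return min(best, 1.0)


def _equipartition(v: np.ndarray, t: int) -> np.ndarray:
    """Greedy near-equal-count row assignment that never splits ties."""
    n = v.size
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    assign = np.empty(n, dtype=np.int64)
    row, filled, placed = 0, 0, 0
    i = 0
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        size = j - i
        rows_left = t - row
        if filled > 0 and rows_left > 1:
            desired = (n - placed + filled) / rows_left
            if abs(filled + size - desired) >= abs(filled - desired):
                row += 1
                filled = 0
        assign[order[i:j]] = row
        filled += size
        placed = j
        i = j
    return assign


def _clump_cumulants(
    x: np.ndarray, rows: np.ndarray, t: int, max_s: int, clump_factor: int
) -> np.ndarray:
    """Cumulative row counts at clump boundaries along the x ordering.

    Points with equal x form one clump; adjacent clumps confined to the
    same single row are merged (lossless for the conditional entropy
    objective). If more clumps remain than ``clump_factor * max_s``, they
    are coarsened into near-equal-count superclumps.
    """
    n = x.size
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    srow = rows[order]
    new_x = np.empty(n, dtype=bool)
    new_x[0] = True
    new_x[1:] = sx[1:] != sx[:-1]
    clump_id = np.cumsum(new_x) - 1
    k = clump_id[-1] + 1
    counts = np.zeros((k, t))
    np.add.at(counts, (clump_id, srow), 1.0)
    counts = _merge_pure_runs(counts)
    cap = max(clump_factor * max_s, 2)
    if counts.shape[0] > cap:
        counts = _superclumps(counts, cap)
    return np.vstack([np.zeros((1, t)), np.cumsum(counts, axis=0)])


def _merge_pure_runs(counts: np.ndarray) -> np.ndarray:
    """Merge adjacent clumps confined to the same single row (lossless)."""
    single = (counts > 0).sum(axis=1) == 1
    row_of = np.where(single, np.argmax(counts, axis=1), -1)
    merged: list[np.ndarray] = []
    last_row = -2
    for i in range(counts.shape[0]):
        if merged and row_of[i] >= 0 and row_of[i] == last_row:
            merged[-1] = merged[-1] + counts[i]
        else:
            merged.append(counts[i].copy())
            last_row = row_of[i] if row_of[i] >= 0 else -2
    return np.array(merged)


def _superclumps(counts: np.ndarray, cap: int) -> np.ndarray:
    """Coarsen to at most ``cap`` contiguous near-equal-mass groups."""
    sizes = counts.sum(axis=1)
    cum = np.cumsum(sizes)
    mid = cum - sizes / 2.0
    grp = np.minimum((mid * cap / cum[-1]).astype(int), cap - 1)
    grp = np.maximum.accumulate(grp)
    out = np.zeros((int(grp[-1]) + 1, counts.shape[1]))
    np.add.at(out, grp, counts)
    return out


def _dp_min_conditional_entropy(cum: np.ndarray, max_s: int) -> dict[int, float]:
    """Minimal weighted conditional row entropy over column partitions.

    ``cum`` holds cumulative row counts at the k+1 clump boundaries. For
    each column count s, returns min over partitions of the clumps into s
    contiguous columns of ``sum_c (n_c / n) * H(rows | column c)`` in bits.
    Mutual information then follows as ``H(rows) - result``.
    """
    k = cum.shape[0] - 1
    n = cum[-1].sum()
    # w[j, m] = weighted entropy of clump range (j, m], j < m
    diff = cum[None, :, :] - cum[:, None, :]  # (k+1, k+1, t)
    sz = diff.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = diff / sz[:, :, None]
        ent = -np.nansum(np.where(diff > 0, frac * np.log2(frac), 0.0), axis=2)
    w = np.where(sz > 0, sz / n * ent, np.inf)
    np.fill_diagonal(w, np.inf)
    g_prev = w[0, :].copy()  # one column covering (0, m]
    out: dict[int, float] = {}
    for s in range(2, max_s + 1):
        cand = g_prev[:, None] + w  # split at j: G[s-1, j] + w[j, m]
        g = np.min(cand, axis=0)
        g[: s] = np.inf  # need at least s clumps for s non-empty columns
        out[s] = float(g[k]) if np.isfinite(g[k]) else np.inf
        g_prev = g
    return out


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class MICMatrix:
    """Pairwise MIC values between two feature sets."""

    row_features: list[str]
    col_features: list[str]
    values: np.ndarray
    n_samples: int
    symmetric: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_features), len(self.col_features)):
            raise ValueError("MIC matrix shape does not match feature lists")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("MIC values must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_features, columns=self.col_features)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="feature")

    @classmethod
    def from_csv(cls, path, n_samples: int = 0) -> "MICMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        rows = [str(i) for i in df.index]
        cols = [str(c) for c in df.columns]
        return cls(rows, cols, df.to_numpy(dtype=float), n_samples, symmetric=rows == cols)


def mic_matrix(a, b=None, b_exponent: float = 0.6, method: str = "auto") -> MICMatrix:
    """All-pairs MIC within one expression matrix or across two layers.

    With a single matrix the result is square and symmetric over its
    features (diagonal 1 for non-constant features). With two matrices the
    result is rectangular; both must already be sample-aligned (same
    patients, same order) — see ``align_samples``.
    """
    if a.n_features < 2 and b is None:
        raise ValueError("need at least 2 features for a MIC matrix")
    if b is None:
        p = a.n_features
        vals = np.zeros((p, p))
        cols = a.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(p):
                vals[i, i] = mic_pair(cols[:, i], cols[:, i], b_exponent, method) if np.ptp(cols[:, i]) > 0 else 0.0
                for j in range(i + 1, p):
                    v = mic_pair(cols[:, i], cols[:, j], b_exponent, method)
                    vals[i, j] = vals[j, i] = v
        return MICMatrix(list(a.feature_ids), list(a.feature_ids), vals, a.n_samples, True)
    _check_aligned(a, b)
    vals = np.zeros((a.n_features, b.n_features))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(a.n_features):
            for j in range(b.n_features):
                vals[i, j] = mic_pair(a.values[:, i], b.values[:, j], b_exponent, method)
    return MICMatrix(list(a.feature_ids), list(b.feature_ids), vals, a.n_samples, False)


def _check_aligned(a, b) -> None:
    from .io import barcode_patient

    if a.n_samples != b.n_samples:
        raise ValueError(
            "cross-layer MIC requires sample-aligned matrices; run align_samples first"
        )
    pa = [barcode_patient(s) for s in a.sample_ids]
    pb = [barcode_patient(s) for s in b.sample_ids]
    if pa != pb:
        raise ValueError(
            "sample order differs between layers; run align_samples first"
        )
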