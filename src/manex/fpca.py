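"""Functional representation of excursion curves and multivariate fPCA.

Each subject contributes four excursion trajectories (2 networks x 2 days).
The pipeline here is:

1. ``smooth_curve`` — cubic smoothing spline with a knot at every
   observation and the roughness penalty lambda chosen by generalized
   cross-validation, GCV(lambda) = n RSS / (n - tr S_lambda)^2.  The
   classical natural-spline (Reinsch) form is used, with a single
   Demmler-Reinsch eigendecomposition per grid shared across curves.
2. ``mfpca`` — multivariate functional PCA: an eigen-decomposition of the
   covariance operator over the 4-tuples of curves, computed as weighted
   PCA on the concatenated grid-discretized smoothed curves with
   trapezoid quadrature weights.
3. ``kruskal_wallis`` / ``conover_iman`` — rank-based group comparison of
   component scores with Benjamini-Hochberg adjustment of the pairwise
   post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FunctionalCurve",
    "SplineSmoother",
    "smooth_curve",
    "MfpcaResult",
    "mfpca",
    "kruskal_wallis",
    "conover_iman",
]

#: default GCV search grid for the smoothing penalty
DEFAULT_LAMBDAS = np.logspace(-6.0, 9.0, 76)


@dataclass
class FunctionalCurve:
    """A smoothed curve: values on its grid plus a natural-spline form."""

    grid: np.ndarray
    values: np.ndarray  # smoothed values at the grid
    gcv_lambda: float
    spline: CubicSpline = field(repr=False, default=None)

    @property
    def coefficients(self) -> np.ndarray:
        return self.spline.c

    def __call__(self, t):
        return self.spline(t)


def _reinsch_penalty(x: np.ndarray) -> np.ndarray:
    """K = Delta^T W^{-1} Delta for the natural cubic smoothing spline.

    Green & Silverman band matrices: Delta is the (n-2) x n second-divided-
    difference operator; W the tridiagonal Gram matrix of the natural-spline
    second derivatives.  Penalty: integral of the squared second derivative.
    """
    n = len(x)
    h = np.diff(x)
    delta = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    delta[idx, idx] = 1.0 / h[:-1]
    delta[idx, idx + 1] = -(1.0 / h[:-1] + 1.0 / h[1:])
    delta[idx, idx + 2] = 1.0 / h[1:]
    w = np.zeros((n - 2, n - 2))
    w[idx, idx] = (h[:-1] + h[1:]) / 3.0
    off = (h[1:-1] / 6.0)
    w[idx[:-1], idx[:-1] + 1] = off
    w[idx[:-1] + 1, idx[:-1]] = off
    return delta.T @ np.linalg.solve(w, delta)


class SplineSmoother:
    """Shared-grid cubic smoothing spline with GCV penalty selection.

    The Demmler-Reinsch eigendecomposition of the penalty is computed once
    per grid, so smoothing many curves on the same grid costs one
    eigendecomposition plus a matrix-vector product per curve.
    """

    def __init__(self, grid: np.ndarray, lambdas: np.ndarray | None = None):
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 10:
            raise ValueError("need a 1-D grid with at least 10 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        self.grid = grid
        self.lambdas = (
            np.asarray(lambdas, float) if lambdas is not None else DEFAULT_LAMBDAS
        )
        k = _reinsch_penalty(grid)
        # K is symmetric PSD with a 2-D null space (straight lines)
        evals, evecs = np.linalg.eigh(0.5 * (k + k.T))
        evals = np.clip(evals, 0.0, None)
        # the penalty null space (straight lines) must stay exactly
        # penalty-free even at huge lambda
        evals[evals < 1e-12 * evals.max()] = 0.0
        self._evals = evals
        self._evecs = evecs

    def fit(self, y: np.ndarray, lam: float | None = None) -> FunctionalCurve:
        """Smooth one curve; ``lam=None`` selects the penalty by GCV."""
        y = np.asarray(y, dtype=float)
        n = len(self.grid)
        if y.shape != (n,):
            raise ValueError(f"samples must have length {n}")
        ytil = self._evecs.T @ y
        if lam is None:
            if np.ptp(y) == 0:
                lam = float(self.lambdas[-1])  # constant curve: any penalty fits
            else:
                lam = float(self.lambdas[int(np.argmin(self._gcv(ytil)))])
        shrink = 1.0 / (1.0 + lam * self._evals)
        fitted = self._evecs @ (shrink * ytil)
        spline = CubicSpline(self.grid, fitted, bc_type="natural")
        return FunctionalCurve(
            grid=self.grid, values=fitted, gcv_lambda=lam, spline=spline
        )

    def _gcv(self, ytil: np.ndarray) -> np.ndarray:
        n = len(ytil)
        lams = self.lambdas[:, None]
        resid_coef = (lams * self._evals) / (1.0 + lams * self._evals)
        rss = np.sum((resid_coef * ytil) ** 2, axis=1)
        tr = np.sum(1.0 / (1.0 + lams * self._evals), axis=1)
        return n * rss / (n - tr) ** 2


def smooth_curve(
    samples: np.ndarray,
    grid: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
) -> FunctionalCurve:
    """GCV-penalized cubic smoothing spline of one sampled curve."""
    samples = np.asarray(samples, dtype=float)
    if grid is None:
        grid = np.arange(len(samples), dtype=float)
    return SplineSmoother(grid, lambdas=lambdas).fit(samples)


@dataclass
class MfpcaResult:
    mean_functions: list  # per element: mean curve on the grid
    components: np.ndarray  # (K, n_elements, G) eigenfunctions
    scores: np.ndarray  # (n_subjects, K)
    var_explained: np.ndarray  # (K,) fraction of total variance
    grid: np.ndarray
    weights: np.ndarray  # quadrature weights on the grid


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def mfpca(curves, K: int = 3, grid: np.ndarray | None = None) -> MfpcaResult:
    """Multivariate functional PCA of per-subject tuples of curves.

    ``curves``: list over subjects of same-length lists of
    ``FunctionalCurve`` (or plain value arrays on a common grid).  The
    multivariate inner product is the unweighted sum over elements of the
    L2 inner products on the grid; components have unit norm under it and
    scores are the centered inner products, zero-mean per component.
    """
    n = len(curves)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    n_el = len(curves[0])
    if any(len(c) != n_el for c in curves):
        raise ValueError("all subjects must contribute the same elements")
    vals = []
    for subj in curves:
        row = []
        for el in subj:
            v = el.values if isinstance(el, FunctionalCurve) else np.asarray(el, float)
            row.append(v)
        vals.append(row)
    g = len(vals[0][0])
    if any(len(v) != g for row in vals for v in row):
        raise ValueError("all curves must share a common grid length")
    if grid is None:
        el0 = curves[0][0]
        grid = (
            el0.grid if isinstance(el0, FunctionalCurve) else np.arange(g, dtype=float)
        )
    if K > n - 1:
        raise ValueError(f"K={K} exceeds subjects-1={n - 1}")
    w = _trapezoid_weights(np.asarray(grid, float))
    sw = np.sqrt(w)
    x = np.stack([np.concatenate(row) for row in vals])  # (n, n_el*g)
    mean = x.mean(axis=0)
    xc = (x - mean) * np.tile(sw, n_el)
    scale = max(1.0, np.abs(x).max())
    if np.ptp(x, axis=0).max() <= 1e-12 * scale:
        raise ValueError("all subjects identical: variance undefined")
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    evals = svals**2 / (n - 1)
    comps_w = vt[:K]  # rows unit-norm in weighted space
    scores = xc @ comps_w.T
    # back to function space: divide out the sqrt quadrature weights
    comps = comps_w / np.tile(sw, n_el)
    comps = comps.reshape(K, n_el, g)
    # sign convention: the largest-|loading| point of each component positive
    for k in range(K):
        flat = comps[k].ravel()
        if flat[np.argmax(np.abs(flat))] < 0:
            comps[k] *= -1
            scores[:, k] *= -1
    return MfpcaResult(
        mean_functions=[mean.reshape(n_el, g)[e] for e in range(n_el)],
        components=comps,
        scores=scores,
        var_explained=evals[:K] / evals.sum(),
        grid=np.asarray(grid, float),
        weights=w,
    )


def kruskal_wallis(scores: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; (H, p) from chi-square g-1 df.

    All-tied samples (H a 0/0) return (0, 1) by convention.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labs = pd.unique(groups)
    if len(labs) < 2:
        raise ValueError("need at least 2 groups")
    samples = [scores[groups == g] for g in labs]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.ptp(scores) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def conover_iman(scores: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Conover-Iman pairwise post hoc tests on ranks, BH-adjusted.

    t-type statistics: t_ab = (Rbar_a - Rbar_b) / sqrt(S^2 (N-1-H)/(N-g)
    (1/n_a + 1/n_b)) with S^2 the pooled variance of the (tie-averaged)
    ranks; two-sided p from Student t with N-g df; Benjamini-Hochberg
    step-up across the pairs.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labs = list(pd.unique(groups))
    if len(labs) < 2:
        raise ValueError("need at least 2 groups")
    h, _ = kruskal_wallis(scores, groups)
    r = stats.rankdata(scores)
    n = len(scores)
    g = len(labs)
    s2 = (np.sum(r**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1 - h) / (n - g)
    rows = []
    for a, b in combinations(labs, 2):
        ra, rb = r[groups == a], r[groups == b]
        denom2 = scale * (1.0 / len(ra) + 1.0 / len(rb))
        if denom2 <= 0:
            t, p = 0.0, 1.0
        else:
            t = (ra.mean() - rb.mean()) / np.sqrt(denom2)
            p = 2.0 * stats.t.sf(abs(t), df=n - g)
        rows.append({"group_a": a, "group_b": b, "statistic": t, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
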