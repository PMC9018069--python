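"""Resting-state manifold estimation and off-manifold excursion.

The dominant covariance structure of resting BOLD activity in a network of
ROIs defines a low-dimensional affine subspace (the "intrinsic manifold"):
the span of the leading principal components through the resting mean.  At
each task volume the activation vector splits into an on-manifold part
(its projection onto the subspace) and an off-manifold residual; the
excursion r_t is the fraction of the activation norm lying off-manifold,

    r_t = ||(I - V V^T)(x_t - mu)|| / ||x_t - mu||,   r_t in [0, 1],

with V the orthonormal PCA basis and mu the resting mean.  Excursion
curves are standardized to the pre-rotation baseline so that post-onset
values read as departures in baseline-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Manifold",
    "ExcursionCurve",
    "fit_manifold",
    "excursion_series",
    "standardize_to_baseline",
    "early_excursion",
]


@dataclass
class Manifold:
    """Orthonormal basis and center of a resting-state subspace."""

    basis: np.ndarray  # (n_rois, d), orthonormal columns
    center: np.ndarray  # (n_rois,)
    d: int
    var_explained: float  # cumulative fraction at d components
    eigenvalues: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        g = self.basis.T @ self.basis
        if np.abs(g - np.eye(self.d)).max() > 1e-10:
            raise ValueError("basis columns are not orthonormal")


@dataclass
class ExcursionCurve:
    """Per-volume excursion of a task scan relative to a resting manifold."""

    values: np.ndarray  # raw r_t in [0, 1]
    standardized_values: np.ndarray | None = None
    network: str | None = None
    day: int | None = None
    baseline_window: tuple[int, int] | None = None  # half-open volume range
    rotation_onset: int | None = None
    degenerate: np.ndarray | None = None  # volumes with near-zero norm


def fit_manifold(rest: np.ndarray, var_threshold: float = 0.75) -> Manifold:
    """PCA manifold of a resting scan (volumes x ROIs).

    Retains the smallest number of components whose cumulative explained
    variance reaches ``var_threshold`` (default 0.75, i.e. 75%).
    """
    rest = np.asarray(rest, dtype=float)
    if rest.ndim != 2:
        raise ValueError("rest must be 2-D (volumes x ROIs)")
    if not 0 < var_threshold < 1:
        raise ValueError("var_threshold must be in (0, 1)")
    sd = rest.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"ROI {idx} has zero variance in the resting scan")
    center = rest.mean(axis=0)
    xc = rest - center
    # SVD of the centered data; eigenvalues of the covariance up to 1/(n-1)
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    evals = svals**2 / (rest.shape[0] - 1)
    frac = np.cumsum(evals) / evals.sum()
    d = int(np.searchsorted(frac, var_threshold) + 1)
    d = min(d, len(evals))
    return Manifold(
        basis=vt[:d].T.copy(),
        center=center,
        d=d,
        var_explained=float(frac[d - 1]),
        eigenvalues=evals,
    )


def excursion_series(
    m: Manifold,
    task: np.ndarray,
    centering: str = "rest-mean",
    norm_tol: float = 1e-12,
    **meta,
) -> ExcursionCurve:
    """Excursion r_t of every task volume from the resting manifold.

    ``centering`` controls the origin subtracted from each task volume
    before projection: ``"rest-mean"`` (the manifold center; default),
    ``"task-mean"``, or ``"none"``.  Volumes with vector norm below
    ``norm_tol`` get r_t = 0 and are flagged in ``degenerate``.
    """
    task = np.asarray(task, dtype=float)
    if task.ndim != 2 or task.shape[1] != m.basis.shape[0]:
        raise ValueError(
            f"task has {task.shape[1] if task.ndim == 2 else '?'} ROIs, "
            f"manifold expects {m.basis.shape[0]}"
        )
    if np.isnan(task).any():
        raise ValueError("NaN in task data")
    if centering == "rest-mean":
        xc = task - m.center
    elif centering == "task-mean":
        xc = task - task.mean(axis=0)
    elif centering == "none":
        xc = task
    else:
        raise ValueError(f"unknown centering {centering!r}")
    on = xc @ m.basis  # coordinates in the basis
    off = xc - on @ m.basis.T
    norm_all = np.linalg.norm(xc, axis=1)
    norm_off = np.linalg.norm(off, axis=1)
    degenerate = norm_all < norm_tol
    r = np.zeros(len(xc))
    ok = ~degenerate
    r[ok] = norm_off[ok] / norm_all[ok]
    # projection can only shrink a vector; clip rounding overshoot
    np.clip(r, 0.0, 1.0, out=r)
    return ExcursionCurve(values=r, degenerate=degenerate, **meta)


def standardize_to_baseline(
    c: ExcursionCurve, baseline_window: tuple[int, int] | None = None
) -> ExcursionCurve:
    """Z-score an excursion curve by its pre-rotation baseline mean and SD.

    SD uses the n-1 denominator.  Raises on an empty window or zero SD.
    """
    window = baseline_window if baseline_window is not None else c.baseline_window
    if window is None:
        raise ValueError("no baseline window specified")
    lo, hi = window
    base = c.values[lo:hi]
    if len(base) < 2:
        raise ValueError("baseline window must contain at least 2 volumes")
    mu = base.mean()
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline SD is zero; cannot standardize")
    return ExcursionCurve(
        values=c.values,
        standardized_values=(c.values - mu) / sd,
        network=c.network,
        day=c.day,
        baseline_window=window,
        rotation_onset=c.rotation_onset,
        degenerate=c.degenerate,
    )


def early_excursion(
    c: ExcursionCurve,
    trials_per_block: int = 8,
    n_blocks: int = 4,
    volumes_per_trial: int = 2,
) -> float:
    """Mean standardized excursion over the first post-onset blocks.

    The window covers the first ``n_blocks`` blocks of ``trials_per_block``
    trials after rotation onset (defaults: 4 blocks x 8 trials x 2
    volumes/trial = 64 volumes), mirroring the behavioral early-error
    window.
    """
    if c.rotation_onset is None:
        raise ValueError("rotation_onset not set on the curve")
    if c.standardized_values is None:
        raise ValueError("curve must be standardized first")
    n = trials_per_block * n_blocks * volumes_per_trial
    lo = c.rotation_onset
    hi = lo + n
    if hi > len(c.standardized_values):
        raise ValueError("early-excursion window exceeds the scan length")
    return float(c.standardized_values[lo:hi].mean())
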