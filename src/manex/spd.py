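"""Affine-invariant geometry on symmetric positive-definite (SPD) matrices.

Covariance matrices of multichannel signals live on the SPD manifold, where
the affine-invariant Riemannian metric gives a natural notion of distance,
mean, and "difference" (a tangent vector) that respects positive
definiteness.  This module provides the primitives used to center each
subject's task covariance matrices at a grand-mean resting covariance:

* ``log_map`` / ``exp_map`` — matrix log/exp charts at a reference point,
* ``transport`` — parallel transport of tangent vectors between references,
* ``geodesic_distance`` — the affine-invariant metric,
* ``frechet_mean`` — the Karcher/Fréchet mean by fixed-point iteration,
* ``center_to_grand_mean`` — the full log → transport → exp centering chain,
* ``shrinkage_covariance`` — well-conditioned covariance estimation.

All functions operate on plain ``numpy`` arrays; symmetry is enforced on
output, positive definiteness is validated on input (a loud error, never a
silent eigenvalue clip).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = [
    "check_spd",
    "shrinkage_covariance",
    "log_map",
    "exp_map",
    "transport",
    "geodesic_distance",
    "frechet_mean",
    "center_to_grand_mean",
]

#: eigenvalues below this are treated as a violation of positive definiteness
EIG_FLOOR = 1e-12
SYM_TOL = 1e-10


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def check_spd(s: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that ``s`` is symmetric positive definite.

    Returns the symmetrized matrix; raises ``ValueError`` with the offending
    property otherwise.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"{name} must be square, got shape {s.shape}")
    asym = np.abs(s - s.T).max() if s.size else 0.0
    if asym > SYM_TOL * max(1.0, np.abs(s).max()):
        raise ValueError(f"{name} is not symmetric (max asymmetry {asym:.3g})")
    s = _symmetrize(s)
    w = np.linalg.eigvalsh(s)
    if w.min() <= EIG_FLOOR:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {w.min():.3g})"
        )
    return s


def _check_symmetric(t: np.ndarray, name: str = "tangent vector") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"{name} must be square, got shape {t.shape}")
    asym = np.abs(t - t.T).max() if t.size else 0.0
    if asym > SYM_TOL * max(1.0, np.abs(t).max()):
        raise ValueError(f"{name} is not symmetric (max asymmetry {asym:.3g})")
    return _symmetrize(t)


def _eig_fun(s: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, v = np.linalg.eigh(_symmetrize(s))
    return _symmetrize((v * fun(w)) @ v.T)


def _powm(s: np.ndarray, p: float) -> np.ndarray:
    return _eig_fun(s, lambda w: np.power(w, p))


def _logm(s: np.ndarray) -> np.ndarray:
    return _eig_fun(s, np.log)


def _expm(s: np.ndarray) -> np.ndarray:
    return _eig_fun(s, np.exp)


def shrinkage_covariance(ts: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance of a (volumes x channels) array.

    Linear shrinkage of the sample covariance toward a scaled identity with
    the data-driven intensity of Ledoit & Wolf; the result is SPD even when
    there are fewer observations than channels.  Raises on constant columns
    (zero-variance channels make the estimate degenerate).
    """
    from sklearn.covariance import LedoitWolf

    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 observations")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"column {idx} is constant; covariance is degenerate")
    est = LedoitWolf(assume_centered=False).fit(ts)
    return check_spd(est.covariance_, "shrinkage covariance")


def log_map(ref: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Project an SPD matrix onto the tangent space at ``ref``.

    T = ref^{1/2} logm(ref^{-1/2} S ref^{-1/2}) ref^{1/2}.  The result is a
    symmetric matrix encoding the covariance difference S - ref in the
    affine-invariant geometry (T = 0 iff S = ref).
    """
    ref = check_spd(ref, "reference")
    s = check_spd(s, "input")
    if ref.shape != s.shape:
        raise ValueError("dimension mismatch between reference and input")
    rh = _powm(ref, 0.5)
    rih = _powm(ref, -0.5)
    return _symmetrize(rh @ _logm(rih @ s @ rih) @ rh)


def exp_map(ref: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Map a tangent vector at ``ref`` back to the SPD manifold.

    S = ref^{1/2} expm(ref^{-1/2} T ref^{-1/2}) ref^{1/2}; inverse of
    ``log_map`` at the same reference.
    """
    ref = check_spd(ref, "reference")
    t = _check_symmetric(t)
    if ref.shape != t.shape:
        raise ValueError("dimension mismatch between reference and tangent")
    rh = _powm(ref, 0.5)
    rih = _powm(ref, -0.5)
    return _symmetrize(rh @ _expm(rih @ t @ rih) @ rh)


def transport(from_ref: np.ndarray, to_ref: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Parallel-transport a tangent vector between reference points.

    T' = G T G^T with G = to_ref^{1/2} from_ref^{-1/2}.  Transport is an
    isometry of the affine-invariant metric: the tangent norm at the
    destination equals the norm at the origin.
    """
    from_ref = check_spd(from_ref, "from_ref")
    to_ref = check_spd(to_ref, "to_ref")
    t = _check_symmetric(t)
    if not (from_ref.shape == to_ref.shape == t.shape):
        raise ValueError("dimension mismatch in transport")
    g = _powm(to_ref, 0.5) @ _powm(from_ref, -0.5)
    return _symmetrize(g @ t @ g.T)


def geodesic_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Affine-invariant geodesic distance ||logm(S1^{-1/2} S2 S1^{-1/2})||_F."""
    s1 = check_spd(s1, "s1")
    s2 = check_spd(s2, "s2")
    if s1.shape != s2.shape:
        raise ValueError("dimension mismatch")
    rih = _powm(s1, -0.5)
    # eigenvalues of S1^{-1} S2 are those of the whitened product
    w = np.linalg.eigvalsh(_symmetrize(rih @ s2 @ rih))
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def frechet_mean(
    mats: list[np.ndarray] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Fréchet (Karcher) mean of a set of SPD matrices.

    Fixed-point iteration: M <- M^{1/2} expm(mean_i logm(M^{-1/2} R_i
    M^{-1/2})) M^{1/2}, initialized at the arithmetic mean, until the mean
    log has Frobenius norm below ``tol``.  For 1x1 inputs this is the
    geometric mean of the scalars.
    """
    mats = [check_spd(m, f"matrix {i}") for i, m in enumerate(mats)]
    if not mats:
        raise ValueError("empty set")
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("matrices must share a common dimension")
    if len(mats) == 1:
        return mats[0]
    m = _symmetrize(np.mean(mats, axis=0))
    for _ in range(max_iter):
        mh = _powm(m, 0.5)
        mih = _powm(m, -0.5)
        mean_log = np.mean([_logm(mih @ r @ mih) for r in mats], axis=0)
        m = _symmetrize(mh @ _expm(mean_log) @ mh)
        if np.linalg.norm(mean_log, "fro") < tol:
            return m
    raise RuntimeError(f"Fréchet mean did not converge in {max_iter} iterations")


def center_to_grand_mean(
    rest: np.ndarray,
    tasks: list[np.ndarray],
    grand: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Center a subject's task covariances at the grand-mean rest covariance.

    For each task matrix S: T = log_map(rest, S); T_c = transport(rest,
    grand, T); S_c = exp_map(grand, T_c).  Removes the static subject
    difference (the subject's own rest maps exactly to the grand mean) while
    preserving the task-vs-rest covariance change.

    Returns ``(centered_tangents, centered_matrices)``.
    """
    rest = check_spd(rest, "rest")
    grand = check_spd(grand, "grand mean")
    tangents, centered = [], []
    for s in tasks:
        t = log_map(rest, s)
        tc = transport(rest, grand, t)
        tangents.append(tc)
        centered.append(exp_map(grand, tc))
    return tangents, centered
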