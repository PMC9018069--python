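"""Behavioral preprocessing, learning summary measures, and learner clustering.

Trial tables come from a visuomotor-rotation task: subjects aim at targets
while the cursor is rotated 45 deg, and the signed angular error between
target and final cursor position tracks adaptation.  This module

* filters implausible reaction times and interpolates error outliers using
  a per-epoch cubic-spline detrend,
* computes the per-subject summary features — early error on each day
  (circular mean over the first 4 eight-trial rotation blocks) and savings
  (day-1 minus day-2 early error),
* clusters learners with complete-linkage agglomeration on the Manhattan
  distance between standardized features, and
* evaluates a cluster count against a parametric multivariate-normal null
  by bootstrap of the within/total sum-of-squares ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import LSQUnivariateSpline

__all__ = [
    "preprocess_trials",
    "circular_mean_deg",
    "early_error",
    "compute_features",
    "cluster_learners",
    "ss_ratio",
    "bootstrap_cluster_validity",
    "ClusterSolution",
    "RT_MAX_S",
    "RT_MIN_S",
    "EARLY_TRIALS",
]

RT_MAX_S = 2.0
RT_MIN_S = 0.1
#: early error = circular mean over the first 4 blocks of 8 learning trials
EARLY_TRIALS = 32
TRIALS_PER_KNOT = 40
OUTLIER_SD = 3.0


def _wrap_deg(a):
    """Map angles in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out


def preprocess_trials(raw: pd.DataFrame) -> pd.DataFrame:
    """Clean a trial table: RT filter, spline detrend, outlier interpolation.

    Expects columns ``trial, block, day, epoch, error_deg, rt_s``.  Trials
    with rt > 2 s or < 100 ms are flagged invalid (discarded from analysis).
    Within each (day, epoch) run, a cubic least-squares B-spline with one
    interior knot per 40 trials is fit to the valid errors; trials whose
    residual exceeds 3 residual-SDs are replaced by the spline value and
    flagged ``interpolated``.  Runs with fewer than 4 valid trials pass
    through undetrended with a warning.
    """
    df = raw.copy()
    for col in ("trial", "day", "epoch", "error_deg", "rt_s"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df["valid"] = (df["rt_s"] <= RT_MAX_S) & (df["rt_s"] >= RT_MIN_S)
    df["interpolated"] = False
    for (_, _), idx in df.groupby(["day", "epoch"], sort=False).groups.items():
        sub = df.loc[idx]
        ok = sub.index[sub["valid"]]
        n = len(ok)
        if n < 4:
            warnings.warn(
                f"run with {n} valid trials: too few for spline detrend; "
                "passed through unchanged",
                stacklevel=2,
            )
            continue
        x = sub.loc[ok, "trial"].to_numpy(dtype=float)
        y = sub.loc[ok, "error_deg"].to_numpy(dtype=float)
        fitted = _spline_trend(x, y)
        resid = y - fitted
        sd = resid.std(ddof=1)
        # floor guards against flagging numerical noise on flat blocks
        if sd <= 1e-8 * max(1.0, np.abs(y).max()):
            continue
        outlier = np.abs(resid) > OUTLIER_SD * sd
        if outlier.any():
            out_idx = ok[outlier]
            df.loc[out_idx, "error_deg"] = fitted[outlier]
            df.loc[out_idx, "interpolated"] = True
    return df


def _spline_trend(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic LSQ B-spline with ceil(n/40) evenly spaced interior knots."""
    n = len(x)
    n_knots = int(np.ceil(n / TRIALS_PER_KNOT))
    # interior knots strictly inside the data range, evenly spaced
    t = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
    # guard: LSQ spline needs Schoenberg-Whitney; evenly spaced trials satisfy it
    spl = LSQUnivariateSpline(x, y, t, k=3)
    return spl(x)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, mapped to (-180, 180]."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-15:
        raise ValueError("circular mean undefined (resultant length ~ 0)")
    return float(_wrap_deg(np.rad2deg(np.arctan2(s, c))))


def early_error(trials: pd.DataFrame, day: int) -> float:
    """Circular mean error over the first 32 learning trials of a day."""
    sub = trials[(trials["day"] == day) & (trials["epoch"] == "learning")]
    sub = sub.sort_values("trial").head(EARLY_TRIALS)
    if len(sub) < EARLY_TRIALS:
        raise ValueError(f"day {day}: fewer than {EARLY_TRIALS} learning trials")
    if "valid" in sub.columns:
        sub = sub[sub["valid"]]
    if len(sub) == 0:
        raise ValueError(f"day {day}: all early learning trials invalid")
    return circular_mean_deg(sub["error_deg"].to_numpy())


def compute_features(trials_by_subject: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subject learning features and their standardized copies.

    Features: ``early_error_day1``, ``early_error_day2`` and ``savings``
    (= day1 - day2).  Standardization (columns ``z_*``) is per feature
    across subjects with the n-1 SD denominator.
    """
    if len(trials_by_subject) < 2:
        raise ValueError("need at least 2 subjects to standardize features")
    rows = {}
    for subj, df in trials_by_subject.items():
        e1 = early_error(df, day=1)
        e2 = early_error(df, day=2)
        rows[subj] = dict(
            early_error_day1=e1, early_error_day2=e2, savings=e1 - e2
        )
    feats = pd.DataFrame.from_dict(rows, orient="index")
    for col in feats.columns:
        sd = feats[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"feature {col!r} has zero SD; cannot standardize")
        feats[f"z_{col}"] = (feats[col] - feats[col].mean()) / sd
    return feats


_Z_COLS = ["z_early_error_day1", "z_early_error_day2", "z_savings"]


@dataclass
class ClusterSolution:
    labels: np.ndarray  # per-subject cluster id in 1..k
    k: int
    linkage: str
    ss_ratio_observed: float
    subjects: list | None = None


def _z_matrix(features: pd.DataFrame) -> np.ndarray:
    cols = [c for c in _Z_COLS if c in features.columns]
    if not cols:  # standardized columns absent: accept raw numeric matrix
        return features.to_numpy(dtype=float)
    return features[cols].to_numpy(dtype=float)


def cluster_learners(features: pd.DataFrame, k: int) -> ClusterSolution:
    """Complete-linkage clustering on Manhattan distance, tree cut at k."""
    x = _z_matrix(features)
    n = len(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects n={n}")
    z = linkage(x, method="complete", metric="cityblock")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterSolution(
        labels=labels,
        k=k,
        linkage="complete/manhattan",
        ss_ratio_observed=ss_ratio(x, labels),
        subjects=list(features.index),
    )


def ss_ratio(x: np.ndarray, labels: np.ndarray) -> float:
    """Ratio of within-cluster to total sums of squares (0 if total is 0)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    total = np.sum((x - x.mean(axis=0)) ** 2)
    if total == 0:
        return 0.0
    within = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        within += np.sum((grp - grp.mean(axis=0)) ** 2)
    return float(within / total)


def bootstrap_cluster_validity(
    features: pd.DataFrame,
    k_range: range | tuple = range(2, 9),
    n_boot: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed vs parametric-null within/total SS ratio per cluster count.

    The null draws ``n_boot`` samples of n subjects from a single
    multivariate normal with the observed feature mean and covariance,
    reruns the clustering for each k, and records the SS ratio.  Returns a
    DataFrame indexed by k with the observed ratio and null percentiles
    (columns ``observed, null_q05, null_q50, null_q95``); the full null
    draws are attached as ``df.attrs['null']`` (k x n_boot).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ks = list(k_range)
    x = _z_matrix(features)
    n, p = x.shape
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    if np.linalg.matrix_rank(cov) < p:
        warnings.warn("singular feature covariance; ridge-stabilized", stacklevel=2)
        cov = cov + 1e-8 * np.trace(cov) / p * np.eye(p)
    rng = np.random.default_rng(seed)
    observed = {}
    for k in ks:
        z = linkage(x, method="complete", metric="cityblock")
        labels = fcluster(z, t=k, criterion="maxclust")
        observed[k] = ss_ratio(x, labels)
    null = np.empty((len(ks), n_boot))
    for b in range(n_boot):
        xb = rng.multivariate_normal(mean, cov, size=n)
        zb = linkage(xb, method="complete", metric="cityblock")
        for j, k in enumerate(ks):
            labels = fcluster(zb, t=k, criterion="maxclust")
            null[j, b] = ss_ratio(xb, labels)
    out = pd.DataFrame(
        {
            "observed": [observed[k] for k in ks],
            "null_q05": np.percentile(null, 5, axis=1),
            "null_q50": np.percentile(null, 50, axis=1),
            "null_q95": np.percentile(null, 95, axis=1),
        },
        index=pd.Index(ks, name="k"),
    )
    out.attrs["null"] = null
    out.attrs["n_boot"] = n_boot
    out.attrs["seed"] = seed
    return out
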