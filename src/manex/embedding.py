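"""Joint rank-one embedding of tangent-vector networks and score tests.

A centered tangent vector is a symmetric matrix encoding the change in
functional connectivity of a task epoch relative to rest.  The joint
embedding approximates every observation i by a shared set of rank-one
connectivity patterns with observation-specific scores,

    T_i  ~=  sum_k  lambda_ik h_k h_k^T,    ||h_k|| = 1,

fit by greedy deflation with alternating exact updates: given h, the best
score is lambda_i = h^T T_i h; given the scores, the best h is the leading
eigenvector of sum_i lambda_i T_i.  Scores are unconstrained in sign
(connectivity can increase or decrease relative to rest).

``score_anova`` runs the split-plot (mixed) ANOVA on component scores with
epoch and day as within-subject factors and learning group between
subjects, BH-corrected across the three main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EmbeddingResult", "joint_embed", "reconstruct", "score_anova"]


@dataclass
class EmbeddingResult:
    components: np.ndarray  # (K, p) unit loading vectors h_k
    scores: np.ndarray  # (n_obs, K) lambda_ik
    residual_norms: np.ndarray  # per-observation Frobenius residual
    fit_history: list = field(default_factory=list)  # objective per iteration, per k
    degenerate: bool = False  # all-zero input: components arbitrary


def _sym_check(mats) -> np.ndarray:
    arr = np.asarray(mats, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("tangents must be (n_obs, p, p)")
    asym = np.abs(arr - arr.transpose(0, 2, 1)).max()
    if asym > 1e-8 * max(1.0, np.abs(arr).max()):
        raise ValueError(f"non-symmetric input (max asymmetry {asym:.3g})")
    return 0.5 * (arr + arr.transpose(0, 2, 1))


def joint_embed(
    tangents,
    K: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> EmbeddingResult:
    """Greedy rank-one joint embedding of symmetric matrices.

    Components are extracted one at a time; after each, the fitted rank-one
    pattern is deflated from every observation.  The objective (total
    squared Frobenius residual) is non-increasing in every alternating
    update.  Components are reported largest-score-variance first, with the
    largest-magnitude loading entry positive.
    """
    r = _sym_check(tangents)
    n, p, _ = r.shape
    if K < 1 or K > p:
        raise ValueError(f"K must be in 1..p={p}")
    rng = np.random.default_rng(seed)
    comps = np.zeros((K, p))
    lams = np.zeros((n, K))
    history = []
    degenerate = False
    for k in range(K):
        h, lam, hist, degen_k = _fit_one(r, tol, max_iter, rng)
        degenerate = degenerate or degen_k
        comps[k] = h
        lams[:, k] = lam
        history.append(hist)
        r = r - lam[:, None, None] * np.outer(h, h)
    # presentation order: largest score variance first; sign rule on loadings
    order = np.argsort(-lams.var(axis=0), kind="stable")
    comps, lams = comps[order], lams[:, order]
    history = [history[i] for i in order]
    for k in range(K):
        if comps[k][np.argmax(np.abs(comps[k]))] < 0:
            comps[k] *= -1
            lams[:, k] *= -1
    resid = np.linalg.norm(r, axis=(1, 2))
    return EmbeddingResult(
        components=comps,
        scores=lams,
        residual_norms=resid,
        fit_history=history,
        degenerate=degenerate,
    )


def _fit_one(r: np.ndarray, tol: float, max_iter: int, rng):
    n, p, _ = r.shape
    scale = np.linalg.norm(r)
    if scale == 0:  # all-zero input: any unit vector fits with zero scores
        return np.eye(p)[0], np.zeros(n), [0.0], True
    m0 = r.sum(axis=0)
    w, v = np.linalg.eigh(m0)
    h = v[:, np.argmax(np.abs(w))]
    if np.abs(w).max() < 1e-12 * scale:
        h = rng.standard_normal(p)
        h /= np.linalg.norm(h)
    hist = []
    prev = np.inf
    lam = np.einsum("ipq,p,q->i", r, h, h)
    for _ in range(max_iter):
        # exact score update for unit h
        lam = np.einsum("ipq,p,q->i", r, h, h)
        obj = float(np.sum(r**2) - np.sum(lam**2))
        hist.append(obj)
        if prev - obj <= tol * max(1.0, abs(prev)):
            break
        prev = obj
        # exact loading update: leading eigenvector of the score-weighted sum
        m = np.einsum("i,ipq->pq", lam, r)
        w, v = np.linalg.eigh(0.5 * (m + m.T))
        h = v[:, -1]
    return h, lam, hist, False


def reconstruct(e: EmbeddingResult, i: int) -> np.ndarray:
    """Rank-K reconstruction sum_k lambda_ik h_k h_k^T of observation i."""
    if not 0 <= i < e.scores.shape[0]:
        raise IndexError(f"observation index {i} out of range")
    return np.einsum("k,kp,kq->pq", e.scores[i], e.components, e.components)


def score_anova(scores: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Split-plot ANOVA main effects of group, day, and epoch on scores.

    ``design`` needs columns ``subject, group, day, epoch`` aligned with
    ``scores``; every subject must contribute exactly one observation per
    day x epoch cell (no imputation — unbalanced designs raise).  Within-
    subject effects (day, epoch) are tested against their interaction with
    subjects-within-group; the between-subject group effect against
    subjects-within-group.  ``q`` is the BH adjustment across the three
    effects.
    """
    df = design.copy()
    df["y"] = np.asarray(scores, dtype=float)
    for col in ("subject", "group", "day", "epoch"):
        if col not in df.columns:
            raise ValueError(f"design is missing column {col!r}")
    cell = df.groupby(["subject", "day", "epoch"]).size()
    if (cell != 1).any():
        raise ValueError("unbalanced design: need one observation per cell")
    n_cells = df.groupby("subject").size()
    if n_cells.nunique() != 1:
        raise ValueError("unbalanced design: subjects differ in cells")
    subj_group = df.groupby("subject")["group"].first()
    if df.groupby("subject")["group"].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")

    gm = df["y"].mean()
    n_subj = df["subject"].nunique()
    n_group = df["group"].nunique()
    days = df["day"].unique()
    epochs = df["epoch"].unique()
    d, e = len(days), len(epochs)

    subj_mean = df.groupby("subject")["y"].mean()
    group_mean = df.groupby("group")["y"].mean()
    n_per_group = subj_group.value_counts()

    ss_group = d * e * float(
        (n_per_group * (group_mean - gm) ** 2).sum()
    )
    ss_subj = d * e * float(((subj_mean - gm) ** 2).sum())
    ss_subj_within = ss_subj - ss_group
    df_group, df_subj_within = n_group - 1, n_subj - n_group

    rows = []

    def _within_effect(name, nlev):
        eff_mean = df.groupby(name)["y"].mean()
        ss_eff = (df.shape[0] / nlev) * float(((eff_mean - gm) ** 2).sum())
        # error: effect x subject interaction, adjusted for group x effect
        sd = df.groupby(["subject", name])["y"].mean().rename("cell").reset_index()
        sd["group"] = sd["subject"].map(subj_group)
        ge = df.groupby(["group", name])["y"].mean()
        sd["ge"] = [ge.loc[(g, lv)] for g, lv in zip(sd["group"], sd[name])]
        sd["smean"] = sd["subject"].map(subj_mean)
        sd["gmean"] = sd["group"].map(group_mean)
        reps = df.shape[0] / (n_subj * nlev)  # obs per subject x level cell
        ss_err = reps * float(
            ((sd["cell"] - sd["smean"] - sd["ge"] + sd["gmean"]) ** 2).sum()
        )
        df1, df2 = nlev - 1, (nlev - 1) * (n_subj - n_group)
        return ss_eff, ss_err, df1, df2

    ss_day, ss_day_err, dfd1, dfd2 = _within_effect("day", d)
    ss_ep, ss_ep_err, dfe1, dfe2 = _within_effect("epoch", e)

    ss_total = float(((df["y"] - gm) ** 2).sum())
    tol = 1e-12 * max(ss_total, 1.0)

    def _f(ss_eff, df1, ss_err, df2):
        if ss_eff <= tol:
            return 0.0, 1.0
        if ss_err <= tol:
            return np.inf, 0.0
        f = (ss_eff / df1) / (ss_err / df2)
        return float(f), float(stats.f.sf(f, df1, df2))

    effects = {
        "day": (ss_day, dfd1, ss_day_err, dfd2),
        "epoch": (ss_ep, dfe1, ss_ep_err, dfe2),
    }
    if n_group > 1:  # between-subject effect needs at least 2 groups
        effects = {"group": (ss_group, df_group, ss_subj_within, df_subj_within),
                   **effects}
    for name, (ss_eff, df1, ss_err, df2) in effects.items():
        f, p = _f(ss_eff, df1, ss_err, df2)
        rows.append({"effect": name, "F": f, "df1": df1, "df2": df2, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
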