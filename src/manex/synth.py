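"""Synthetic behavioral and neural data with known ground truth.

The generators emulate the statistical structure that the analysis assumes,
so every downstream stage has a recovery test against planted truth:

* ``generate_behavior`` — visuomotor-rotation error curves for three
  learner phenotypes (FF fast both days, SS slow both days, SF slow day 1 /
  fast day 2), exponential learning and washout plus Gaussian trial noise,
  lognormal reaction times with occasional RT violations to exercise the
  filters.
* ``generate_neural`` — low-rank latent-factor ROI BOLD: x_t = mu + W z_t +
  s_t u + eps with an orthonormal loading matrix W, a fixed off-manifold
  unit direction u orthogonal to span(W), and a schedulable per-volume
  perturbation magnitude s_t (zero during rest).
* ``generate_covariance_set`` — SPD matrices built by exponential-mapping
  planted rank-one tangent components at jittered subject base matrices,
  S_ij = Exp_{R_i}(sum_k lambda_ijk h_k h_k^T).

Defaults are the task's condition counts: 120 baseline / 320 learning /
120 washout trials, 45 deg clockwise rotation, 2 s TR with 4 s trials
(2 volumes per trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spd

__all__ = [
    "PHENOTYPES",
    "BehaviorSimConfig",
    "NeuralSimConfig",
    "BehaviorDataset",
    "NeuralDataset",
    "CovarianceSet",
    "generate_behavior",
    "generate_neural",
    "generate_covariance_set",
]

PHENOTYPES = ("FF", "SS", "SF")

#: learning time constants in trials: fast ~8 trials, slow ~60 trials
FAST_RATE = 8.0
SLOW_RATE = 60.0


def _default_rates_day1():
    return {"FF": FAST_RATE, "SS": SLOW_RATE, "SF": SLOW_RATE}


def _default_rates_day2():
    return {"FF": FAST_RATE, "SS": SLOW_RATE, "SF": FAST_RATE}


def _default_washout():
    return {p: 15.0 for p in PHENOTYPES}


def _default_rt_mean():
    return {"FF": 0.45, "SS": 0.50, "SF": 0.48}


def _default_rt_sd():
    return {p: 0.15 for p in PHENOTYPES}


@dataclass
class BehaviorSimConfig:
    n_subjects_per_group: int = 10
    n_baseline_trials: int = 120
    n_learning_trials: int = 320
    n_washout_trials: int = 120
    rotation_deg: float = 45.0  # clockwise
    learn_rate_day1: dict = field(default_factory=_default_rates_day1)
    learn_rate_day2: dict = field(default_factory=_default_rates_day2)
    washout_rate: dict = field(default_factory=_default_washout)
    rt_mean: dict = field(default_factory=_default_rt_mean)
    rt_sd: dict = field(default_factory=_default_rt_sd)
    error_noise_sd: float = 6.0  # degrees
    rt_violation_rate: float = 0.02  # trials given rt > 2 s or < 0.1 s
    seed: int | None = None

    def __post_init__(self):
        for n in (
            self.n_subjects_per_group,
            self.n_baseline_trials,
            self.n_learning_trials,
            self.n_washout_trials,
        ):
            if n <= 0:
                raise ValueError("all counts must be > 0")
        for rates in (self.learn_rate_day1, self.learn_rate_day2, self.washout_rate):
            for ph, r in rates.items():
                if ph not in PHENOTYPES:
                    raise ValueError(f"invalid phenotype {ph!r}")
                if r <= 0:
                    raise ValueError(f"non-positive rate for {ph}: {r}")
        if self.error_noise_sd < 0:
            raise ValueError("error_noise_sd must be >= 0")


@dataclass
class BehaviorDataset:
    trials: dict  # subject id -> trial DataFrame (both days)
    groups: pd.Series  # subject id -> phenotype (ground truth)
    config: BehaviorSimConfig


_TARGETS = np.arange(0, 360, 45)


def generate_behavior(cfg: BehaviorSimConfig) -> BehaviorDataset:
    """Simulate the two-day rotation task for all phenotype groups."""
    rng = np.random.default_rng(cfg.seed)
    trials, groups = {}, {}
    for ph in PHENOTYPES:
        for s in range(cfg.n_subjects_per_group):
            subj = f"{ph}{s:02d}"
            days = [
                _simulate_day(cfg, ph, day, rng) for day in (1, 2)
            ]
            trials[subj] = pd.concat(days, ignore_index=True)
            groups[subj] = ph
    return BehaviorDataset(
        trials=trials, groups=pd.Series(groups, name="group"), config=cfg
    )


def _simulate_day(cfg: BehaviorSimConfig, ph: str, day: int, rng) -> pd.DataFrame:
    rate = (cfg.learn_rate_day1 if day == 1 else cfg.learn_rate_day2)[ph]
    nb, nl, nw = cfg.n_baseline_trials, cfg.n_learning_trials, cfg.n_washout_trials
    t_learn = np.arange(nl, dtype=float)
    t_wash = np.arange(nw, dtype=float)
    mean_err = np.concatenate(
        [
            np.zeros(nb),
            cfg.rotation_deg * np.exp(-t_learn / rate),
            # after-effect: adapted amount released at washout, decays to 0
            -cfg.rotation_deg
            * (1.0 - np.exp(-nl / rate))
            * np.exp(-t_wash / cfg.washout_rate[ph]),
        ]
    )
    n = nb + nl + nw
    err = mean_err + (
        rng.normal(0.0, cfg.error_noise_sd, size=n) if cfg.error_noise_sd > 0 else 0.0
    )
    # lognormal RT with the requested mean/sd on the natural scale
    m, s = cfg.rt_mean[ph], cfg.rt_sd[ph]
    sigma2 = np.log(1.0 + (s / m) ** 2)
    rt = rng.lognormal(np.log(m) - sigma2 / 2, np.sqrt(sigma2), size=n)
    if cfg.rt_violation_rate > 0:
        viol = rng.random(n) < cfg.rt_violation_rate
        fast = rng.random(viol.sum()) < 0.5
        rt_v = np.where(fast, rng.uniform(0.0, 0.09, viol.sum()),
                        rng.uniform(2.1, 2.6, viol.sum()))
        rt[viol] = rt_v
    epoch = np.array(["baseline"] * nb + ["learning"] * nl + ["washout"] * nw)
    trial = np.arange(n)
    return pd.DataFrame(
        {
            "trial": trial,
            "block": trial // 8,
            "day": day,
            "epoch": epoch,
            "target_deg": _TARGETS[trial % len(_TARGETS)].astype(float),
            "error_deg": err,
            "rt_s": rt,
        }
    )


def _default_schedule():
    return None


@dataclass
class NeuralSimConfig:
    n_rois: int = 30
    manifold_dim: int = 5
    n_volumes_rest: int = 180
    n_volumes_task: int = 880
    tr_seconds: float = 2.0
    #: per-volume magnitude of the off-manifold perturbation during task
    off_manifold_schedule: np.ndarray | None = None
    subject_covariance_jitter: float = 0.0
    #: planted rank-one tangent structure for generate_covariance_set:
    #: dict with "components" (K x p loading vectors) and "scores"
    #: (n_subjects x n_epochs x K)
    epoch_tangent_components: dict | None = None
    #: per-factor latent variances decay geometrically by this factor
    factor_decay: float = 0.6
    factor_scale: float = 4.0
    noise_sd: float = 0.0
    seed: int | None = None
    #: seeds the subject's structural draw (loading matrix, off-manifold
    #: direction, mean) separately from the per-scan noise, so repeated
    #: scans of one subject share structure; defaults to ``seed``
    structure_seed: int | None = None

    def __post_init__(self):
        if self.manifold_dim >= self.n_rois:
            raise ValueError("manifold_dim must be < n_rois")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.off_manifold_schedule is not None:
            self.off_manifold_schedule = np.asarray(
                self.off_manifold_schedule, dtype=float
            )
            if len(self.off_manifold_schedule) != self.n_volumes_task:
                raise ValueError(
                    "off_manifold_schedule length must equal n_volumes_task"
                )

    def factor_variances(self) -> np.ndarray:
        return self.factor_scale * self.factor_decay ** np.arange(self.manifold_dim)


@dataclass
class NeuralDataset:
    rest: np.ndarray  # (n_volumes_rest, n_rois)
    task: np.ndarray  # (n_volumes_task, n_rois)
    loading: np.ndarray  # ground-truth W (n_rois, k), orthonormal
    off_direction: np.ndarray  # ground-truth u, unit, orthogonal to span(W)
    schedule: np.ndarray  # s_t
    mean: np.ndarray  # mu


def generate_neural(cfg: NeuralSimConfig) -> NeuralDataset:
    """One subject's rest and task scans from the latent-factor model."""
    rng = np.random.default_rng(cfg.seed)
    struct = np.random.default_rng(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    )
    p, k = cfg.n_rois, cfg.manifold_dim
    # orthonormal frame: first k columns = W, column k = u
    q, _ = np.linalg.qr(struct.standard_normal((p, k + 1)))
    w, u = q[:, :k], q[:, k]
    mu = struct.normal(0.0, 1.0, size=p)
    var = cfg.factor_variances()
    if cfg.subject_covariance_jitter > 0:
        var = var * struct.lognormal(0.0, cfg.subject_covariance_jitter, size=k)
    schedule = (
        cfg.off_manifold_schedule
        if cfg.off_manifold_schedule is not None
        else np.zeros(cfg.n_volumes_task)
    )

    def _scan(n, s_t):
        z = rng.standard_normal((n, k)) * np.sqrt(var)
        x = mu + z @ w.T + np.outer(s_t, u)
        if cfg.noise_sd > 0:
            x = x + rng.normal(0.0, cfg.noise_sd, size=(n, p))
        return x

    rest = _scan(cfg.n_volumes_rest, np.zeros(cfg.n_volumes_rest))
    task = _scan(cfg.n_volumes_task, schedule)
    return NeuralDataset(
        rest=rest, task=task, loading=w, off_direction=u,
        schedule=np.asarray(schedule, float), mean=mu,
    )


@dataclass
class CovarianceSet:
    matrices: list  # list over subjects of list over epochs of SPD arrays
    bases: list  # subject base matrices R_i
    components: np.ndarray  # planted loading vectors (K, p), unit norm
    scores: np.ndarray  # (n_subjects, n_epochs, K)


def generate_covariance_set(cfg: NeuralSimConfig) -> CovarianceSet:
    """SPD matrices with planted rank-one tangent structure.

    For each subject i and epoch j, S_ij = Exp_{R_i}(sum_k lambda_ijk
    h_k h_k^T) where R_i is an identity base perturbed by a symmetric
    jitter of scale ``subject_covariance_jitter`` (kept SPD by
    construction).  Ground-truth components and scores are returned.
    """
    if cfg.epoch_tangent_components is None:
        raise ValueError("epoch_tangent_components must be supplied")
    comp = np.asarray(cfg.epoch_tangent_components["components"], dtype=float)
    scores = np.asarray(cfg.epoch_tangent_components["scores"], dtype=float)
    if comp.ndim != 2:
        raise ValueError("components must be (K, p)")
    kk, p = comp.shape
    if scores.ndim != 3 or scores.shape[2] != kk:
        raise ValueError("scores must be (n_subjects, n_epochs, K)")
    comp = comp / np.linalg.norm(comp, axis=1, keepdims=True)
    rng = np.random.default_rng(cfg.seed)
    n_subj, n_epoch = scores.shape[:2]
    bases, matrices = [], []
    for i in range(n_subj):
        if cfg.subject_covariance_jitter > 0:
            a = rng.normal(0.0, cfg.subject_covariance_jitter, size=(p, p))
            base = spd.exp_map(np.eye(p), 0.5 * (a + a.T))
        else:
            base = np.eye(p)
        spd.check_spd(base, "base")
        bases.append(base)
        row = []
        for j in range(n_epoch):
            t = np.einsum("k,kp,kq->pq", scores[i, j], comp, comp)
            row.append(spd.exp_map(base, t))
        matrices.append(row)
    return CovarianceSet(
        matrices=matrices, bases=bases, components=comp, scores=scores
    )
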