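"""End-to-end synthetic analysis: simulate -> cluster -> excursion -> fPCA
-> covariance centering -> embedding.

``run_pipeline`` wires the stage modules together on a fully synthetic
cohort with known ground truth, so the whole chain can be exercised and
checked deterministically from a single seed.  Stage outputs are returned
in a :class:`PipelineResult` and, when ``out_dir`` is given, written as
tab-delimited tables plus a JSON summary carrying the config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import behavior as bhv
from . import embedding as emb
from . import excursion as exc
from . import fpca, spd, synth
from .io import write_matrix, write_roi_timeseries

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

#: planted off-manifold step height per (group, day); FF/SF engage the
#: cognitive system more than SS at rotation onset, SF most on day 2
COG_STEP = {("FF", 1): 3.0, ("SS", 1): 1.0, ("SF", 1): 3.0,
            ("FF", 2): 2.0, ("SS", 2): 1.0, ("SF", 2): 3.0}
SM_STEP_FRACTION = 0.5  # sensorimotor perturbation relative to cognitive


def _default_networks():
    return {"cognitive": 62, "sensorimotor": 51}


@dataclass
class PipelineConfig:
    out_dir: str | None = None
    seed: int = 0
    n_subjects_per_group: int = 10
    networks: dict = field(default_factory=_default_networks)
    manifold_dim: int = 5
    tr_seconds: float = 2.0
    volumes_per_trial: int = 2
    var_threshold: float = 0.75
    k_clusters: int = 3
    n_boot: int = 500
    n_mfpca_components: int = 3
    n_embed_components: int = 2
    epoch_length: int = 177  # volumes per covariance window (rest and task)
    noise_sd: float = 0.5
    force: bool = False

    # behavioral task layout (trials)
    n_baseline_trials: int = 120
    n_learning_trials: int = 320
    n_washout_trials: int = 120

    def __post_init__(self):
        if self.epoch_length < 2:
            raise ValueError("epoch_length must be >= 2")
        names = list(self.networks)
        if len(set(names)) != len(names):
            raise ValueError("networks must be disjoint (unique names)")
        onset = self.n_baseline_trials * self.volumes_per_trial
        n_task = (self.n_baseline_trials + self.n_learning_trials) * self.volumes_per_trial
        windows = self.epoch_windows(n_task, onset)
        lengths = {hi - lo for lo, hi in windows.values()}
        if len(lengths) != 1:
            raise ValueError("epoch windows must all have equal length")
        for lo, hi in windows.values():
            if lo < 0 or hi > n_task:
                raise ValueError("epoch window outside the task scan")

    def epoch_windows(self, n_task: int, onset: int) -> dict:
        """Half-open task-volume windows for the covariance epochs."""
        L = self.epoch_length
        return {
            "baseline": (onset - L, onset),
            "early": (onset, onset + L),
            "late": (n_task - L, n_task),
        }

    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    cluster_labels: np.ndarray
    ari: float
    bootstrap: pd.DataFrame
    excursion_table: pd.DataFrame  # subject, group, network, day, early_excursion
    mfpca_result: fpca.MfpcaResult
    mfpca_tests: pd.DataFrame  # per-component Kruskal-Wallis + post hoc count
    embeddings: dict  # network -> EmbeddingResult
    anovas: dict  # network -> per-component score ANOVA tables
    summary: dict


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic cohort; see the module docstring."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        if out.exists() and any(out.iterdir()) and not cfg.force:
            raise FileExistsError(f"{out} is not empty; pass force=True")
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    seed_behavior, seed_neural, seed_boot, seed_embed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    # ---- behavior: simulate, preprocess, features, clustering ----
    bcfg = synth.BehaviorSimConfig(
        n_subjects_per_group=cfg.n_subjects_per_group,
        n_baseline_trials=cfg.n_baseline_trials,
        n_learning_trials=cfg.n_learning_trials,
        n_washout_trials=cfg.n_washout_trials,
        seed=seed_behavior,
    )
    bdata = synth.generate_behavior(bcfg)
    clean = {s: bhv.preprocess_trials(t) for s, t in bdata.trials.items()}
    features = bhv.compute_features(clean)
    solution = bhv.cluster_learners(features, k=cfg.k_clusters)
    ari = float(
        adjusted_rand_score(bdata.groups.loc[features.index], solution.labels)
    )
    with warnings.catch_warnings():
        # savings is a linear combination of the two early errors, so the
        # feature covariance is singular by construction; the ridge
        # stabilization inside the bootstrap is expected here
        warnings.simplefilter("ignore", UserWarning)
        bootstrap = bhv.bootstrap_cluster_validity(
            features, k_range=range(2, 9), n_boot=cfg.n_boot, seed=seed_boot
        )

    # ---- neural simulation + excursion per subject/network/day ----
    onset = cfg.n_baseline_trials * cfg.volumes_per_trial
    n_task = (cfg.n_baseline_trials + cfg.n_learning_trials) * cfg.volumes_per_trial
    subjects = list(features.index)
    groups = bdata.groups.loc[subjects]
    neural_ss = np.random.SeedSequence(seed_neural)
    # one structural seed per subject x network (shared across days), one
    # noise seed per scan
    child = iter(neural_ss.spawn(len(subjects) * len(cfg.networks) * 3))

    rows = []
    curves = {s: {} for s in subjects}  # (network, day) -> standardized curve
    rest_scans = {}  # (subject, network) -> rest array (day-1 rest)
    task_scans = {}  # (subject, network, day) -> task array
    for subj in subjects:
        group = groups.loc[subj]
        for net, n_rois in cfg.networks.items():
            structure_seed = int(next(child).generate_state(1)[0] % (2**31))
            for day in (1, 2):
                height = COG_STEP[(group, day)]
                if net != "cognitive":
                    height *= SM_STEP_FRACTION
                # perturbation peaks at rotation onset and relaxes over the
                # early-learning window (32 trials), like the excursion peak
                tau = 32 * cfg.volumes_per_trial
                sched = np.zeros(n_task)
                t = np.arange(n_task - onset, dtype=float)
                sched[onset:] = height * np.exp(-t / tau)
                ncfg = synth.NeuralSimConfig(
                    n_rois=n_rois,
                    manifold_dim=cfg.manifold_dim,
                    n_volumes_rest=max(180, cfg.epoch_length),
                    n_volumes_task=n_task,
                    tr_seconds=cfg.tr_seconds,
                    off_manifold_schedule=sched,
                    noise_sd=cfg.noise_sd,
                    seed=int(next(child).generate_state(1)[0] % (2**31)),
                    structure_seed=structure_seed,
                )
                nd = synth.generate_neural(ncfg)
                task_scans[(subj, net, day)] = nd.task
                if day == 1:
                    rest_scans[(subj, net)] = nd.rest
                manifold = exc.fit_manifold(
                    rest_scans[(subj, net)], var_threshold=cfg.var_threshold
                )
                curve = exc.excursion_series(
                    manifold, nd.task, network=net, day=day,
                    baseline_window=(0, onset), rotation_onset=onset,
                )
                curve = exc.standardize_to_baseline(curve)
                early = exc.early_excursion(
                    curve, volumes_per_trial=cfg.volumes_per_trial
                )
                curves[subj][(net, day)] = curve
                rows.append(
                    dict(subject=subj, group=group, network=net, day=day,
                         early_excursion=early, manifold_dim=manifold.d)
                )
    excursion_table = pd.DataFrame(rows)

    # ---- mfPCA on the 4 curves per subject + group tests ----
    elements = [(net, day) for net in cfg.networks for day in (1, 2)]
    smoother = fpca.SplineSmoother(np.arange(n_task, dtype=float))
    tuples = [
        [smoother.fit(curves[s][el].standardized_values) for el in elements]
        for s in subjects
    ]
    mf = fpca.mfpca(tuples, K=cfg.n_mfpca_components)
    test_rows = []
    glabels = groups.to_numpy()
    for k in range(cfg.n_mfpca_components):
        h, p = fpca.kruskal_wallis(mf.scores[:, k], glabels)
        post = fpca.conover_iman(mf.scores[:, k], glabels)
        test_rows.append(
            dict(component=k + 1, H=h, p=p,
                 n_pairs_significant=int((post["p_adj"] < 0.05).sum()))
        )
    mfpca_tests = pd.DataFrame(test_rows)

    # ---- covariance estimation, centering, embedding per network ----
    embeddings, anovas = {}, {}
    embed_ss = iter(np.random.SeedSequence(seed_embed).spawn(len(cfg.networks)))
    for net in cfg.networks:
        rests = {
            s: spd.shrinkage_covariance(rest_scans[(s, net)][: cfg.epoch_length])
            for s in subjects
        }
        grand = spd.frechet_mean(list(rests.values()))
        tangents, design_rows = [], []
        for subj in subjects:
            for day in (1, 2):
                task = task_scans[(subj, net, day)]
                windows = cfg.epoch_windows(n_task, onset)
                mats = [
                    spd.shrinkage_covariance(task[lo:hi])
                    for lo, hi in windows.values()
                ]
                tcs, _ = spd.center_to_grand_mean(rests[subj], mats, grand)
                for epoch, tc in zip(windows, tcs):
                    tangents.append(tc)
                    design_rows.append(
                        dict(subject=subj, group=groups.loc[subj],
                             day=day, epoch=epoch)
                    )
        design = pd.DataFrame(design_rows)
        result = emb.joint_embed(
            tangents, K=cfg.n_embed_components,
            seed=int(next(embed_ss).generate_state(1)[0] % (2**31)),
        )
        embeddings[net] = (result, design)
        anovas[net] = {
            k + 1: emb.score_anova(result.scores[:, k], design)
            for k in range(cfg.n_embed_components)
        }

    ee = excursion_table.query("network == 'cognitive' and day == 1")
    group_early = ee.groupby("group")["early_excursion"].mean()
    summary = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_subjects": len(subjects),
        "ari": ari,
        "cluster_sizes": np.bincount(solution.labels)[1:].tolist(),
        "ss_ratio_k3_observed": float(bootstrap.loc[cfg.k_clusters, "observed"]),
        "ss_ratio_k3_null_q05": float(bootstrap.loc[cfg.k_clusters, "null_q05"]),
        "early_excursion_group_means_cognitive_day1": group_early.to_dict(),
        "mfpca_var_explained": mf.var_explained.tolist(),
        "embedding_residual_mean": {
            net: float(embeddings[net][0].residual_norms.mean())
            for net in cfg.networks
        },
    }

    result = PipelineResult(
        features=features,
        cluster_labels=solution.labels,
        ari=ari,
        bootstrap=bootstrap,
        excursion_table=excursion_table,
        mfpca_result=mf,
        mfpca_tests=mfpca_tests,
        embeddings=embeddings,
        anovas=anovas,
        summary=summary,
    )
    if out is not None:
        _write_outputs(out, cfg, result, groups)
    return result


def _write_outputs(out: Path, cfg: PipelineConfig, res: PipelineResult, groups):
    res.features.assign(group=groups, cluster=res.cluster_labels).to_csv(
        out / "features.tsv", sep="\t"
    )
    res.bootstrap.to_csv(out / "bootstrap.tsv", sep="\t")
    res.excursion_table.to_csv(out / "excursion.tsv", sep="\t", index=False)
    res.mfpca_tests.to_csv(out / "mfpca_tests.tsv", sep="\t", index=False)
    pd.DataFrame(
        res.mfpca_result.scores,
        index=res.features.index,
        columns=[f"mfpc{k + 1}" for k in range(res.mfpca_result.scores.shape[1])],
    ).to_csv(out / "mfpca_scores.tsv", sep="\t")
    for net, (embr, design) in res.embeddings.items():
        scores = pd.concat(
            [design.reset_index(drop=True),
             pd.DataFrame(embr.scores,
                          columns=[f"comp{k + 1}" for k in range(embr.scores.shape[1])])],
            axis=1,
        )
        scores.to_csv(out / f"embedding_scores_{net}.tsv", sep="\t", index=False)
        for k, table in res.anovas[net].items():
            table.to_csv(out / f"anova_{net}_comp{k}.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2)
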