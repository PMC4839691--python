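"""End-to-end synthetic studies: cohorts, fits, statistics, figures.

``run_study`` mirrors the flow of a full ACI experiment: a control and
a case cohort of simulated listeners run the staircase task, each
observer's ACI is estimated with the cohort-level smoothing selection,
auto/cross-prediction deviances and specificity are computed, and the
two groups are compared with the cluster permutation test and the ROI
analysis.  Every artifact is written as CSV/JSON plus a manifest with
the config hash and all seeds, so a study is reproducible end to end.

The default configuration reflects the reference task: two cohorts of
18 listeners, 10,000 trials each in 20 sessions of 500, a 10-point
logarithmic smoothing grid, and 5000 permutations.  That is hours of
compute; scale ``n_per_group``, ``n_trials`` and ``n_perm`` down for
smoke runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

import acimage
from acimage.cochleogram import build_filterbank
from acimage.fit import (DEFAULT_LAMBDA_GRID, cross_validate, make_folds,
                         select_lambda_and_refit)
from acimage.groupstats import (cluster_permutation_test, define_rois,
                                roi_compare)
from acimage.observer import (StaircaseConfig, matched_observer,
                              performance_summary, run_experiment,
                              smooth_bump)
from acimage.specificity import prediction_matrix, specificity
from acimage.stimuli import synthesize_targets


@dataclass
class StudyConfig:
    """Complete, serializable description of one synthetic study."""

    n_per_group: int = 18                 # per-cohort size
    n_trials: int = 10_000
    session_length: int = 500
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_folds: int = 10
    internal_noise_sd: float = 10.0
    template_variability: float = 0.25    # SD of smooth per-observer quirks
    case_f1_attenuation: float = 0.0      # 0 = case templates match controls
    n_perm: int = 5000
    cluster_alpha: float = 0.05
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    seed: int = 0
    make_figures: bool = True

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = [float(v) for v in self.lambda_grid]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text)
        d["staircase"] = StaircaseConfig(**d["staircase"])
        d["lambda_grid"] = tuple(d["lambda_grid"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _observer_perturbation(rng: np.random.Generator, scale: float,
                           shape=(54, 81)) -> np.ndarray:
    """Smooth random template quirk: a mixture of a few Gaussian bumps."""
    if scale <= 0:
        return np.zeros(shape)
    p = np.zeros(shape)
    for _ in range(4):
        p += rng.normal() * smooth_bump(rng.uniform(5, shape[0] - 5),
                                        rng.uniform(5, shape[1] - 5),
                                        shape=shape)
    n = np.linalg.norm(p)
    return scale * p / n if n > 0 else p


def _f1_cue_mask(center_frequencies: np.ndarray,
                 frame_times: np.ndarray) -> np.ndarray:
    """Low-frequency (F1-onset) cue region: 500-900 Hz, 380-450 ms."""
    ch = (center_frequencies >= 500) & (center_frequencies <= 900)
    fr = (frame_times >= 380) & (frame_times <= 450)
    return np.outer(ch, fr)


def run_study(cfg: StudyConfig, out_dir) -> Path:
    """Run the full synthetic study; returns the study directory.

    Emits, under ``out_dir``: per-observer ``<label>/trials.csv`` and
    ``<label>/model.npz``; ``cv_curves.csv``, ``prediction_matrix.csv``,
    ``specificity.csv``, ``cluster_test.json``, ``roi_table.csv``,
    ``session_curves.csv``, ``performance.csv``, ``manifest.json`` and
    (optionally) mean-ACI figures.  Deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = synthesize_targets()
    fb = build_filterbank(sample_rate=targets.sample_rate)
    root_rng = np.random.default_rng(cfg.seed)

    groups = {"control": cfg.n_per_group, "case": cfg.n_per_group}
    datasets, cv_tables, labels, group_of, seeds, trials_by_group = \
        [], [], [], {}, [], {"control": [], "case": []}
    ref_coch_axes = {}
    prefix = {"control": "C", "case": "D"}
    for gname, n_obs in groups.items():
        for i in range(n_obs):
            label = f"{prefix[gname]}{i + 1}"
            obs_seed = int(root_rng.integers(2 ** 31))
            rng = np.random.default_rng(obs_seed)
            pert = _observer_perturbation(rng, cfg.template_variability)
            observer = matched_observer(
                targets, fb, internal_noise_sd=cfg.internal_noise_sd,
                template_perturbation=pert, label=label)
            if gname == "case" and cfg.case_f1_attenuation > 0:
                from acimage.cochleogram import compute_cochleogram
                c0 = compute_cochleogram(targets.waveforms[targets.labels[0]],
                                         fb)
                mask = _f1_cue_mask(c0.center_frequencies, c0.frame_times)
                t = observer.template.copy()
                t[mask] *= (1.0 - cfg.case_f1_attenuation)
                observer.template = t / np.linalg.norm(t)
            trials, X = run_experiment(
                observer, targets, n_trials=cfg.n_trials, seed=obs_seed,
                filterbank=fb, staircase=cfg.staircase,
                session_length=cfg.session_length, return_predictors=True)
            obs_dir = out / label
            obs_dir.mkdir(exist_ok=True)
            trials.to_csv(obs_dir / "trials.csv", index=False)
            folds = make_folds(len(trials), n_folds=cfg.n_folds,
                               seed=obs_seed)
            cv = cross_validate(X, trials, lambda_grid=cfg.lambda_grid,
                                seed=obs_seed, n_folds=cfg.n_folds,
                                folds=folds)
            cv["observer"] = label
            cv_tables.append(cv)
            datasets.append((X, trials, label))
            labels.append(label)
            group_of[label] = gname
            seeds.append(obs_seed)
            trials_by_group[gname].append(trials)
    pd.concat(cv_tables).to_csv(out / "cv_curves.csv", index=False)

    models = select_lambda_and_refit(datasets, cv_tables, seed=cfg.seed)
    for model, (X, trials, label), obs_seed, folds_seed in \
            zip(models, datasets, seeds, seeds):
        model.fold_assignment = make_folds(len(trials),
                                           n_folds=cfg.n_folds,
                                           seed=obs_seed)
        model.save(out / label / "model.npz")

    pm = prediction_matrix(models, [(X, t) for X, t, _ in datasets],
                           seeds=seeds, n_folds=cfg.n_folds)
    pm.to_frame().to_csv(out / "prediction_matrix.csv")
    spec = specificity(pm)
    sdf = spec.to_frame()
    sdf["group"] = [group_of[o] for o in spec.observers]
    sdf.to_csv(out / "specificity.csv", index=False)

    maps = {m.label: m.beta for m in models}
    maps_control = [maps[l] for l in labels if group_of[l] == "control"]
    maps_case = [maps[l] for l in labels if group_of[l] == "case"]
    ct = cluster_permutation_test(maps_control, maps_case,
                                  n_perm=cfg.n_perm,
                                  alpha=cfg.cluster_alpha, seed=cfg.seed)
    (out / "cluster_test.json").write_text(json.dumps({
        "n_permutations": ct.n_permutations,
        "cluster_alpha": ct.cluster_alpha,
        "clusters": ct.to_frame().to_dict(orient="records"),
    }, indent=2))

    from acimage.cochleogram import compute_cochleogram
    c0 = compute_cochleogram(targets.waveforms[targets.labels[0]], fb)
    rois = define_rois(maps_control + maps_case,
                       frame_times=c0.frame_times,
                       center_frequencies=c0.center_frequencies)
    if len(rois):
        roi_compare(rois, maps_control, maps_case).to_csv(
            out / "roi_table.csv", index=False)
    else:
        (out / "roi_table.csv").write_text("")

    session_curves(trials_by_group).to_csv(out / "session_curves.csv",
                                           index=False)
    perf = pd.DataFrame([
        {"observer": lab, "group": group_of[lab],
         **{k: v for k, v in performance_summary(t).items()
            if not isinstance(v, pd.DataFrame)}}
        for lab, t in zip(labels,
                          trials_by_group["control"] +
                          trials_by_group["case"])])
    perf.to_csv(out / "performance.csv", index=False)

    if cfg.make_figures:
        for name, group_maps in (("control", maps_control),
                                 ("case", maps_case)):
            plot_aci(np.mean(group_maps, axis=0), targets.formant_tracks,
                     c0.frame_times, c0.center_frequencies,
                     out / f"mean_aci_{name}.png",
                     title=f"mean ACI ({name})")

    manifest = {
        "package_version": acimage.__version__,
        "config_hash": cfg.digest(),
        "config": yaml.safe_load(cfg.to_yaml()),
        "observer_seeds": dict(zip(labels, seeds)),
        "selected_lambda": float(models[0].lam),
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(cfg.to_yaml())
    return out


def plot_aci(beta_map: np.ndarray, formant_tracks, frame_times,
             center_frequencies, path, title: str = "ACI"):
    """Heatmap of an ACI with formant-track overlays.

    Positive ('da'-pushing) weights are red, negative ('ga') blue, on a
    symmetric diverging scale; /da/ target formant tracks are drawn in
    red and /ga/ tracks in blue, axes in ms and Hz.
    """
    beta_map = np.asarray(beta_map, dtype=float)
    vmax = float(np.abs(beta_map).max()) or 1.0
    fig, ax = plt.subplots(figsize=(7, 4.5))
    mesh = ax.pcolormesh(frame_times, center_frequencies, beta_map,
                         cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                         shading="nearest")
    if formant_tracks:
        for label, tracks in formant_tracks.items():
            color = "red" if label.endswith("da") else "blue"
            for fmt, pts in tracks.items():
                pts = np.asarray(pts, dtype=float)
                ax.plot(pts[:, 0], pts[:, 1], color=color, lw=0.6,
                        alpha=0.6)
    ax.set_yscale("log")
    ax.set_ylim(center_frequencies[0], center_frequencies[-1])
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="weight (towards 'da'  <->  'ga')")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def session_curves(trials_by_group: dict[str, list[pd.DataFrame]]
                   ) -> pd.DataFrame:
    """Per-session mean SNR (+- sem over observers) per group.

    Expects every observer's sessions to have equal trial counts;
    ragged session lengths raise.
    """
    rows = []
    for gname, tables in trials_by_group.items():
        if not tables:
            continue
        per_obs = []
        for t in tables:
            counts = t.groupby("session").size()
            if counts.nunique() != 1:
                raise ValueError("ragged sessions in a trial table")
            per_obs.append(t.groupby("session")["snr_db"].mean())
        stacked = pd.concat(per_obs, axis=1)
        mean = stacked.mean(axis=1)
        sem = stacked.std(axis=1, ddof=1) / np.sqrt(stacked.shape[1]) \
            if stacked.shape[1] > 1 else pd.Series(0.0, index=stacked.index)
        for s in stacked.index:
            rows.append({"group": gname, "session": int(s),
                         "mean_snr": float(mean[s]),
                         "sem_snr": float(sem[s])})
    return pd.DataFrame(rows)
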