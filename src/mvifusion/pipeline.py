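"""End-to-end driver: phantom -> cubes -> training -> metrics -> saliency.

Each stage reads only its declared inputs from the run directory and records
its completion in ``run_manifest.json``, so a run can be resumed or partially
re-executed; ``--force`` re-runs a completed stage.  Layout of a run
directory:

    outdir/
      config.yaml           normalized config snapshot
      run_manifest.json     stage completion flags, seeds, version
      phantom/              NIfTI volumes + roster.csv
      cubes/                split.json, manifest.csv, cubes.npz
      models/<name>/        fold checkpoints (.npz + .json) and learning curves
      metrics/              metrics.csv, roc_*.csv, dca_*.csv, report.txt, plots
      saliency/             Grad-CAM NIfTI volumes, phase-weight CSV + heatmap
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import save_config
from .evaluation import compare_models, format_report, net_benefit, roc_auc
from .interpret import (
    attention_mass_fraction,
    grad_cam,
    margin_shell_region,
    permutation_null_fraction,
    phase_weight_heatmap,
)
from .nn.network import NetworkConfig, build_network, load_checkpoint, save_checkpoint
from .phantom import PHASES, PhantomConfig, generate_cohort, load_study
from .preprocess import CubeStore, SplitPlan, build_manifest, build_cube_store, make_split, mask_to_bbox
from .training import FoldModel, TrainConfig, ensemble_predict, train_fold

log = logging.getLogger("mvifusion")

STAGES = ("simulate", "preprocess", "train", "evaluate", "explain")


def model_name(phases: Sequence[str]) -> str:
    return f"{len(phases)}P" if len(phases) > 1 else phases[0]


class RunManifest:
    """Stage-completion ledger of one run directory."""

    def __init__(self, outdir: Path):
        self.path = Path(outdir) / "run_manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}, "seeds": {}}

    def done(self, stage: str) -> bool:
        return self.data["stages"].get(stage, {}).get("completed", False)

    def mark(self, stage: str, **info) -> None:
        self.data["stages"][stage] = {"completed": True, "wall_time": time.time(), **info}
        self.path.parent.mkdir(parents=True, exist_ok=True)
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.data, indent=2))
        tmp.replace(self.path)


def _phantom_config(cfg: dict) -> PhantomConfig:
    p = cfg["phantom"]
    return PhantomConfig(
        n_patients=p["n_patients"],
        mvi_fraction=p["mvi_fraction"],
        volume_shape=tuple(p["volume_shape"]),
        tumor_radius_range=tuple(p["tumor_radius_range"]),
        margin_irregularity_amp=p["margin_irregularity_amp"],
        ap_ring_contrast=p["ap_ring_contrast"],
        hbp_ring_contrast=p["hbp_ring_contrast"],
        ring_thickness=p["ring_thickness"],
        noise_sd=p["noise_sd"],
        seed=p["seed"],
    )


def _network_config(cfg: dict, phases: Sequence[str] | None = None) -> NetworkConfig:
    n = cfg["network"]
    return NetworkConfig(
        phases=tuple(phases or n["phases"]),
        conv_channels=tuple(n["conv_channels"]),
        fc_feature_dim_per_phase=n["fc_feature_dim_per_phase"],
        dropout_rate=n["dropout_rate"],
        attention_gamma_init=n["attention_gamma_init"],
        attention_d_qk=n["attention_d_qk"],
    )


def _train_config(cfg: dict) -> TrainConfig:
    t = dict(cfg["train"])
    if t["loss_weights"] is not None:
        t["loss_weights"] = tuple(t["loss_weights"])
    return TrainConfig(**t)


def stage_simulate(cfg: dict, outdir: Path, force: bool = False) -> pd.DataFrame:
    manifest = RunManifest(outdir)
    roster_path = outdir / "phantom" / "roster.csv"
    if manifest.done("simulate") and roster_path.exists() and not force:
        log.info("simulate: already complete, skipping")
        return pd.read_csv(roster_path)
    pcfg = _phantom_config(cfg)
    log.info("simulate: %d patients -> %s", pcfg.n_patients, outdir / "phantom")
    roster = generate_cohort(pcfg, outdir / "phantom")
    manifest.mark("simulate", n_patients=pcfg.n_patients, seed=pcfg.seed)
    return roster


def stage_preprocess(cfg: dict, outdir: Path, force: bool = False) -> None:
    manifest = RunManifest(outdir)
    cubes_dir = outdir / "cubes"
    if manifest.done("preprocess") and (cubes_dir / "manifest.csv").exists() and not force:
        log.info("preprocess: already complete, skipping")
        return
    roster_path = outdir / "phantom" / "roster.csv"
    if not roster_path.exists():
        raise FileNotFoundError(f"missing roster {roster_path}: run the simulate stage first")
    roster = pd.read_csv(roster_path)
    split = make_split(roster, cfg["split"]["test_fraction"], cfg["split"]["n_folds"], cfg["split"]["seed"])
    sample_manifest = build_manifest(roster, split)
    store = build_cube_store((load_study(row) for _, row in roster.iterrows()), split)
    cubes_dir.mkdir(parents=True, exist_ok=True)
    (cubes_dir / "split.json").write_text(
        json.dumps(
            {"train_ids": split.train_ids, "test_ids": split.test_ids, "fold_assignment": split.fold_assignment},
            indent=2,
        )
    )
    sample_manifest.to_csv(cubes_dir / "manifest.csv", index=False)
    arrays = {f"{pid}__{ph}__global": arr for (pid, ph), arr in store._global.items()}
    arrays.update({f"{pid}__{ph}__local32": arr for (pid, ph), arr in store._local32.items()})
    np.savez_compressed(cubes_dir / "cubes.npz", **arrays)
    manifest.mark("preprocess", n_train=len(split.train_ids), n_test=len(split.test_ids))
    log.info("preprocess: %d train / %d test patients", len(split.train_ids), len(split.test_ids))


def load_cubes(outdir: Path) -> tuple[CubeStore, pd.DataFrame, SplitPlan]:
    cubes_dir = Path(outdir) / "cubes"
    if not (cubes_dir / "cubes.npz").exists():
        raise FileNotFoundError(f"missing cube archive in {cubes_dir}: run the preprocess stage first")
    sample_manifest = pd.read_csv(cubes_dir / "manifest.csv")
    sp = json.loads((cubes_dir / "split.json").read_text())
    split = SplitPlan(sp["train_ids"], sp["test_ids"], {k: int(v) for k, v in sp["fold_assignment"].items()})
    store = CubeStore()
    labels = dict(zip(sample_manifest["patient_id"], sample_manifest["label"]))
    store.labels = {str(k): int(v) for k, v in labels.items()}
    with np.load(cubes_dir / "cubes.npz") as z:
        for key in z.files:
            pid, ph, kind = key.split("__")
            target = store._global if kind == "global" else store._local32
            target[(pid, ph)] = z[key]
    return store, sample_manifest, split


def stage_train(
    cfg: dict, outdir: Path, phases: Sequence[str] | None = None, force: bool = False
) -> list[FoldModel]:
    manifest = RunManifest(outdir)
    ncfg = _network_config(cfg, phases)
    name = model_name(ncfg.phases)
    model_dir = outdir / "models" / name
    stage_key = f"train:{name}"
    if manifest.done(stage_key) and model_dir.exists() and not force:
        log.info("train[%s]: already complete, skipping", name)
        return load_fold_models(outdir, ncfg)
    store, sample_manifest, split = load_cubes(outdir)
    tcfg = _train_config(cfg)
    model_dir.mkdir(parents=True, exist_ok=True)
    fold_models = []
    for fold in range(cfg["split"]["n_folds"]):
        t0 = time.time()
        fm = train_fold(store, sample_manifest, fold, ncfg, tcfg)
        fold_models.append(fm)
        model = build_network(ncfg)
        model.load_state_dict(fm.state_dict)
        save_checkpoint(model, ncfg, model_dir / f"fold{fold}.npz")
        fm.curve.to_csv(model_dir / f"fold{fold}_curve.csv", index=False)
        log.info(
            "train[%s] fold %d: stopped at step %d, best val loss %.4f (%.1fs)",
            name, fold, fm.stopped_step, fm.best_val_loss, time.time() - t0,
        )
    manifest.mark(stage_key, seed=tcfg.seed)
    return fold_models


def load_fold_models(outdir: Path, ncfg: NetworkConfig) -> list[FoldModel]:
    name = model_name(ncfg.phases)
    model_dir = Path(outdir) / "models" / name
    fold_models = []
    for fold in range(100):
        path = model_dir / f"fold{fold}.npz"
        if not path.exists():
            break
        model, loaded_cfg = load_checkpoint(path)
        curve_path = model_dir / f"fold{fold}_curve.csv"
        curve = pd.read_csv(curve_path) if curve_path.exists() else pd.DataFrame()
        fold_models.append(FoldModel(fold, loaded_cfg, model.state_dict(), curve, -1, float("nan")))
    if not fold_models:
        raise FileNotFoundError(f"missing checkpoints under {model_dir}: run the train stage first")
    return fold_models


def stage_evaluate(cfg: dict, outdir: Path, force: bool = False) -> pd.DataFrame:
    manifest = RunManifest(outdir)
    metrics_dir = outdir / "metrics"
    if manifest.done("evaluate") and (metrics_dir / "metrics.csv").exists() and not force:
        log.info("evaluate: already complete, skipping")
        return pd.read_csv(metrics_dir / "metrics.csv")
    store, _, split = load_cubes(outdir)
    models_root = outdir / "models"
    if not models_root.exists():
        raise FileNotFoundError(f"missing checkpoints under {models_root}: run the train stage first")
    labels = np.array([store.labels[p] for p in split.test_ids])
    scores: dict[str, np.ndarray] = {}
    for model_dir in sorted(models_root.iterdir()):
        _, ncfg = load_checkpoint(model_dir / "fold0.npz")
        fms = load_fold_models(outdir, ncfg)
        scores[model_dir.name] = ensemble_predict(fms, store, split.test_ids)
    metrics_dir.mkdir(parents=True, exist_ok=True)
    ev = cfg["evaluate"]
    table = compare_models(scores, labels, n_boot=ev["n_boot"], seed=cfg["split"]["seed"])
    table.to_csv(metrics_dir / "metrics.csv", index=False)
    (metrics_dir / "report.txt").write_text(format_report(table) + "\n")
    start, stop, step = ev["dca_grid"]
    grid = np.arange(start, stop + step / 2, step)
    score_table = pd.DataFrame({"patient_id": split.test_ids, "label": labels, **scores})
    score_table.to_csv(metrics_dir / "test_scores.csv", index=False)
    for name, s in scores.items():
        r = roc_auc(s, labels, n_boot=ev["n_boot"], seed=cfg["split"]["seed"], threshold=ev["threshold"])
        pd.DataFrame({"fpr": r.fpr, "tpr": r.tpr}).to_csv(metrics_dir / f"roc_{name}.csv", index=False)
        d = net_benefit(s, labels, grid)
        pd.DataFrame(
            {"threshold": d.thresholds, "net_benefit": d.net_benefit,
             "treat_all": d.treat_all, "treat_none": d.treat_none}
        ).to_csv(metrics_dir / f"dca_{name}.csv", index=False)
    _plot_roc_dca(scores, labels, grid, metrics_dir)
    manifest.mark("evaluate", models=sorted(scores))
    log.info("evaluate: wrote metrics for %d models\n%s", len(scores), format_report(table))
    return table


def _plot_roc_dca(scores: dict[str, np.ndarray], labels: np.ndarray, grid: np.ndarray, metrics_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    for name, s in scores.items():
        r = roc_auc(s, labels, n_boot=10)
        ax1.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.2f})")
        d = net_benefit(s, labels, grid)
        ax2.plot(d.thresholds, d.net_benefit, label=name)
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set(xlabel="1 - specificity", ylabel="sensitivity", title="ROC")
    ax1.legend(fontsize=8)
    d0 = net_benefit(next(iter(scores.values())), labels, grid)
    ax2.plot(d0.thresholds, d0.treat_all, "k--", lw=0.8, label="treat all")
    ax2.plot(d0.thresholds, d0.treat_none, "k:", lw=0.8, label="treat none")
    ax2.set(xlabel="threshold probability", ylabel="net benefit", title="Decision curves")
    ax2.set_ylim(bottom=-0.1)
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(metrics_dir / "roc_dca.png", dpi=120)
    plt.close(fig)


def stage_explain(cfg: dict, outdir: Path, force: bool = False) -> pd.DataFrame | None:
    import nibabel as nib

    manifest = RunManifest(outdir)
    sal_dir = outdir / "saliency"
    if manifest.done("explain") and sal_dir.exists() and not force:
        log.info("explain: already complete, skipping")
        return None
    store, _, split = load_cubes(outdir)
    roster = pd.read_csv(outdir / "phantom" / "roster.csv")
    models_root = outdir / "models"
    fusion_dirs = [d for d in sorted(models_root.iterdir()) if d.name.endswith("P") and d.name[0].isdigit()]
    if not fusion_dirs:
        raise FileNotFoundError("explain requires a trained fusion model (e.g. 4P)")
    model, ncfg = load_checkpoint(fusion_dirs[-1] / "fold0.npz")
    sal_dir.mkdir(parents=True, exist_ok=True)
    grid = phase_weight_heatmap(model)
    grid.to_csv(sal_dir / "phase_weights.csv", index=False)
    _plot_phase_weights(grid, sal_dir)
    ex = cfg["explain"]
    rows = []
    positives = [p for p in split.test_ids if store.labels[p] == 1][: ex["n_examples"]]
    roster_idx = roster.set_index("patient_id")
    for pid in positives:
        cubes = {ph: store.get_cube(pid, ph, "global", (0, 0, 0))[None] for ph in ncfg.phases}
        mask = np.asarray(nib.load(str(roster_idx.loc[pid, "mask_path"])).dataobj) > 0
        bbox = mask_to_bbox(mask)
        region = margin_shell_region(mask, bbox, ex["shell_inner"], ex["shell_outer"])
        for phase in ncfg.phases:
            sal = grad_cam(model, cubes, ex["layer"], phase, target_class=1)
            nib.save(
                nib.Nifti1Image(sal.heatmap.astype(np.float32), np.eye(4)),
                sal_dir / f"{pid}_{phase}_{ex['layer']}.nii.gz",
            )
            _plot_overlay(cubes[phase][0], sal.heatmap, sal_dir / f"{pid}_{phase}_{ex['layer']}.png")
            rows.append(
                {
                    "patient_id": pid,
                    "phase": phase,
                    "layer": ex["layer"],
                    "mass_fraction_margin_shell": attention_mass_fraction(sal, region),
                    "permutation_null": permutation_null_fraction(region),
                }
            )
    frac = pd.DataFrame(rows)
    frac.to_csv(sal_dir / "attention_mass_fractions.csv", index=False)
    manifest.mark("explain", n_examples=len(positives))
    log.info("explain: wrote saliency for %d positive test patients", len(positives))
    return frac


def _plot_overlay(cube: np.ndarray, heatmap: np.ndarray, path: Path) -> None:
    """Three orthogonal mid-slices of the cube with the heatmap overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = cube.shape[0] // 2
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, axis in zip(axes, range(3)):
        img = np.take(cube, mid, axis=axis)
        heat = np.take(heatmap, mid, axis=axis)
        ax.imshow(img, cmap="gray")
        ax.imshow(heat, cmap="jet", alpha=0.4, vmin=0, vmax=1)
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_phase_weights(grid: pd.DataFrame, sal_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phases = list(dict.fromkeys(grid["phase"]))
    mat = np.stack([grid[grid["phase"] == p]["weight"].to_numpy() for p in phases])
    fig, ax = plt.subplots(figsize=(8, 2 + 0.4 * len(phases)))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(phases)), phases)
    ax.set_xlabel("feature index (32 per phase)")
    fig.colorbar(im, ax=ax, label="|weight|")
    fig.tight_layout()
    fig.savefig(sal_dir / "phase_weights.png", dpi=120)
    plt.close(fig)


def run_all(cfg: dict, outdir: Path, phases_list: Sequence[Sequence[str]] | None = None, force: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    stage_simulate(cfg, outdir, force)
    stage_preprocess(cfg, outdir, force)
    for phases in phases_list or [cfg["network"]["phases"]]:
        stage_train(cfg, outdir, phases, force)
    stage_evaluate(cfg, outdir, force)
    if any(len(p) > 1 for p in (phases_list or [cfg["network"]["phases"]])):
        stage_explain(cfg, outdir, force)
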