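"""Training: weighted multi-phase loss, momentum SGD, 5-fold CV, ensembling.

The default optimization recipe: batch size 16, momentum SGD (lr 0.004,
momentum 0.9, weight decay 1e-4), an epoch budget of 50 and a hard cap of
501 optimizer steps per fold — whichever binds first (at full augmentation
scale, 122,640 samples per phase, the step cap always binds), plus early
stopping on validation loss.

The classification loss is a weighted sum of per-phase cross-entropies,
``L = sum_x w_x * CE_x``.  Single-phase models have one term; fusion models
attach a lightweight auxiliary two-way head to each phase's 32-d feature to
carry its term, and the fused head's cross-entropy is added with weight 1.
The weights ``w_x`` are normalized to sum to one, so an uninformed model
(all heads at (0.5, 0.5)) scores exactly ln 2 on the per-phase part.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .nn.autodiff import Tensor, cross_entropy
from .nn.layers import SGD, Module
from .nn.network import NetworkConfig, build_network
from .preprocess import CubeStore


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 50
    max_iterations: int = 501
    lr: float = 0.004
    momentum: float = 0.9
    weight_decay: float = 1e-4
    loss_weights: tuple[float, ...] | None = None  # per phase; None = equal
    fused_head_weight: float = 1.0
    early_stop_patience: int = 5  # evaluation rounds without val-loss improvement
    eval_interval: int | None = None  # steps between validations; None = once per epoch
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "max_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lr < 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("lr, momentum and weight_decay must be >= 0")
        if self.loss_weights is not None and any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss_weights must be positive")


def normalized_loss_weights(cfg_weights: Sequence[float] | None, phases: Sequence[str]) -> dict[str, float]:
    if cfg_weights is None:
        w = np.ones(len(phases))
    else:
        if len(cfg_weights) != len(phases):
            raise ValueError(f"need one loss weight per phase ({len(phases)}), got {len(cfg_weights)}")
        w = np.asarray(cfg_weights, dtype=float)
    w = w / w.sum()
    return dict(zip(phases, w.tolist()))


def multi_phase_loss(
    aux_logits: Mapping[str, Tensor], labels: np.ndarray, weights: Mapping[str, float]
) -> Tensor:
    """Weighted sum of per-phase cross-entropies; weights are normalized."""
    total = sum(weights.values())
    loss: Tensor | None = None
    for phase, logits in aux_logits.items():
        term = cross_entropy(logits, labels) * (weights[phase] / total)
        loss = term if loss is None else loss + term
    assert loss is not None, "no phase logits given"
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite loss {loss.data!r}; inspect inputs and learning rate")
    return loss


def _training_loss(model_out, labels: np.ndarray, weights: Mapping[str, float], fused_w: float) -> Tensor:
    loss = multi_phase_loss(model_out.aux_logits, labels, weights)
    if len(model_out.aux_logits) > 1 and fused_w > 0:
        loss = loss + cross_entropy(model_out.logits, labels) * fused_w
    return loss


@dataclasses.dataclass
class FoldModel:
    """One cross-validation fold's trained weights and learning curve."""

    fold: int
    network_config: NetworkConfig
    state_dict: dict[str, np.ndarray]
    curve: pd.DataFrame  # step, train_loss, val_loss, val_auc
    stopped_step: int
    best_val_loss: float

    def build(self) -> Module:
        model = build_network(self.network_config)
        model.load_state_dict(self.state_dict)
        return model.eval()


def predict_proba(model: Module, store: CubeStore, patient_ids: Sequence[str], batch_size: int = 16) -> np.ndarray:
    """MVI-positive probability per patient from the global 16^3 cubes."""
    model.eval()
    phases = model.cfg.phases
    out = np.empty(len(patient_ids))
    for start in range(0, len(patient_ids), batch_size):
        chunk = list(patient_ids[start : start + batch_size])
        cubes = {
            ph: np.stack([store.get_cube(pid, ph, "global", (0, 0, 0)) for pid in chunk])
            for ph in phases
        }
        out[start : start + len(chunk)] = model(cubes).probs[:, 1]
    return out


def train_fold(
    store: CubeStore,
    manifest: pd.DataFrame,
    fold: int,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> FoldModel:
    """Train one CV fold; returns the best-validation-loss checkpoint.

    Deterministic for a fixed (seed, fold): model init, batch order and
    dropout all derive from counter-based substreams of the fold seed.
    """
    train_rows = manifest[(manifest["side"] == "train") & (manifest["fold"] != fold)].reset_index(drop=True)
    val_ids = (
        manifest[(manifest["side"] == "train") & (manifest["fold"] == fold)]["patient_id"].unique().tolist()
    )
    if len(train_rows) == 0 or len(val_ids) == 0:
        raise ValueError(f"fold {fold} has an empty train or validation side")
    val_labels = np.array([store.labels[p] for p in val_ids])
    if len(np.unique(val_labels)) < 2:
        raise ValueError(f"validation fold {fold} contains a single class; cannot monitor AUC")

    ss = np.random.SeedSequence(entropy=train_cfg.seed, spawn_key=(fold,))
    init_seed, order_seed, drop_seed = (int(s) % (2**31) for s in ss.generate_state(3))
    model = build_network(net_cfg, seed=init_seed)
    for i, m in enumerate(model.modules()):
        if hasattr(m, "rng") and isinstance(getattr(m, "rng"), np.random.Generator):
            m.rng = np.random.default_rng([drop_seed, i])
    order_rng = np.random.default_rng(order_seed)
    weights = normalized_loss_weights(train_cfg.loss_weights, net_cfg.phases)
    opt = SGD(model.parameters(), train_cfg.lr, train_cfg.momentum, train_cfg.weight_decay)

    n = len(train_rows)
    steps_per_epoch = math.ceil(n / train_cfg.batch_size)
    total_steps = min(train_cfg.epochs * steps_per_epoch, train_cfg.max_iterations)
    eval_interval = train_cfg.eval_interval or min(steps_per_epoch, total_steps)

    phases = net_cfg.phases

    def validate() -> tuple[float, float]:
        model.eval()
        losses, probs = [], []
        for start in range(0, len(val_ids), train_cfg.batch_size):
            chunk = val_ids[start : start + train_cfg.batch_size]
            cubes = {
                ph: np.stack([store.get_cube(p, ph, "global", (0, 0, 0)) for p in chunk])
                for ph in phases
            }
            out = model(cubes)
            y = np.array([store.labels[p] for p in chunk])
            losses.append(float(_training_loss(out, y, weights, train_cfg.fused_head_weight).data) * len(chunk))
            probs.append(out.probs[:, 1])
        vloss = float(np.sum(losses) / len(val_ids))
        vauc = float(roc_auc_score(val_labels, np.concatenate(probs)))
        model.train()
        return vloss, vauc

    perm = order_rng.permutation(n)
    cursor = 0
    running: list[float] = []
    records = []
    best_val = math.inf
    best_state = model.state_dict()
    stale = 0
    step = 0
    model.train()
    while step < total_steps:
        if cursor + train_cfg.batch_size > n:
            perm = order_rng.permutation(n)
            cursor = 0
        idx = perm[cursor : cursor + train_cfg.batch_size]
        cursor += train_cfg.batch_size
        rows = train_rows.iloc[idx]
        labels = rows["label"].to_numpy()
        cubes = {
            ph: np.stack(
                [store.get_cube(r.patient_id, ph, r.kind, (r.off_i, r.off_j, r.off_k)) for r in rows.itertuples()]
            )
            for ph in phases
        }
        model.zero_grad()
        loss = _training_loss(model(cubes), labels, weights, train_cfg.fused_head_weight)
        loss.backward()
        opt.step()
        running.append(float(loss.data))
        step += 1
        if step % eval_interval == 0 or step == total_steps:
            vloss, vauc = validate()
            records.append((step, float(np.mean(running)), vloss, vauc))
            running.clear()
            if vloss < best_val - 1e-9:
                best_val, best_state, stale = vloss, model.state_dict(), 0
            else:
                stale += 1
                if stale >= train_cfg.early_stop_patience:
                    break
    curve = pd.DataFrame(records, columns=["step", "train_loss", "val_loss", "val_auc"])
    return FoldModel(fold, net_cfg, best_state, curve, step, best_val)


def train_cv(
    store: CubeStore,
    manifest: pd.DataFrame,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    n_folds: int = 5,
) -> list[FoldModel]:
    return [train_fold(store, manifest, f, net_cfg, train_cfg) for f in range(n_folds)]


def ensemble_predict(
    fold_models: Sequence[FoldModel], store: CubeStore, patient_ids: Sequence[str]
) -> np.ndarray:
    """Average the fold models' MVI-positive probabilities per test patient."""
    if len(fold_models) == 0:
        raise ValueError("no fold models given")
    cfgs = {fm.network_config for fm in fold_models}
    if len(cfgs) > 1:
        raise ValueError("fold models were trained with differing network configs")
    probs = np.stack([predict_proba(fm.build(), store, patient_ids) for fm in fold_models])
    return probs.mean(axis=0)
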