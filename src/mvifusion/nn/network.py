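"""Single-phase and multi-phase attention networks.

The backbone is a LeNet5-style 3D CNN for 16^3 intensity cubes: three small
convolution stages interleaved with 2x2x2 max pooling.  A self-attention
block sits between the last convolution stage and the last pooling layer
(N = 4^3 = 64 spatial positions); in fusion models a collaborative-attention
block follows it, letting each phase's map query the other phases before
pooling.  Each phase branch ends in a 32-d feature vector; fusion models
concatenate the per-phase features into a |phases| x 32 vector feeding the
final two-way softmax head, with a lightweight auxiliary two-way head per
phase to carry the per-phase terms of the weighted multi-phase loss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..phantom import PHASES
from .autodiff import Tensor, concat, softmax
from .attention import AttentionBlockOutput, CollaborativeAttention3d, SelfAttention3d
from .layers import Conv3d, Dropout, Linear, MaxPool3d, Module

CUBE_SIZE = 16


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    phases: tuple[str, ...] = PHASES
    conv_channels: tuple[int, int, int] = (6, 16, 16)
    fc_feature_dim_per_phase: int = 32
    dropout_rate: float = 0.5
    attention_gamma_init: float = 0.0
    attention_d_qk: int = 2

    def __post_init__(self) -> None:
        if not (1 <= len(self.phases) <= 4):
            raise ValueError("phases must name 1 to 4 phases")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)} (choose from {PHASES})")
        if self.fc_feature_dim_per_phase < 1:
            raise ValueError("fc_feature_dim_per_phase must be >= 1")

    @property
    def is_fusion(self) -> bool:
        return len(self.phases) > 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["phases"] = tuple(d["phases"])
        d["conv_channels"] = tuple(d["conv_channels"])
        return NetworkConfig(**d)


@dataclasses.dataclass
class ForwardResult:
    """Everything a forward pass exposes, for training and interpretability."""

    probs: np.ndarray  # (B, 2) softmax probabilities of the final head
    logits: Tensor  # (B, 2) final-head logits
    aux_logits: dict[str, Tensor]  # per-phase head logits (single-phase: the only head)
    features: dict[str, Tensor]  # per-phase 32-d feature segments
    self_attention: dict[str, AttentionBlockOutput]
    collaborative_attention: dict[str, AttentionBlockOutput]  # empty for single-phase
    attention_inputs: dict[str, Tensor]  # conv-stage map entering the attention band


class PhaseBranch(Module):
    """Conv stem -> self-attention for one phase; shared layout across phases."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = cfg.conv_channels
        self.conv1 = Conv3d(1, c1, rng)
        self.conv2 = Conv3d(c1, c2, rng)
        self.conv3 = Conv3d(c2, c3, rng)
        self.pool = MaxPool3d(2)
        self.self_attn = SelfAttention3d(c3, cfg.attention_d_qk, rng, cfg.attention_gamma_init)
        self.fc1 = Linear(c3 * (CUBE_SIZE // 8) ** 3, cfg.fc_feature_dim_per_phase, rng)
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self._c3 = c3

    def stem(self, x: Tensor) -> tuple[Tensor, AttentionBlockOutput]:
        """16^3 cube -> self-attended (B, C, 64) map at the 4^3 stage."""
        if x.data.ndim != 5 or x.data.shape[2:] != (CUBE_SIZE,) * 3:
            raise ValueError(f"expected input (B, 1, 16, 16, 16), got {x.data.shape}")
        h = self.pool(self.conv1(x).relu())  # 8^3
        h = self.pool(self.conv2(h).relu())  # 4^3
        h = self.conv3(h).relu()  # (B, C, 4, 4, 4)
        B, C = h.data.shape[:2]
        flat = h.reshape(B, C, 64)
        return flat, self.self_attn(flat)

    def head_features(self, attended: Tensor) -> Tensor:
        """Attended (B, C, 64) map -> pooled, flattened 32-d phase feature."""
        B, C = attended.data.shape[:2]
        h = self.pool(attended.reshape(B, C, 4, 4, 4))  # 2^3
        h = self.fc1(h.reshape(B, C * 8)).relu()
        return self.dropout(h)


class SinglePhaseNet(Module):
    """Backbone + self-attention for one phase, two-way softmax output."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        if cfg.is_fusion:
            raise ValueError("SinglePhaseNet requires a single-phase NetworkConfig")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branch = PhaseBranch(cfg, rng)
        self.head = Linear(cfg.fc_feature_dim_per_phase, 2, rng)

    def forward(self, cubes: Mapping[str, np.ndarray] | np.ndarray) -> ForwardResult:
        phase = self.cfg.phases[0]
        x = cubes[phase] if isinstance(cubes, Mapping) else cubes
        xt = Tensor(_as_batch(x))
        flat, sa = self.branch.stem(xt)
        feat = self.branch.head_features(sa.features)
        logits = self.head(feat)
        return ForwardResult(
            probs=softmax(logits, axis=-1).data,
            logits=logits,
            aux_logits={phase: logits},
            features={phase: feat},
            self_attention={phase: sa},
            collaborative_attention={},
            attention_inputs={phase: flat},
        )

    __call__ = forward


class FusionNet(Module):
    """Attention-guided multi-phase feature-fusion network (2-4 phases)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        if not cfg.is_fusion:
            raise ValueError("FusionNet requires >= 2 phases; use SinglePhaseNet for one")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c3 = cfg.conv_channels[2]
        self.branches = {p: PhaseBranch(cfg, rng) for p in cfg.phases}
        self.collab = {
            p: CollaborativeAttention3d(c3, cfg.attention_d_qk, rng, cfg.attention_gamma_init)
            for p in cfg.phases
        }
        self.aux_heads = {p: Linear(cfg.fc_feature_dim_per_phase, 2, rng) for p in cfg.phases}
        self.fusion_head = Linear(len(cfg.phases) * cfg.fc_feature_dim_per_phase, 2, rng)

    def forward(self, cubes: Mapping[str, np.ndarray]) -> ForwardResult:
        missing = [p for p in self.cfg.phases if p not in cubes]
        if missing:
            raise ValueError(f"missing cubes for phases: {missing}")
        flats: dict[str, Tensor] = {}
        selfs: dict[str, AttentionBlockOutput] = {}
        for p in self.cfg.phases:
            flat, sa = self.branches[p].stem(Tensor(_as_batch(cubes[p])))
            flats[p], selfs[p] = flat, sa
        collabs: dict[str, AttentionBlockOutput] = {}
        feats: dict[str, Tensor] = {}
        aux_logits: dict[str, Tensor] = {}
        for p in self.cfg.phases:
            others = [selfs[q].features for q in self.cfg.phases if q != p]
            ca = self.collab[p](selfs[p].features, others)
            collabs[p] = ca
            feat = self.branches[p].head_features(ca.features)
            feats[p] = feat
            aux_logits[p] = self.aux_heads[p](feat)
        fused = concat([feats[p] for p in self.cfg.phases], axis=-1)
        logits = self.fusion_head(fused)
        return ForwardResult(
            probs=softmax(logits, axis=-1).data,
            logits=logits,
            aux_logits=aux_logits,
            features=feats,
            self_attention=selfs,
            collaborative_attention=collabs,
            attention_inputs=flats,
        )

    __call__ = forward


def build_network(cfg: NetworkConfig, seed: int = 0) -> Module:
    return FusionNet(cfg, seed) if cfg.is_fusion else SinglePhaseNet(cfg, seed)


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    if x.ndim == 4:
        x = x[:, None]
    return x


def save_checkpoint(model: Module, cfg: NetworkConfig, path: str | Path) -> None:
    """Weights as .npz next to a JSON architecture snapshot."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(cfg.to_json())


def load_checkpoint(path: str | Path, seed: int = 0) -> tuple[Module, NetworkConfig]:
    path = Path(path)
    cfg = NetworkConfig.from_json(path.with_suffix(".json").read_text())
    model = build_network(cfg, seed)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, cfg
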