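"""Interpretability: Grad-CAM on the attention blocks, per-phase FC weight
heatmaps, and a quantitative attention-localization statistic.

Grad-CAM here follows the classic recipe on the attention block's *output
feature map*: channel weights are the spatial average of the target-class
logit's gradient at that layer, the CAM is the rectified weighted channel
sum, upsampled trilinearly to cube resolution and min-max normalized to
[0, 1].  The raw N x N attention coefficient matrices are available from any
forward pass (``ForwardResult``) for direct inspection.

The phase-weight heatmap summarizes the fused head's first fully connected
layer: the mean absolute weight attached to each of the 32 features of each
phase segment — the phase whose grid carries the most weight contributes most
to the fused prediction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .nn.autodiff import Tensor
from .nn.network import CUBE_SIZE, ForwardResult, FusionNet, Module
from .preprocess import BoundingBox

LAYER_TAGS = ("self_attention", "collaborative_attention")


@dataclasses.dataclass
class SaliencyVolume:
    heatmap: np.ndarray  # (16, 16, 16) in [0, 1]
    raw: np.ndarray  # un-normalized CAM at the attention-stage resolution
    layer: str
    phase: str
    target_class: int


def grad_cam(
    model: Module,
    cubes: Mapping[str, np.ndarray] | np.ndarray,
    layer: str = "self_attention",
    phase: str | None = None,
    target_class: int = 1,
) -> SaliencyVolume:
    """Gradient-weighted class activation map at an attention block's output."""
    if layer not in LAYER_TAGS:
        raise ValueError(f"layer must be one of {LAYER_TAGS}")
    model.eval()
    model.zero_grad()
    phase = phase or model.cfg.phases[0]
    if phase not in model.cfg.phases:
        raise ValueError(f"model has no phase {phase!r}")
    res: ForwardResult = model(cubes)
    blocks = res.self_attention if layer == "self_attention" else res.collaborative_attention
    if phase not in blocks:
        raise ValueError(f"{layer} layer does not exist for phase {phase!r} in this model variant")
    feat = blocks[phase].features  # (B, C, N)
    onehot = np.zeros_like(res.logits.data)
    onehot[:, target_class] = 1.0
    (res.logits * Tensor(onehot)).sum().backward()
    grad = feat.grad
    act = feat.data
    weights = grad.mean(axis=2, keepdims=True)  # (B, C, 1): spatially averaged gradients
    cam = np.maximum((weights * act).sum(axis=1), 0.0)[0]  # (N,), first sample
    side = round(cam.size ** (1.0 / 3.0))
    cam3 = cam.reshape(side, side, side)
    up = _sk_resize(cam3.astype(np.float64), (CUBE_SIZE,) * 3, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    up = np.maximum(up, 0.0)
    peak = up.max()
    heat = up / peak if peak > 0 else np.zeros_like(up)
    return SaliencyVolume(heatmap=heat, raw=cam3, layer=layer, phase=phase, target_class=target_class)


def saliency_to_study_space(
    saliency: SaliencyVolume, bbox: BoundingBox, volume_shape: tuple[int, int, int]
) -> np.ndarray:
    """Paste a cube-grid heatmap back into study coordinates through the bbox."""
    block = _sk_resize(saliency.heatmap, bbox.shape, order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    out = np.zeros(volume_shape)
    sl = tuple(slice(l, h) for l, h in zip(bbox.lo, bbox.hi))
    out[sl] = block
    return out


def phase_weight_heatmap(model: Module) -> pd.DataFrame:
    """Fused-head weight magnitudes grouped into per-phase grids of 32.

    Rows: (phase, index, weight) with weight = mean |W| over the two output
    units for that feature.  Only meaningful for fusion models.
    """
    if not isinstance(model, FusionNet):
        raise ValueError("phase weight heatmap requires a multi-phase fusion model")
    W = np.abs(model.fusion_head.weight.data).mean(axis=1)  # (|phases| * fc_dim,)
    d = model.cfg.fc_feature_dim_per_phase
    rows = []
    for i, phase in enumerate(model.cfg.phases):
        seg = W[i * d : (i + 1) * d]
        rows.extend({"phase": phase, "index": j, "weight": float(w)} for j, w in enumerate(seg))
    return pd.DataFrame(rows)


def phase_mean_weights(model: Module) -> dict[str, float]:
    grid = phase_weight_heatmap(model)
    return grid.groupby("phase", sort=False)["weight"].mean().to_dict()


def attention_mass_fraction(saliency: SaliencyVolume | np.ndarray, region: np.ndarray) -> float:
    """Share of total heatmap mass inside ``region``; NaN if the map is all zero."""
    heat = saliency.heatmap if isinstance(saliency, SaliencyVolume) else np.asarray(saliency)
    region = np.asarray(region, dtype=bool)
    if heat.shape != region.shape:
        raise ValueError(f"heatmap shape {heat.shape} != region shape {region.shape}")
    total = float(heat.sum())
    if total == 0.0:
        return float("nan")
    return float(heat[region].sum() / total)


def margin_shell_region(
    mask: np.ndarray, bbox: BoundingBox, inner: int = 2, outer: int = 2
) -> np.ndarray:
    """Tumor-margin band (inside) plus peritumoral shell (outside) on the cube grid.

    The study-space mask is cropped to the bbox, resampled to 16^3 (nearest
    neighbour) and the band of voxels within ``inner`` of the boundary on the
    tumor side or ``outer`` on the parenchyma side is returned.
    """
    m = bbox.crop(np.asarray(mask) > 0)
    m16 = _sk_resize(m.astype(float), (CUBE_SIZE,) * 3, order=0, preserve_range=True) > 0.5
    if not m16.any() or m16.all():
        raise ValueError("resampled mask is degenerate (empty or full cube)")
    d_out = ndimage.distance_transform_edt(~m16)
    d_in = ndimage.distance_transform_edt(m16)
    return (~m16 & (d_out <= outer)) | (m16 & (d_in <= inner))


def permutation_null_fraction(region: np.ndarray) -> float:
    """Expected attention-mass fraction if heatmap voxels were randomly permuted."""
    return float(np.asarray(region, dtype=bool).mean())
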