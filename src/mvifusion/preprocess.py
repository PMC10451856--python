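"""From studies to model-ready cubes.

The pipeline mirrors standard tumor-cube preprocessing for volumetric CNNs:

1. a tight bounding box around the tumor mask, expanded by 2 voxels to take in
   the peritumoral area, then extended to a cube;
2. a *global* cube: the boxed region resampled to 16^3 (train and test);
3. *local* cubes (training-time augmentation only): the boxed region resampled
   to 32^3 and cut into 16^3 sub-cubes on a stride-2 offset grid — 9 offsets
   per axis, 729 cubes per tumor per phase;
4. a stratified 4:1 train/test split with stratified 5-fold assignment on the
   training side.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import StratifiedKFold, train_test_split

from .phantom import PHASES, MultiPhaseStudy

GLOBAL_SIZE = 16
LOCAL_RESAMPLE_SIZE = 32
LOCAL_CUT_SIZE = 16
LOCAL_STRIDE = 2


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Half-open, 0-based voxel box: ``lo`` inclusive, ``hi`` exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate bounding box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def crop(self, volume: np.ndarray) -> np.ndarray:
        sl = tuple(slice(l, h) for l, h in zip(self.lo, self.hi))
        return volume[sl]


@dataclasses.dataclass
class CubicRegion:
    """A 16^3 single-phase intensity cube with provenance."""

    patient_id: str
    phase: str
    kind: str  # "global" | "local"
    data: np.ndarray
    offset: tuple[int, int, int]
    label: int

    def __post_init__(self) -> None:
        # default pipeline geometry is 16^3; non-default cut sizes stay cubic
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"cube data must be cubic, got {self.data.shape}")


def mask_to_bbox(mask: np.ndarray, margin: int = 2, cubify: bool = True) -> BoundingBox:
    """Tight foreground box, dilated by ``margin`` voxels per side and clamped.

    With ``cubify`` the shorter axes are extended symmetrically to the longest
    axis length (again clamped at the volume border) so the extracted region is
    cubic.
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise ValueError("mask is empty: cannot derive a bounding box")
    idx = np.nonzero(fg)
    lo = np.array([int(a.min()) - margin for a in idx])
    hi = np.array([int(a.max()) + 1 + margin for a in idx])
    shape = np.asarray(mask.shape)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if cubify:
        target = int((hi - lo).max())
        for ax in range(3):
            extra = target - (hi[ax] - lo[ax])
            if extra <= 0:
                continue
            lo[ax] = max(0, lo[ax] - extra // 2)
            hi[ax] = min(int(shape[ax]), lo[ax] + target)
            lo[ax] = max(0, hi[ax] - target)  # re-extend low side if high side clamped
    return BoundingBox(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


def _resample(block: np.ndarray, size: int) -> np.ndarray:
    if any(s < 2 for s in block.shape):
        raise ValueError(f"region {block.shape} too small to resample (every side must be >= 2)")
    if block.shape == (size,) * 3:
        return block.astype(np.float64)
    return _sk_resize(
        block.astype(np.float64), (size,) * 3, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def zscore(cube: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-cube intensity normalization to zero mean / unit sd (flat cube -> zeros)."""
    sd = float(cube.std())
    if sd < eps:
        return np.zeros_like(cube, dtype=np.float64)
    return (cube - float(cube.mean())) / sd


def extract_global_cube(
    volume: np.ndarray, bbox: BoundingBox, *, patient_id: str = "", phase: str = "", label: int = 0
) -> CubicRegion:
    """Crop the box and trilinearly resample to the 16^3 global cube."""
    data = _resample(bbox.crop(volume), GLOBAL_SIZE)
    return CubicRegion(patient_id, phase, "global", data, (0, 0, 0), label)


def local_offsets(
    resample_size: int = LOCAL_RESAMPLE_SIZE, cut_size: int = LOCAL_CUT_SIZE, stride: int = LOCAL_STRIDE
) -> np.ndarray:
    """Per-axis corner offsets of the sliding-cut grid: 0, stride, ..., R - c."""
    return np.arange(0, resample_size - cut_size + 1, stride)


def augment_local_cubes(
    volume: np.ndarray,
    bbox: BoundingBox,
    *,
    patient_id: str = "",
    phase: str = "",
    label: int = 0,
    resample_size: int = LOCAL_RESAMPLE_SIZE,
    cut_size: int = LOCAL_CUT_SIZE,
    stride: int = LOCAL_STRIDE,
) -> list[CubicRegion]:
    """Stride-``stride`` sliding-window cut of the ``resample_size``^3 region.

    At the default (32, 16, 2) geometry this yields 9 offsets per axis and
    729 local cubes, each inheriting the patient's label.
    """
    big = _resample(bbox.crop(volume), resample_size)
    offs = local_offsets(resample_size, cut_size, stride)
    cubes = []
    for i in offs:
        for j in offs:
            for k in offs:
                data = big[i : i + cut_size, j : j + cut_size, k : k + cut_size]
                cubes.append(CubicRegion(patient_id, phase, "local", np.array(data), (int(i), int(j), int(k)), label))
    return cubes


@dataclasses.dataclass
class SplitPlan:
    """Stratified 4:1 train/test partition with stratified fold assignment."""

    train_ids: list[str]
    test_ids: list[str]
    fold_assignment: dict[str, int]

    def fold_train_val(self, fold: int) -> tuple[list[str], list[str]]:
        val = [p for p in self.train_ids if self.fold_assignment[p] == fold]
        train = [p for p in self.train_ids if self.fold_assignment[p] != fold]
        return train, val


def make_split(roster: pd.DataFrame, test_fraction: float = 0.2, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified train/test split plus stratified K folds on the training side."""
    ids = roster["patient_id"].to_numpy()
    labels = roster["mvi_label"].to_numpy().astype(int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both MVI classes must be present to stratify the split")
    train_ids, test_ids, train_y, _ = train_test_split(
        ids, labels, test_size=test_fraction, stratify=labels, random_state=seed
    )
    counts = np.bincount(train_y)
    if counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} training patients per class, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(train_ids, train_y)):
        for i in val_idx:
            fold_assignment[str(train_ids[i])] = fold
    return SplitPlan([str(i) for i in train_ids], [str(i) for i in test_ids], fold_assignment)


def build_manifest(roster: pd.DataFrame, split: SplitPlan) -> pd.DataFrame:
    """Sample manifest: one row per (patient, kind, offset) cube position.

    Each row stands for one cube *per phase* (phases are co-registered and cut
    at identical offsets), so the row count of the training part equals the
    per-phase sample count: 729 local + 1 global cube per training patient,
    and 1 global cube per test patient (the test side is never augmented).
    """
    labels = dict(zip(roster["patient_id"].astype(str), roster["mvi_label"].astype(int)))
    missing = [p for p in split.train_ids + split.test_ids if p not in labels]
    if missing:
        raise ValueError(f"split references patients absent from roster: {missing[:5]}")
    rows = []
    offs = local_offsets()
    for pid in split.train_ids:
        rows.append((pid, "train", "global", 0, 0, 0, labels[pid], split.fold_assignment[pid]))
        for i in offs:
            for j in offs:
                for k in offs:
                    rows.append((pid, "train", "local", int(i), int(j), int(k), labels[pid], split.fold_assignment[pid]))
    for pid in split.test_ids:
        rows.append((pid, "test", "global", 0, 0, 0, labels[pid], -1))
    return pd.DataFrame(
        rows, columns=["patient_id", "side", "kind", "off_i", "off_j", "off_k", "label", "fold"]
    )


class CubeStore:
    """Normalized cube tensors for a set of studies, sliced lazily.

    Per patient and phase the store keeps the 16^3 global cube and (training
    side only) the 32^3 resampled region from which the 729 local cubes are
    cut on demand — local cubes are views into the 32^3 array, so the full
    augmented dataset is never materialized.  Every returned cube is z-scored.
    """

    def __init__(self, phases: Sequence[str] = PHASES, dtype=np.float32):
        self.phases = tuple(phases)
        self.dtype = dtype
        self._global: dict[tuple[str, str], np.ndarray] = {}
        self._local32: dict[tuple[str, str], np.ndarray] = {}
        self.labels: dict[str, int] = {}

    def add_study(self, study: MultiPhaseStudy, *, with_local: bool) -> None:
        bbox = mask_to_bbox(study.mask)
        self.labels[study.patient_id] = study.mvi_label
        for phase in self.phases:
            vol = study.volumes[phase]
            g = zscore(_resample(bbox.crop(vol), GLOBAL_SIZE)).astype(self.dtype)
            self._global[(study.patient_id, phase)] = g
            if with_local:
                self._local32[(study.patient_id, phase)] = _resample(bbox.crop(vol), LOCAL_RESAMPLE_SIZE).astype(
                    self.dtype
                )

    def get_cube(self, patient_id: str, phase: str, kind: str, offset: tuple[int, int, int]) -> np.ndarray:
        if kind == "global":
            return self._global[(patient_id, phase)]
        i, j, k = offset
        big = self._local32[(patient_id, phase)]
        cube = big[i : i + LOCAL_CUT_SIZE, j : j + LOCAL_CUT_SIZE, k : k + LOCAL_CUT_SIZE]
        return zscore(cube).astype(self.dtype)

    def get_sample(self, row: Mapping[str, object]) -> dict[str, np.ndarray]:
        offset = (int(row["off_i"]), int(row["off_j"]), int(row["off_k"]))
        return {ph: self.get_cube(str(row["patient_id"]), ph, str(row["kind"]), offset) for ph in self.phases}


def build_cube_store(
    studies: Iterable[MultiPhaseStudy], split: SplitPlan, phases: Sequence[str] = PHASES
) -> CubeStore:
    """Extract cubes for every study: train side gets global + 32^3 local source."""
    store = CubeStore(phases)
    train = set(split.train_ids)
    test = set(split.test_ids)
    for study in studies:
        if study.patient_id in train:
            store.add_study(study, with_local=True)
        elif study.patient_id in test:
            store.add_study(study, with_local=False)
    missing = (train | test) - set(store.labels)
    if missing:
        raise ValueError(f"studies missing for patients: {sorted(missing)[:5]}")
    return store
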