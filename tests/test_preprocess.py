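"""Bounding boxes, cube extraction, augmentation counts and splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvifusion.phantom import PhantomConfig, generate_study
from mvifusion.preprocess import (
    augment_local_cubes,
    build_cube_store,
    build_manifest,
    extract_global_cube,
    local_offsets,
    make_split,
    mask_to_bbox,
    zscore,
)


class TestBoundingBox:
    def test_point_mask_margin_arithmetic(self):
        mask = np.zeros((64, 64, 64), dtype=np.uint8)
        mask[10, 10, 10] = 1
        box = mask_to_bbox(mask, margin=2, cubify=False)
        assert box.lo == (8, 8, 8) and box.hi == (13, 13, 13)

    def test_corner_mask_is_clamped(self):
        mask = np.zeros((32, 32, 32), dtype=np.uint8)
        mask[0, 0, 0] = 1
        box = mask_to_bbox(mask, margin=2)
        assert box.lo == (0, 0, 0)
        assert all(h <= 32 for h in box.hi)

    def test_cubified_box_is_cubic_and_contains_margin(self):
        mask = np.zeros((64, 64, 64), dtype=np.uint8)
        mask[20:30, 25:28, 22:24] = 1
        box = mask_to_bbox(mask, margin=2)
        sides = box.shape
        assert len(set(sides)) == 1  # cubic
        assert sides[0] == (30 - 20) + 4  # longest extent + 2 per side

    def test_every_foreground_voxel_inside_box_for_random_phantoms(self):
        for seed in range(25):
            cfg = PhantomConfig(n_patients=1, volume_shape=(48, 48, 48), noise_sd=0.0, seed=seed)
            mask = generate_study(cfg, 0, seed % 2).mask
            box = mask_to_bbox(mask)
            fg = np.argwhere(mask > 0)
            assert (fg >= np.array(box.lo)).all() and (fg < np.array(box.hi)).all()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_bbox(np.zeros((8, 8, 8)))


class TestResampling:
    def test_constant_crop_resamples_to_constant(self):
        vol = np.full((40, 40, 40), 7.5)
        mask = np.zeros_like(vol)
        mask[10:20, 10:20, 10:20] = 1
        cube = extract_global_cube(vol, mask_to_bbox(mask))
        assert np.allclose(cube.data, 7.5)
        assert cube.kind == "global" and cube.offset == (0, 0, 0)

    def test_identity_resample_preserves_values(self, rng):
        vol = rng.standard_normal((40, 40, 40))
        mask = np.zeros((40, 40, 40))
        mask[12:24, 12:24, 12:24] = 1  # 12 + 2*2 margin = 16^3 box
        box = mask_to_bbox(mask)
        assert box.shape == (16, 16, 16)
        cube = extract_global_cube(vol, box)
        assert np.allclose(cube.data, box.crop(vol))

    def test_linear_ramp_stays_monotone_along_ramp_axis(self):
        vol = np.broadcast_to(np.arange(40, dtype=float)[:, None, None], (40, 40, 40)).copy()
        mask = np.zeros((40, 40, 40))
        mask[5:35, 5:35, 5:35] = 1
        cube = extract_global_cube(vol, mask_to_bbox(mask))
        diffs = np.diff(cube.data, axis=0)
        assert (diffs >= -1e-9).all() and diffs.max() > 0


class TestAugmentation:
    def test_default_geometry_yields_9_offsets_per_axis_and_729_cubes(self, rng):
        vol = rng.standard_normal((48, 48, 48))
        mask = np.zeros((48, 48, 48))
        mask[14:34, 14:34, 14:34] = 1
        cubes = augment_local_cubes(vol, mask_to_bbox(mask), patient_id="P0", phase="AP", label=1)
        assert len(cubes) == 729
        assert len(local_offsets()) == 9
        offs = {c.offset for c in cubes}
        assert len(offs) == 729
        assert all(all(o in {0, 2, 4, 6, 8, 10, 12, 14, 16} for o in off) for off in offs)
        assert all(c.label == 1 and c.kind == "local" for c in cubes)

    def test_constant_volume_gives_identical_cubes(self):
        vol = np.full((48, 48, 48), 3.0)
        mask = np.zeros((48, 48, 48))
        mask[20:30, 20:30, 20:30] = 1
        cubes = augment_local_cubes(vol, mask_to_bbox(mask))
        assert all(np.allclose(c.data, 3.0) for c in cubes)

    @given(
        resample=st.integers(20, 40),
        cut=st.integers(8, 20),
        stride=st.integers(1, 6),
    )
    @settings(max_examples=25, deadline=None)
    def test_cube_count_law_matches_brute_force_enumeration(self, resample, cut, stride):
        if cut > resample:
            return
        law = (resample - cut) // stride + 1
        brute = sum(1 for o in range(0, resample - cut + 1, stride))
        assert len(local_offsets(resample, cut, stride)) == law == brute

    def test_stride4_and_identity_cut_counts(self, rng):
        vol = rng.standard_normal((48, 48, 48))
        mask = np.zeros((48, 48, 48))
        mask[16:32, 16:32, 16:32] = 1
        box = mask_to_bbox(mask)
        assert len(augment_local_cubes(vol, box, stride=4)) == 125
        assert len(augment_local_cubes(vol, box, cut_size=32)) == 1


class TestSplit:
    def _roster(self, n_pos, n_neg):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i:04d}" for i in range(n_pos + n_neg)],
                "mvi_label": [1] * n_pos + [0] * n_neg,
            }
        )

    def test_study_scale_split_arithmetic(self):
        split = make_split(self._roster(70, 140), seed=0)
        assert len(split.train_ids) == 168 and len(split.test_ids) == 42

    def test_stratification_preserves_class_ratio(self):
        roster = self._roster(70, 140)
        split = make_split(roster, seed=3)
        labels = roster.set_index("patient_id")["mvi_label"]
        assert labels.loc[split.test_ids].sum() == 14
        assert labels.loc[split.train_ids].sum() == 56
        # folds partition the training side and are themselves stratified
        folds = [split.fold_train_val(f)[1] for f in range(5)]
        assert sorted(sum(folds, [])) == sorted(split.train_ids)
        for val in folds:
            pos = labels.loc[val].sum()
            assert 10 <= pos <= 12  # 56 positives over 5 folds

    def test_split_deterministic_and_disjoint(self):
        roster = self._roster(20, 40)
        a = make_split(roster, seed=5)
        b = make_split(roster, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.fold_assignment == b.fold_assignment
        assert set(a.train_ids).isdisjoint(a.test_ids)
        assert set(a.train_ids) | set(a.test_ids) == set(roster["patient_id"])

    def test_single_class_roster_rejected(self):
        with pytest.raises(ValueError, match="class"):
            make_split(self._roster(0, 30), seed=0)


class TestManifest:
    def test_per_patient_sample_counts(self, small_roster):
        split = make_split(small_roster, seed=0)
        manifest = build_manifest(small_roster, split)
        train = manifest[manifest["side"] == "train"]
        test = manifest[manifest["side"] == "test"]
        assert len(train) == 730 * len(split.train_ids)  # 729 local + 1 global each
        assert len(test) == len(split.test_ids)
        assert (test["kind"] == "global").all()  # test side never augmented

    def test_cubes_inherit_patient_label(self, small_roster):
        split = make_split(small_roster, seed=0)
        manifest = build_manifest(small_roster, split)
        labels = small_roster.set_index("patient_id")["mvi_label"]
        per_patient = manifest.groupby("patient_id")["label"].nunique()
        assert (per_patient == 1).all()
        assert all(labels[pid] == g["label"].iloc[0] for pid, g in manifest.groupby("patient_id"))

    def test_missing_patient_rejected(self, small_roster):
        split = make_split(small_roster, seed=0)
        split.train_ids.append("P9999")
        split.fold_assignment["P9999"] = 0
        with pytest.raises(ValueError, match="P9999"):
            build_manifest(small_roster, split)


class TestCubeStore:
    def test_store_slices_match_direct_augmentation(self, small_cohort, small_roster):
        _, studies = small_cohort
        split = make_split(small_roster, seed=0)
        store = build_cube_store(studies, split)
        pid = split.train_ids[0]
        study = next(s for s in studies if s.patient_id == pid)
        box = mask_to_bbox(study.mask)
        direct = augment_local_cubes(study.volumes["AP"], box)
        got = store.get_cube(pid, "AP", "local", direct[5].offset)
        assert np.allclose(got, zscore(direct[5].data), atol=1e-5)

    def test_flat_cube_normalizes_to_zeros(self):
        assert np.array_equal(zscore(np.full((16, 16, 16), 4.2)), np.zeros((16, 16, 16)))
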