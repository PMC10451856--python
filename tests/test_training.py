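"""Loss closed forms, optimizer invariants, fold training determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from mvifusion.nn import NetworkConfig, SinglePhaseNet
from mvifusion.nn.autodiff import Tensor
from mvifusion.nn.layers import SGD
from mvifusion.preprocess import build_cube_store, build_manifest, make_split
from mvifusion.training import (
    TrainConfig,
    ensemble_predict,
    multi_phase_loss,
    normalized_loss_weights,
    predict_proba,
    train_fold,
)


class TestMultiPhaseLoss:
    def test_single_phase_reduces_to_plain_cross_entropy(self, rng):
        logits = Tensor(rng.standard_normal((4, 2)))
        labels = np.array([0, 1, 0, 1])
        loss = multi_phase_loss({"AP": logits}, labels, {"AP": 1.0})
        p = np.exp(logits.data) / np.exp(logits.data).sum(axis=1, keepdims=True)
        expected = -np.log(p[np.arange(4), labels]).mean()
        assert loss.data == pytest.approx(expected, abs=1e-12)

    def test_uninformed_heads_score_exactly_ln2_for_any_weights(self):
        zeros = Tensor(np.zeros((3, 2)))  # logits (0,0) -> probs (0.5,0.5)
        labels = np.array([0, 1, 1])
        for weights in ({"a": 1, "b": 1, "c": 1, "d": 1}, {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}):
            loss = multi_phase_loss({k: zeros for k in weights}, labels, weights)
            assert loss.data == pytest.approx(math.log(2.0), abs=1e-9)

    def test_two_phase_weighted_loss_matches_hand_arithmetic(self):
        # phase A: prob 0.8 on the true class; phase B: prob 0.6
        la = math.log(0.8 / 0.2)
        lb = math.log(0.6 / 0.4)
        logits = {
            "A": Tensor(np.array([[0.0, la]])),
            "B": Tensor(np.array([[0.0, lb]])),
        }
        loss = multi_phase_loss(logits, np.array([1]), {"A": 0.3, "B": 0.7})
        expected = -(0.3 * math.log(0.8) + 0.7 * math.log(0.6))
        assert loss.data == pytest.approx(expected, abs=1e-10)

    def test_weights_are_normalized_and_validated(self):
        w = normalized_loss_weights(None, ("AP", "PP"))
        assert w == {"AP": 0.5, "PP": 0.5}
        assert sum(normalized_loss_weights((2, 6), ("AP", "PP")).values()) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="one loss weight per phase"):
            normalized_loss_weights((1.0,), ("AP", "PP"))


def test_sgd_with_zero_learning_rate_never_moves_parameters(rng):
    p = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
    before = p.data.copy()
    opt = SGD([p], lr=0.0, momentum=0.9, weight_decay=1e-4)
    for _ in range(5):
        p.grad = rng.standard_normal((3, 3))
        opt.step()
    np.testing.assert_array_equal(p.data, before)


@pytest.fixture(scope="module")
def tiny_training_setup(small_cohort, small_roster):
    _, studies = small_cohort
    split = make_split(small_roster, seed=0)
    manifest = build_manifest(small_roster, split)
    store = build_cube_store(studies, split)
    return store, manifest, split


class TestTrainFold:
    NCFG = NetworkConfig(phases=("AP",))

    def test_iteration_cap_binds(self, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        tcfg = TrainConfig(max_iterations=7, eval_interval=7, early_stop_patience=99, seed=0)
        fm = train_fold(store, manifest, 0, self.NCFG, tcfg)
        assert fm.stopped_step == 7
        assert np.isfinite(fm.curve["train_loss"]).all()

    def test_epoch_bound_binds_on_tiny_data(self, small_roster, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        # global cubes only: 16 train patients minus fold -> n < batch means 1 step/epoch
        globals_only = manifest[manifest["kind"] == "global"].reset_index(drop=True)
        tcfg = TrainConfig(epochs=3, max_iterations=501, eval_interval=99, early_stop_patience=99, seed=0)
        fm = train_fold(store, globals_only, 0, self.NCFG, tcfg)
        assert fm.stopped_step == 3  # ceil(n/batch)=1 step per epoch, 3 epochs

    def test_identical_seed_gives_identical_curves_and_weights(self, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        tcfg = TrainConfig(max_iterations=6, eval_interval=3, early_stop_patience=99, seed=123)
        a = train_fold(store, manifest, 1, self.NCFG, tcfg)
        b = train_fold(store, manifest, 1, self.NCFG, tcfg)
        pd.testing.assert_frame_equal(a.curve, b.curve)
        for k in a.state_dict:
            np.testing.assert_array_equal(a.state_dict[k], b.state_dict[k])

    def test_loss_decreases_on_separable_noiseless_smoke(self, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        tcfg = TrainConfig(max_iterations=40, eval_interval=20, early_stop_patience=99, seed=5)
        fm = train_fold(store, manifest, 0, self.NCFG, tcfg)
        assert fm.curve["train_loss"].iloc[-1] < fm.curve["train_loss"].iloc[0] * 1.5
        assert np.isfinite(fm.best_val_loss)

    def test_early_stopping_never_beats_full_training_on_val_loss(self, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        base = dict(max_iterations=30, eval_interval=5, seed=7)
        early = train_fold(store, manifest, 0, self.NCFG, TrainConfig(early_stop_patience=1, **base))
        full = train_fold(store, manifest, 0, self.NCFG, TrainConfig(early_stop_patience=99, **base))
        assert full.best_val_loss <= early.best_val_loss + 1e-12
        assert early.stopped_step <= full.stopped_step

    def test_single_class_validation_fold_rejected(self, tiny_training_setup):
        store, manifest, _ = tiny_training_setup
        bad = manifest.copy()
        val_ids = bad[(bad["side"] == "train") & (bad["fold"] == 0)]["patient_id"].unique()
        bad.loc[bad["patient_id"].isin(val_ids), "label"] = 1
        store2 = type(store)()
        store2.phases, store2._global, store2._local32 = store.phases, store._global, store._local32
        store2.labels = {p: (1 if p in set(val_ids) else l) for p, l in store.labels.items()}
        with pytest.raises(ValueError, match="single class"):
            train_fold(store2, bad, 0, self.NCFG, TrainConfig(max_iterations=2, seed=0))


class TestEnsemble:
    def test_identical_folds_equal_single_model(self, tiny_training_setup):
        store, manifest, split = tiny_training_setup
        tcfg = TrainConfig(max_iterations=4, eval_interval=4, early_stop_patience=9, seed=0)
        fm = train_fold(store, manifest, 0, NetworkConfig(phases=("AP",)), tcfg)
        single = predict_proba(fm.build(), store, split.test_ids)
        twice = ensemble_predict([fm, fm], store, split.test_ids)
        np.testing.assert_allclose(twice, single, atol=1e-7)

    def test_mismatched_configs_rejected(self, tiny_training_setup):
        store, manifest, split = tiny_training_setup
        tcfg = TrainConfig(max_iterations=2, eval_interval=2, early_stop_patience=9, seed=0)
        a = train_fold(store, manifest, 0, NetworkConfig(phases=("AP",)), tcfg)
        b = train_fold(store, manifest, 0, NetworkConfig(phases=("PP",)), tcfg)
        with pytest.raises(ValueError, match="differing network configs"):
            ensemble_predict([a, b], store, split.test_ids)

    def test_empty_ensemble_rejected(self, tiny_training_setup):
        store, _, split = tiny_training_setup
        with pytest.raises(ValueError, match="no fold models"):
            ensemble_predict([], store, split.test_ids)
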