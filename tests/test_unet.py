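import numpy as np
import pytest

from neuroseg import _nn, phantom
from neuroseg.io_brats import LabelCodec, remap_label_codes, with_labels
from neuroseg.patches import PatchSpec
from neuroseg.unet import (
    LabelConfigMismatchError,
    TrainConfig,
    TrainedEnsemble,
    UNet3D,
    UNetConfig,
    build_model,
    channel_plan,
    lr_at_epoch,
    make_folds,
    normalize_case,
    predict_case,
    train_ensemble,
    train_model,
)

TINY = UNetConfig(n_classes=4, levels=2, base_filters=4)


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = phantom.PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor=phantom.TumorSpec(3.0, 2.0, 2.0),
        wmh=phantom.WMHSpec(count_range=(1, 2), radius_range_mm=(1.5, 2.2),
                            min_distance_from_tumor_mm=4.0),
    )
    return phantom.generate_cohort(2, spec, master_seed=21)


class TestChannelPlan:
    def test_reference_plan(self):
        assert channel_plan(UNetConfig()) == [32, 64, 128, 256]

    def test_single_level(self):
        assert channel_plan(UNetConfig(levels=1)) == [32]

    def test_doubling_rule(self):
        assert channel_plan(UNetConfig(levels=3, base_filters=8)) == [8, 16, 32]


class TestLrSchedule:
    def test_initial_value(self):
        assert lr_at_epoch(0, TrainConfig()) == pytest.approx(1e-4)

    def test_terminal_value_is_zero(self):
        assert lr_at_epoch(600, TrainConfig()) == 0.0

    def test_halfway_value(self):
        assert lr_at_epoch(300, TrainConfig()) == pytest.approx(2.5e-5)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig(epochs=50)
        lrs = [lr_at_epoch(e, cfg) for e in range(51)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_epoch_raises(self):
        with pytest.raises(ValueError):
            lr_at_epoch(601, TrainConfig())


class TestMakeFolds:
    def test_285_cases_10_folds(self):
        ids = [f"c{i}" for i in range(285)]
        folds = make_folds(ids, 10, seed=0)
        sizes = sorted(
            sum(1 for f in folds.values() if f == k) for k in range(10)
        )
        assert sizes == [28] * 5 + [29] * 5

    def test_20_cases_10_folds(self):
        folds = make_folds([f"c{i}" for i in range(20)], 10, seed=1)
        assert all(
            sum(1 for f in folds.values() if f == k) == 2 for k in range(10)
        )

    def test_partition_property_and_determinism(self):
        ids = [f"c{i}" for i in range(23)]
        a = make_folds(ids, 5, seed=3)
        b = make_folds(ids, 5, seed=3)
        assert a == b
        assert set(a) == set(ids)

    def test_more_folds_than_cases_raises(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 3, seed=0)


class TestModelShapes:
    @pytest.mark.parametrize(
        "levels,classes,edge",
        [(4, 5, 16), (2, 4, 16), (3, 5, 16), (2, 5, 32)],
    )
    def test_output_shape_equals_input_shape(self, levels, classes, edge):
        cfg = UNetConfig(n_classes=classes, levels=levels, base_filters=2)
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(1, 4, edge, edge, edge))
        y = model.forward(x.astype(np.float32))
        assert y.shape == (1, classes, edge, edge, edge)

    def test_indivisible_edge_raises(self):
        cfg = UNetConfig(levels=4, base_filters=2)
        model = build_model(cfg)
        x = np.zeros((1, 4, 81, 81, 81), dtype=np.float32)
        with pytest.raises(ValueError):
            model.forward(x)

    def test_class_count_changes_only_final_layer(self):
        """4- and 5-class variants share every parameter count except the
        1x1x1 classification layer."""
        m4 = build_model(UNetConfig(n_classes=4, levels=3, base_filters=4))
        m5 = build_model(UNetConfig(n_classes=5, levels=3, base_filters=4))
        final4 = sum(p.data.size for p in m4.final.params())
        final5 = sum(p.data.size for p in m5.final.params())
        assert m4.n_parameters() - final4 == m5.n_parameters() - final5
        assert final5 - final4 == 4 + 1  # one extra 1x1x1 filter + bias


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Float64 finite-difference check of the full network gradient."""
        rng = np.random.default_rng(0)
        cfg = UNetConfig(n_classes=4, levels=2, base_filters=2)
        model = UNet3D(cfg, seed=1)
        for p in model.params():
            p.data = p.data.astype(np.float64)
            p.grad = np.zeros_like(p.data)
        x = rng.normal(size=(2, 4, 4, 4, 4))
        y = rng.integers(0, 4, size=(2, 4, 4, 4))

        def loss():
            logits = model.forward(x, train=True)
            return _nn.softmax_cross_entropy(logits, y)

        l0, d = loss()
        for p in model.params():
            p.grad[...] = 0
        model.backward(d.astype(np.float64))
        check_rng = np.random.default_rng(42)
        params = model.params()
        for pi in check_rng.choice(len(params), size=8, replace=False):
            p = params[pi]
            idx = tuple(check_rng.integers(s) for s in p.data.shape)
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp, _ = loss()
            p.data[idx] = orig - eps
            lm, _ = loss()
            p.data[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestTraining:
    def test_loss_decreases_on_overfit_run(self, tiny_cohort):
        cases = [pc.case for pc in tiny_cohort]
        ucfg = UNetConfig(n_classes=5, levels=2, base_filters=8)
        tcfg = TrainConfig(
            initial_lr=3e-3, epochs=30, patches_per_epoch=8, batch_size=2,
            seed=4,
        )
        _, hist = train_model(cases, ucfg, tcfg, PatchSpec(edge=16))
        assert hist[-1] < hist[0]

    def test_wmh_labels_incompatible_with_four_class_model(self, tiny_cohort):
        cases = [pc.case for pc in tiny_cohort]
        assert any((c.labels == 3).any() for c in cases)
        ucfg = UNetConfig(n_classes=4, levels=2, base_filters=2)
        tcfg = TrainConfig(epochs=1, patches_per_epoch=2, seed=0)
        with pytest.raises(LabelConfigMismatchError):
            train_model(cases, ucfg, tcfg, PatchSpec(edge=16))

    def test_training_is_deterministic(self, tiny_cohort):
        cases = [pc.case for pc in tiny_cohort]
        ucfg = UNetConfig(n_classes=5, levels=2, base_filters=2)
        tcfg = TrainConfig(
            initial_lr=1e-3, epochs=2, patches_per_epoch=4, batch_size=2,
            seed=11,
        )
        _, h1 = train_model(cases, ucfg, tcfg, PatchSpec(edge=16))
        _, h2 = train_model(cases, ucfg, tcfg, PatchSpec(edge=16))
        assert h1 == h2


@pytest.fixture(scope="module")
def trained(tiny_cohort):
    cases = [pc.case for pc in tiny_cohort]
    ucfg = UNetConfig(n_classes=5, levels=2, base_filters=2)
    tcfg = TrainConfig(
        initial_lr=1e-3, epochs=2, patches_per_epoch=4, batch_size=2,
        ensemble_size=2, seed=8,
    )
    return train_ensemble(cases, ucfg, tcfg, PatchSpec(edge=16))


class TestEnsemble:
    def test_members_have_distinct_weights(self, trained):
        w0 = trained.members[0].state_arrays()[0]
        w1 = trained.members[1].state_arrays()[0]
        assert not np.array_equal(w0, w1)

    def test_histories_recorded_per_member(self, trained):
        assert len(trained.histories) == 2
        assert all(len(h) == 2 for h in trained.histories)

    def test_probabilities_sum_to_one(self, trained, tiny_cohort):
        probs, codes = predict_case(trained, tiny_cohort[0].case)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert codes.shape == tiny_cohort[0].case.shape

    def test_prediction_codes_are_on_disk_codes(self, trained, tiny_cohort):
        _, codes = predict_case(trained, tiny_cohort[0].case)
        assert set(np.unique(codes)) <= {0, 1, 2, 3, 4}

    def test_duplicate_member_equals_single(self, trained, tiny_cohort):
        single = TrainedEnsemble(
            [trained.members[0]], trained.ucfg, trained.tcfg
        )
        double = TrainedEnsemble(
            [trained.members[0], trained.members[0]], trained.ucfg, trained.tcfg
        )
        _, c1 = predict_case(single, tiny_cohort[0].case)
        _, c2 = predict_case(double, tiny_cohort[0].case)
        np.testing.assert_array_equal(c1, c2)

    def test_crop_contract_on_odd_extent(self, trained):
        """A case whose z extent is not divisible by the network comes back
        on its original grid (pad at inference, crop after)."""
        rng = np.random.default_rng(0)
        channels = rng.uniform(1, 2, size=(4, 16, 16, 15)).astype(np.float32)
        from neuroseg.io_brats import MpMRICase

        case = MpMRICase("odd", channels)
        probs, codes = predict_case(trained, case)
        assert codes.shape == (16, 16, 15)
        assert probs.shape == (5, 16, 16, 15)

    def test_empty_ensemble_raises(self, tiny_cohort):
        empty = TrainedEnsemble([], UNetConfig(), TrainConfig())
        with pytest.raises(ValueError):
            predict_case(empty, tiny_cohort[0].case)

    def test_save_load_roundtrip(self, trained, tiny_cohort, tmp_path):
        trained.save(tmp_path / "ens")
        back = TrainedEnsemble.load(tmp_path / "ens")
        _, c1 = predict_case(trained, tiny_cohort[0].case)
        _, c2 = predict_case(back, tiny_cohort[0].case)
        np.testing.assert_array_equal(c1, c2)


class TestNormalization:
    def test_zscore_over_brain_mask(self, small_phantom):
        norm = normalize_case(small_phantom.case)
        mask = small_phantom.case.brain_mask
        for ch in range(4):
            vals = norm.channels[ch][mask]
            assert vals.mean() == pytest.approx(0.0, abs=1e-4)
            assert vals.std() == pytest.approx(1.0, abs=1e-3)
        assert (norm.channels[:, ~mask] == 0).all()
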