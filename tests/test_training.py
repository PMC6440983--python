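"""Training-loop mechanics: overfitting, determinism, splits, benchmark."""

import numpy as np
import pytest

from mousetrack import synthetic
from mousetrack.augmentation import AugmentationConfig
from mousetrack.datasets import (load_dataset, load_dataset_hdf5, save_dataset,
                                 save_dataset_hdf5, train_val_split)
from mousetrack.networks import (ArchitectureSpec, BinnedHeadSpec,
                                 build_binned_net, build_regression_net,
                                 build_segmentation_net)
from mousetrack.training import Hyperparams, evaluate, subsample_benchmark, train


@pytest.fixture(scope="module")
def tiny_ds():
    scene = synthetic.preset("black", frame_size=96)
    return synthetic.generate_dataset(12, scene, seed=4, id_prefix="t")


def seg_model(seed=0):
    return build_segmentation_net(ArchitectureSpec("segmentation", 96, seed=seed))


class TestTrain:
    def test_single_sample_loss_decreases(self, tiny_ds):
        model = seg_model()
        hp = Hyperparams(learning_rate=1e-3, batch_size=1, epochs=40, seed=0)
        hist = train(model, tiny_ds[:1], hp)
        losses = np.array(hist.train_loss)
        assert (np.diff(losses) < 0).mean() >= 0.9
        # the pixel term overfits; the direction term cannot go below its
        # batch-norm floor at batch size 1, so compare against pixel + ln 4
        assert losses[-1] < losses[0]

    def test_same_seed_identical_history(self, tiny_ds):
        hp = Hyperparams(learning_rate=1e-3, batch_size=4, epochs=3, seed=7)
        h1 = train(seg_model(1), tiny_ds[:8], hp, val_dataset=tiny_ds[8:])
        h2 = train(seg_model(1), tiny_ds[:8], hp, val_dataset=tiny_ds[8:])
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_augmented_training_runs_and_is_deterministic(self, tiny_ds):
        hp = Hyperparams(learning_rate=1e-3, batch_size=4, epochs=2, seed=3)
        aug = AugmentationConfig(rotation_range_deg=5, translation_range_px=5)
        h1 = train(seg_model(2), tiny_ds[:4], hp, aug=aug)
        h2 = train(seg_model(2), tiny_ds[:4], hp, aug=aug)
        assert h1.train_loss == h2.train_loss

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(seg_model(), [], Hyperparams())

    def test_id_leak_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="leak"):
            train(seg_model(), tiny_ds[:4], Hyperparams(epochs=1),
                  val_dataset=tiny_ds[3:5])

    def test_binned_family_trains(self, tiny_ds):
        heads = BinnedHeadSpec.center_xy(96, resolution=4.0)
        model = build_binned_net(ArchitectureSpec("binned", 96, seed=0), heads)
        hp = Hyperparams(learning_rate=1e-3, batch_size=4, epochs=2, seed=0)
        hist = train(model, tiny_ds[:4], hp)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_regression_family_trains(self, tiny_ds):
        model = build_regression_net(ArchitectureSpec("regression", 96, seed=0))
        hp = Hyperparams(learning_rate=1e-4, batch_size=4, epochs=2, seed=0)
        hist = train(model, tiny_ds[:4], hp)
        assert np.isfinite(hist.train_loss).all()


class TestEvaluate:
    def test_perfect_predictions_zero_error(self, tiny_ds, monkeypatch):
        import mousetrack.training as tr
        model = seg_model()
        monkeypatch.setattr(tr, "predict_sample",
                            lambda m, s: (s.ellipse, s.mask))
        df, agg = tr.evaluate(model, tiny_ds[:5])
        assert agg["center_error_median_px"] == 0.0
        assert agg["iou_mean"] == 1.0
        assert agg["direction_accuracy"] == 1.0

    def test_no_detection_counted_not_averaged(self, tiny_ds, monkeypatch):
        import mousetrack.training as tr
        from mousetrack.geometry import NO_DETECTION
        calls = {"n": 0}

        def fake(m, s):
            calls["n"] += 1
            return (NO_DETECTION, None) if calls["n"] == 1 else (s.ellipse, s.mask)
        monkeypatch.setattr(tr, "predict_sample", fake)
        df, agg = tr.evaluate(seg_model(), tiny_ds[:4])
        assert agg["no_detection_fraction"] == pytest.approx(0.25)
        assert agg["center_error_median_px"] == 0.0

    def test_agrees_with_metrics_module(self, tiny_ds):
        """evaluate's per-sample numbers equal direct metric calls."""
        from mousetrack.metrics import center_error, mask_iou
        from mousetrack.training import predict_sample
        model = seg_model()
        df, _ = evaluate(model, tiny_ds[:3])
        for row, s in zip(df.itertuples(), tiny_ds[:3]):
            pred, pmask = predict_sample(model, s)
            if row.detected:
                assert row.center_error_px == pytest.approx(
                    center_error(pred, s.ellipse))
                assert row.iou == pytest.approx(mask_iou(pmask, s.mask))


class TestSubsampleBenchmark:
    def test_sizes_are_nested_prefixes(self, tiny_ds):
        seen = []

        class Probe:
            family = "segmentation"

            def __init__(self):
                self.inner = seg_model()
                self.input_size = 96

            def __getattr__(self, name):
                return getattr(self.inner, name)

        import mousetrack.training as tr
        orig = tr.train

        def spy(model, subset, hp, **kw):
            seen.append([s.sample_id for s in subset])
            return orig(model, subset, hp, **kw)
        hp = Hyperparams(learning_rate=1e-3, batch_size=4, epochs=1, seed=0)
        try:
            tr.train = spy
            tr.subsample_benchmark(lambda: seg_model(), tiny_ds[:10],
                                   [4, 8], hp, tiny_ds[10:], seed=5)
        finally:
            tr.train = orig
        assert len(seen) == 2
        assert seen[0] == seen[1][:4]  # larger set contains the smaller

    def test_oversized_request_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            subsample_benchmark(lambda: seg_model(), tiny_ds[:4], [10],
                                Hyperparams(epochs=1), tiny_ds[4:])


class TestDatasetStore:
    def test_png_csv_round_trip(self, tiny_ds, tmp_path):
        save_dataset(tiny_ds[:3], tmp_path)
        loaded = load_dataset(tmp_path)
        for a, b in zip(tiny_ds[:3], loaded):
            assert a.sample_id == b.sample_id
            assert np.array_equal(a.frame, b.frame)
            assert np.array_equal(a.mask, b.mask)
            assert b.ellipse.as_vector() == pytest.approx(
                a.ellipse.as_vector(), abs=1e-9)
            assert a.direction == b.direction

    def test_hdf5_round_trip(self, tiny_ds, tmp_path):
        path = str(tmp_path / "d.h5")
        save_dataset_hdf5(tiny_ds[:3], path)
        loaded = load_dataset_hdf5(path)
        for a, b in zip(tiny_ds[:3], loaded):
            assert np.array_equal(a.frame, b.frame)
            assert a.direction == b.direction

    def test_split_disjoint_and_deterministic(self, tiny_ds):
        tr1, va1 = train_val_split(tiny_ds, 4, seed=1)
        tr2, va2 = train_val_split(tiny_ds, 4, seed=1)
        assert [s.sample_id for s in va1] == [s.sample_id for s in va2]
        assert not ({s.sample_id for s in tr1} & {s.sample_id for s in va1})
        assert len(tr1) + len(va1) == len(tiny_ds)
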