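"""Architecture shape schedule, losses, and output decoders."""

import math

import numpy as np
import pytest

from mousetrack.geometry import (NO_DETECTION, CardinalDirection, EllipseFit,
                                 UndirectedEllipse, rasterize_ellipse)
from mousetrack.networks import (
    ArchitectureSpec,
    BinnedHeadSpec,
    binned_loss,
    build_binned_net,
    build_regression_net,
    build_segmentation_net,
    decode_binned,
    decode_regression,
    load_model,
    regression_loss,
    save_model,
    segmentation_loss,
    segmentation_to_ellipse,
)
from mousetrack.nn.functional import softmax


@pytest.fixture(scope="module")
def seg480():
    model = build_segmentation_net(ArchitectureSpec("segmentation", 480, seed=0))
    model.forward(np.zeros((1, 1, 480, 480), np.float32))
    return model


@pytest.fixture(scope="module")
def binned480():
    model = build_binned_net(ArchitectureSpec("binned", 480, seed=0))
    model.forward(np.zeros((1, 1, 480, 480), np.float32))
    return model


class TestShapeSchedule:
    def test_segmentation_encoder_terminal(self, seg480):
        assert seg480.shapes["encoder_terminal"] == (128, 15, 15)

    def test_segmentation_bottleneck(self, seg480):
        assert seg480.shapes["bottleneck"] == (512, 5, 5)

    def test_segmentation_outputs(self, seg480):
        assert seg480.shapes["mask_out"] == (2, 480, 480)
        assert seg480.shapes["dir_out"] == (4,)

    def test_binned_encoder_terminal(self, binned480):
        assert binned480.shapes["encoder_terminal"] == (256, 15, 15)

    def test_binned_x_head_480_bins(self, binned480):
        assert binned480.shapes["head_x"] == (480,)
        assert binned480.shapes["head_y"] == (480,)

    def test_regression_six_outputs(self):
        model = build_regression_net(ArchitectureSpec("regression", 96, seed=0))
        out = model.forward(np.zeros((2, 1, 96, 96), np.float32))
        assert out.shape == (2, 6)

    def test_downscaled_schedule_proportional(self):
        model = build_segmentation_net(ArchitectureSpec("segmentation", 96, seed=0))
        model.forward(np.zeros((1, 1, 96, 96), np.float32))
        assert model.shapes["encoder_terminal"] == (128, 3, 3)
        assert model.shapes["bottleneck"] == (512, 1, 1)
        assert model.shapes["mask_out"] == (2, 96, 96)

    def test_unreachable_input_size_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("segmentation", 100)

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            build_segmentation_net(ArchitectureSpec("binned", 480))

    def test_pixel_softmax_normalizes(self, rng):
        model = build_segmentation_net(ArchitectureSpec("segmentation", 96, seed=0))
        ml, _ = model.forward(rng.random((1, 1, 96, 96), np.float32))
        p = softmax(ml, axis=1)
        assert p.sum(axis=1) == pytest.approx(np.ones((1, 96, 96)), abs=1e-6)

    def test_binned_heads_independent(self):
        heads = BinnedHeadSpec.center_xy(96)
        model = build_binned_net(ArchitectureSpec("binned", 96, seed=0), heads)
        x = np.random.default_rng(0).random((1, 1, 96, 96), np.float32)
        before = model.forward(x)["y"].copy()
        model.fcs["x"].w.value[...] = 0.0
        model.fcs["x"].b.value[...] = 0.0
        after = model.forward(x)
        assert np.array_equal(after["y"], before)
        assert np.all(after["x"] == 0.0)

    def test_inference_deterministic(self):
        model = build_regression_net(ArchitectureSpec("regression", 96, seed=0))
        x = np.random.default_rng(1).random((1, 1, 96, 96), np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))


class TestLosses:
    def test_segmentation_loss_limits(self):
        mask_true = np.zeros((1, 4, 4), np.int64)
        mask_true[0, :2] = 1
        dir_true = np.array([2])
        big = 50.0
        ml = np.stack([np.where(mask_true == 0, big, -big),
                       np.where(mask_true == 1, big, -big)], axis=1)
        dl = np.full((1, 4), -big)
        dl[0, 2] = big
        assert segmentation_loss(ml, dl, mask_true, dir_true) == \
            pytest.approx(0.0, abs=1e-6)
        uniform = np.zeros((1, 2, 4, 4))
        loss = segmentation_loss(uniform, np.zeros((1, 4)), mask_true, dir_true)
        assert loss == pytest.approx(math.log(2) + math.log(4), abs=1e-6)

    def test_segmentation_loss_hand_computed(self):
        # 2x2 mask, scores chosen so softmax probs are known exactly
        mask_true = np.array([[[1, 0], [0, 1]]], dtype=np.int64)
        ml = np.zeros((1, 2, 2, 2))
        ml[0, 1] = np.log(3)  # p_fg = 3/4 everywhere
        pix = -(2 * math.log(3 / 4) + 2 * math.log(1 / 4)) / 4
        dl = np.array([[math.log(2), 0.0, 0.0, 0.0]])  # p0 = 2/5
        direc = -math.log(2 / 5)
        got = segmentation_loss(ml, dl, mask_true, np.array([0]))
        assert got == pytest.approx(pix + direc, abs=1e-6)

    def test_segmentation_loss_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            segmentation_loss(np.zeros((1, 2, 2, 2)), np.zeros((1, 4)),
                              np.full((1, 2, 2), 2), np.array([0]))

    def test_binned_loss_uniform_and_additive(self):
        scores = {"x": np.zeros((1, 480)), "y": np.zeros((1, 240))}
        targets = {"x": np.array([7]), "y": np.array([3])}
        assert binned_loss(scores, targets) == \
            pytest.approx(math.log(480) + math.log(240), abs=1e-6)
        only_x = binned_loss({"x": scores["x"]}, targets)
        only_y = binned_loss({"y": scores["y"]}, targets)
        assert binned_loss(scores, targets) == pytest.approx(only_x + only_y)

    def test_binned_loss_target_out_of_range(self):
        with pytest.raises(ValueError):
            binned_loss({"x": np.zeros((1, 10))}, {"x": np.array([10])})

    def test_regression_loss_values(self, rng):
        t = np.arange(6.0)
        assert regression_loss(t, t) == 0.0
        p = t.copy()
        p[0] += 1.0
        assert regression_loss(p, t) == pytest.approx(1 / 6)
        a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        assert regression_loss(a, b) == pytest.approx(np.mean((a - b) ** 2))


class TestDecodeBinned:
    def test_one_hot_bin_center(self):
        heads = BinnedHeadSpec.center_xy(480, resolution=1.0)
        scores = np.zeros(480)
        scores[240] = 1.0
        assert decode_binned({"x": scores}, heads)["x"] == 240.5

    def test_tie_breaks_low_index(self):
        heads = BinnedHeadSpec.center_xy(480)
        scores = np.zeros(480)
        scores[10] = scores[20] = 5.0
        assert decode_binned({"x": scores}, heads)["x"] == 10.5

    def test_matches_exhaustive_scan(self, rng):
        heads = BinnedHeadSpec.center_xy(480)
        for _ in range(20):
            scores = rng.normal(0, 1, 480)
            got = decode_binned({"x": scores}, heads)["x"]
            best = max(range(480), key=lambda i: scores[i])
            assert got == best + 0.5

    def test_round_trip_within_half_bin(self):
        heads = BinnedHeadSpec(ranges={"x": (0.0, 480.0, 2.0)})
        for v in np.linspace(0.01, 479.9, 197):
            idx = heads.encode("x", v)
            one_hot = np.zeros(heads.n_bins("x"))
            one_hot[idx] = 1.0
            assert abs(decode_binned({"x": one_hot}, heads)["x"] - v) <= 1.0

    def test_nonfinite_scores_rejected(self):
        heads = BinnedHeadSpec.center_xy(480)
        with pytest.raises(ValueError):
            decode_binned({"x": np.full(480, np.nan)}, heads)


class TestDecodeRegression:
    @pytest.mark.parametrize("sc,expected", [((0, 1), 0), ((1, 0), 90),
                                             ((0.6, 0.6), 45)])
    def test_angle_from_sin_cos(self, sc, expected):
        out = decode_regression([10, 20, 30, 10, sc[0], sc[1]])
        assert out.theta_deg == pytest.approx(expected)

    def test_round_trip_360_angles(self):
        for t in range(360):
            s, c = math.sin(math.radians(t)), math.cos(math.radians(t))
            out = decode_regression([0, 0, 10, 5, s, c])
            assert out.theta_deg == pytest.approx(t, abs=1e-9)

    def test_degenerate_direction_reports_undirected(self):
        with pytest.warns(UserWarning):
            out = decode_regression([10, 10, 20, 10, 0.0, 0.0])
        assert isinstance(out, UndirectedEllipse)

    def test_negative_axes_clamped(self):
        with pytest.warns(UserWarning):
            out = decode_regression([10, 10, -5, -3, 0, 1])
        assert out.major == 0.0 and out.minor == 0.0


class TestSegmentationToEllipse:
    def test_perfect_scores_recover_ellipse(self):
        truth = EllipseFit.from_angle(48, 40, 30, 12, 100)
        mask = rasterize_ellipse(truth, (96, 96))
        big = 20.0
        scores = np.stack([np.where(mask == 0, big, -big),
                           np.where(mask == 1, big, -big)])
        dir_scores = np.array([0.0, 0.0, 0.0, 0.0])
        dir_scores[int(CardinalDirection.UP)] = 5.0
        fit = segmentation_to_ellipse(scores, dir_scores)
        assert abs(fit.x - truth.x) <= 1 and abs(fit.y - truth.y) <= 1
        assert fit.major == pytest.approx(truth.major, rel=0.05)
        d = abs(fit.theta_deg - truth.theta_deg)
        assert min(d, 360 - d) <= 2.0

    def test_all_background_no_detection(self):
        scores = np.zeros((2, 32, 32))
        scores[0] = 10.0
        assert segmentation_to_ellipse(scores, np.zeros(4)) is NO_DETECTION

    def test_tied_direction_scores_lowest_class(self):
        truth = EllipseFit.from_angle(48, 48, 30, 12, 0)
        mask = rasterize_ellipse(truth, (96, 96))
        scores = np.stack([1.0 - 2.0 * mask, 2.0 * mask - 1.0])
        fit = segmentation_to_ellipse(scores, np.zeros(4))
        # class 0 (up) wins the tie; the fit is near-horizontal so the
        # resolved angle is the candidate closer to 90 deg
        assert fit.theta_deg < 180


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = build_segmentation_net(ArchitectureSpec("segmentation", 96, seed=3))
        x = np.random.default_rng(0).random((1, 1, 96, 96), np.float32)
        ml, dl = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        clone = load_model(path)
        ml2, dl2 = clone.forward(x)
        assert np.array_equal(ml, ml2) and np.array_equal(dl, dl2)
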