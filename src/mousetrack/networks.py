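"""The three tracker network families: builders, losses, decoders.

* **segmentation** — encoder-decoder net that predicts a per-pixel
  foreground/background mask plus a 4-way cardinal-direction head from the
  feature bottleneck; an ellipse is then fit to the predicted mask.
* **binned** — VGG-style encoder whose flattened features feed one
  independent fully connected head per ellipse parameter, each predicting a
  score over discretized value bins.
* **regression** — a pluggable feature encoder with a fully connected head
  regressing the six ellipse parameters (x, y, major, minor, sin, cos)
  directly under an L2 loss.

At the reference input size of 480 px the segmentation encoder reaches
15x15x128 after its six blocks and a 5x5x512 bottleneck; the binned encoder
terminates at 15x15x256.  Any input size with ``size % 32 == 0`` and
``(size // 32) % 3 == 0`` (e.g. 96) follows the same schedule proportionally.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

from . import nn
from .geometry import (
    NO_DETECTION,
    CardinalDirection,
    EllipseFit,
    UndirectedEllipse,
    fit_ellipse_to_mask,
    resolve_direction,
)
from .nn.functional import softmax, softmax_cross_entropy

SEG_FILTERS = (8, 16, 32, 64, 128, 128)
BINNED_FILTERS = (16, 32, 64, 128, 256)


@dataclass
class ArchitectureSpec:
    """Declarative description of one network family."""

    family: str                      # segmentation | binned | regression
    input_size: int = 480
    base_filters: int = 0            # 0 -> family default (8 seg, 16 binned)
    conv_kernel: int = 0             # 0 -> family default (5 seg, 3 binned)
    n_encoder_blocks: int = 0        # 0 -> family default (6 seg, 5 binned)
    encoder: str = "vgg"             # regression family feature encoder
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("segmentation", "binned", "regression"):
            raise ValueError(f"unknown family {self.family!r}")
        s = self.input_size
        if s % 32 != 0 or (s // 32) % 3 != 0:
            raise ValueError(
                f"input_size {s} unreachable by the shape schedule: "
                "need size % 32 == 0 and (size // 32) % 3 == 0")


@dataclass
class BinnedHeadSpec:
    """Value range and resolution per binned-head parameter.

    Each head covers ``[vmin, vmax)`` at ``resolution`` units per bin;
    decoded values sit at bin centers.
    """

    ranges: Dict[str, tuple] = field(default_factory=dict)

    @classmethod
    def center_xy(cls, input_size: int = 480, resolution: float = 1.0):
        r = (0.0, float(input_size), resolution)
        return cls(ranges={"x": r, "y": r})

    def n_bins(self, name: str) -> int:
        vmin, vmax, res = self.ranges[name]
        n = (vmax - vmin) / res
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(f"head {name!r}: bin count must be a positive integer")
        return int(round(n))

    def encode(self, name: str, value: float) -> int:
        vmin, _, res = self.ranges[name]
        return int(np.clip(int((value - vmin) // res), 0, self.n_bins(name) - 1))

    def decode(self, name: str, index: int) -> float:
        vmin, _, res = self.ranges[name]
        return vmin + (index + 0.5) * res


def _conv_bn_relu(c_in, c_out, k, rng, name):
    return (nn.Conv2d(c_in, c_out, k, rng, name),
            nn.BatchNorm2d(c_out, name=f"{name}.bn"),
            nn.ReLU())


class SegmentationNet:
    """Encoder-decoder segmentation tracker with a direction head.

    Encoder: six 5x5 conv+BN+ReLU blocks (filters 8,16,32,64,128,128), 2x2
    max-pool after the first five; a 5x5 conv to 256, 3x3/stride-3 max-pool
    and a final 5x5 conv to the 512-channel bottleneck.  Decoder: strided
    transposed convolutions without ReLU, with pre-pool encoder activations
    added back at matching resolutions (summation skip junctions), closed by
    a 1x1 conv to two channels (background, foreground).  Direction head:
    two 5x5 conv+BN+ReLU blocks (128, 64) on the bottleneck, flatten, one
    fully connected layer to the four quadrant classes.
    """

    family = "segmentation"

    def __init__(self, input_size: int = 480, seed: int = 0):
        ArchitectureSpec("segmentation", input_size)  # validates size
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        k = 5
        self.enc = []
        c_prev = 1
        for i, c in enumerate(SEG_FILTERS):
            self.enc.append(_conv_bn_relu(c_prev, c, k, rng, f"enc{i}"))
            c_prev = c
        self.pools = [nn.MaxPool2d(2) for _ in range(5)]
        self.trans1 = _conv_bn_relu(128, 256, k, rng, "trans1")
        self.pool3 = nn.MaxPool2d(3)
        self.trans2 = _conv_bn_relu(256, 512, k, rng, "trans2")
        dec_ch = [(512, 128), (128, 128), (128, 64), (64, 32), (32, 16), (16, 8)]
        self.dec = [nn.ConvTranspose2d(ci, co, 5, 3 if j == 0 else 2,
                                       1 if j == 0 else 2,
                                       0 if j == 0 else 1, rng, f"dec{j}")
                    for j, (ci, co) in enumerate(dec_ch)]
        self.out_conv = nn.Conv2d(8, 2, 1, rng, "out")
        self.head1 = _conv_bn_relu(512, 128, k, rng, "dir1")
        self.head2 = _conv_bn_relu(128, 64, k, rng, "dir2")
        self.head_flat = nn.Flatten()
        b = input_size // 96  # bottleneck spatial size
        self.head_fc = nn.Linear(b * b * 64, 4, rng, "dir_fc")
        self.shapes: Dict[str, tuple] = {}

    # -- plumbing -----------------------------------------------------------
    def _triples(self):
        return [*self.enc, self.trans1, self.trans2, self.head1, self.head2]

    def params(self):
        out = []
        for conv, bn, _ in self._triples():
            out += conv.params() + bn.params()
        for ct in self.dec:
            out += ct.params()
        out += self.out_conv.params() + self.head_fc.params()
        return out

    def bn_layers(self):
        return [bn for _, bn, _ in self._triples()]

    def arch(self):
        return {"family": self.family, "input_size": self.input_size}

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False):
        assert x.shape[2] == x.shape[3] == self.input_size, \
            f"expected {self.input_size} px input, got {x.shape}"
        acts = []
        h = x.astype(np.float32)
        for i, (conv, bn, relu) in enumerate(self.enc):
            h = relu.forward(bn.forward(conv.forward(h, training), training), training)
            acts.append(h)
            if i < 5:
                h = self.pools[i].forward(h, training)
        self.shapes["encoder_terminal"] = acts[-1].shape[1:]
        for layer in self.trans1:
            h = layer.forward(h, training)
        h = self.pool3.forward(h, training)
        for layer in self.trans2:
            h = layer.forward(h, training)
        bottleneck = h
        self.shapes["bottleneck"] = bottleneck.shape[1:]
        d = bottleneck
        for j, ct in enumerate(self.dec):
            d = ct.forward(d, training) + acts[5 - j]
        mask_logits = self.out_conv.forward(d, training)
        g = bottleneck
        for layer in (*self.head1, *self.head2):
            g = layer.forward(g, training)
        dir_logits = self.head_fc.forward(self.head_flat.forward(g, training), training)
        self.shapes["mask_out"] = mask_logits.shape[1:]
        self.shapes["dir_out"] = dir_logits.shape[1:]
        self._acts = acts if training else None
        return mask_logits, dir_logits

    def backward(self, dmask: np.ndarray, ddir: np.ndarray) -> None:
        g = self.head_flat.backward(self.head_fc.backward(ddir))
        for layer in reversed((*self.head1, *self.head2)):
            g = layer.backward(g)
        dbott_head = g
        dd = self.out_conv.backward(dmask)
        skip_grads = []
        for ct in reversed(self.dec):
            skip_grads.append(dd)
            dd = ct.backward(dd)
        skip_grads.reverse()  # skip_grads[j] pairs with acts[5 - j]
        dbott = dd + dbott_head
        h = dbott
        for layer in reversed(self.trans2):
            h = layer.backward(h)
        h = self.pool3.backward(h)
        for layer in reversed(self.trans1):
            h = layer.backward(h)
        g = h + skip_grads[0]  # gradient at acts[5]
        for i in range(5, -1, -1):
            conv, bn, relu = self.enc[i]
            g = conv.backward(bn.backward(relu.backward(g)))
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + skip_grads[6 - i]
        self._acts = None


class BinnedNet:
    """Binned classification tracker.

    Five [3x3 conv, 3x3 conv, 2x2 max-pool] blocks with ReLU activations,
    filter depths doubling 16 -> 256; the flattened encoder output feeds one
    fully connected layer per requested parameter, sized by that parameter's
    bin count.  Heads share the encoder but are otherwise independent.
    """

    family = "binned"

    def __init__(self, heads: BinnedHeadSpec, input_size: int = 480,
                 seed: int = 0):
        if input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        self.input_size = input_size
        self.heads = heads
        rng = np.random.default_rng(seed)
        layers = []
        c_prev = 1
        for i, c in enumerate(BINNED_FILTERS):
            layers += [nn.Conv2d(c_prev, c, 3, rng, f"b{i}a"), nn.ReLU(),
                       nn.Conv2d(c, c, 3, rng, f"b{i}b"), nn.ReLU(),
                       nn.MaxPool2d(2)]
            c_prev = c
        self.encoder = nn.Sequential(*layers)
        self.flat = nn.Flatten()
        t = input_size // 32
        n_flat = t * t * 256
        self.fcs = {name: nn.Linear(n_flat, heads.n_bins(name), rng, f"head_{name}")
                    for name in heads.ranges}
        self.shapes: Dict[str, tuple] = {}

    def params(self):
        out = self.encoder.params()
        for name in sorted(self.fcs):
            out += self.fcs[name].params()
        return out

    def bn_layers(self):
        return []

    def arch(self):
        return {"family": self.family, "input_size": self.input_size,
                "heads": {k: list(v) for k, v in self.heads.ranges.items()}}

    def forward(self, x: np.ndarray, training: bool = False):
        h = self.encoder.forward(x.astype(np.float32), training)
        self.shapes["encoder_terminal"] = h.shape[1:]
        f = self.flat.forward(h, training)
        out = {name: fc.forward(f, training) for name, fc in self.fcs.items()}
        self.shapes.update({f"head_{k}": v.shape[1:] for k, v in out.items()})
        return out

    def backward(self, dscores: Mapping[str, np.ndarray]) -> None:
        df = None
        for name, g in dscores.items():
            d = self.fcs[name].backward(g)
            df = d if df is None else df + d
        self.encoder.backward(self.flat.backward(df))


class RegressionNet:
    """Direct regression tracker: encoder, flatten, FC head to 6 outputs.

    The feature encoder is pluggable; the default is the binned family's
    VGG-style encoder (any encoder meeting the flatten-shape contract works).
    """

    family = "regression"

    def __init__(self, input_size: int = 480, encoder: str = "vgg",
                 seed: int = 0):
        if encoder != "vgg":
            raise ValueError(f"unknown encoder {encoder!r}")
        if input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        self.input_size = input_size
        self.encoder_name = encoder
        rng = np.random.default_rng(seed)
        layers = []
        c_prev = 1
        for i, c in enumerate(BINNED_FILTERS):
            layers += [nn.Conv2d(c_prev, c, 3, rng, f"e{i}a"), nn.ReLU(),
                       nn.Conv2d(c, c, 3, rng, f"e{i}b"), nn.ReLU(),
                       nn.MaxPool2d(2)]
            c_prev = c
        t = input_size // 32
        self.net = nn.Sequential(*layers, nn.Flatten(),
                                 nn.Linear(t * t * 256, 64, rng, "fc1"),
                                 nn.ReLU(), nn.Linear(64, 6, rng, "fc2"))
        self.shapes: Dict[str, tuple] = {}

    def params(self):
        return self.net.params()

    def bn_layers(self):
        return []

    def arch(self):
        return {"family": self.family, "input_size": self.input_size,
                "encoder": self.encoder_name}

    def forward(self, x: np.ndarray, training: bool = False):
        out = self.net.forward(x.astype(np.float32), training)
        self.shapes["out"] = out.shape[1:]
        return out

    def backward(self, dout: np.ndarray) -> None:
        self.net.backward(dout)


# ---------------------------------------------------------------------------
# Builders


def build_segmentation_net(spec: ArchitectureSpec) -> SegmentationNet:
    if spec.family != "segmentation":
        raise ValueError("spec.family must be 'segmentation'")
    return SegmentationNet(spec.input_size, seed=spec.seed)


def build_binned_net(spec: ArchitectureSpec,
                     heads: Optional[BinnedHeadSpec] = None) -> BinnedNet:
    if spec.family != "binned":
        raise ValueError("spec.family must be 'binned'")
    if heads is None:
        heads = BinnedHeadSpec.center_xy(spec.input_size)
    return BinnedNet(heads, spec.input_size, seed=spec.seed)


def build_regression_net(spec: ArchitectureSpec) -> RegressionNet:
    if spec.family != "regression":
        raise ValueError("spec.family must be 'regression'")
    return RegressionNet(spec.input_size, spec.encoder, seed=spec.seed)


# ---------------------------------------------------------------------------
# Losses (scalar values; training uses the gradient-bearing variants)


def segmentation_loss_grad(mask_logits, dir_logits, mask_true, dir_true):
    """Summed mask + direction cross entropy, with gradients wrt logits."""
    mask_true = np.asarray(mask_true)
    if not np.isin(np.unique(mask_true), [0, 1]).all():
        raise ValueError("mask labels must be binary")
    l1, g1 = softmax_cross_entropy(mask_logits, mask_true, axis=1)
    l2, g2 = softmax_cross_entropy(dir_logits, dir_true, axis=1)
    return l1 + l2, g1, g2


def segmentation_loss(mask_scores, dir_scores, mask_true, dir_true) -> float:
    """Mean per-pixel 2-class cross entropy plus 4-class direction cross
    entropy, summed."""
    loss, _, _ = segmentation_loss_grad(mask_scores, dir_scores,
                                        mask_true, dir_true)
    return loss


def binned_loss_grad(per_head_scores: Mapping[str, np.ndarray],
                     targets: Mapping[str, np.ndarray]):
    total = 0.0
    grads = {}
    for name, scores in per_head_scores.items():
        l, g = softmax_cross_entropy(scores, targets[name], axis=1)
        total += l
        grads[name] = g
    return total, grads


def binned_loss(per_head_scores, targets) -> float:
    """Sum of per-head categorical cross entropies."""
    loss, _ = binned_loss_grad(per_head_scores, targets)
    return loss


def regression_loss_grad(pred6: np.ndarray, target6: np.ndarray):
    pred6 = np.asarray(pred6, dtype=np.float64)
    target6 = np.asarray(target6, dtype=np.float64)
    diff = pred6 - target6
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 * diff / diff.size).astype(np.float32)


def regression_loss(pred6, target6) -> float:
    """Mean squared difference over the six ellipse parameters."""
    return regression_loss_grad(pred6, target6)[0]


# ---------------------------------------------------------------------------
# Decoders


def decode_binned(per_head_scores: Mapping[str, np.ndarray],
                  heads: BinnedHeadSpec) -> Dict[str, float]:
    """Argmax bin per head, decoded to the bin-center value.

    Ties break to the lowest bin index.  Returns a partial parameter dict
    (only the heads the network was built with).
    """
    out = {}
    for name, scores in per_head_scores.items():
        scores = np.asarray(scores).reshape(-1)
        if not np.isfinite(scores).all():
            raise ValueError(f"non-finite scores for head {name!r}")
        out[name] = heads.decode(name, int(np.argmax(scores)))
    return out


def decode_regression(out6: np.ndarray):
    """Six raw outputs -> EllipseFit (or UndirectedEllipse if directionless).

    The (sin, cos) pair is normalized to unit length before taking atan2;
    negative axis predictions are clamped to zero with a warning, and if the
    clamped axes come out reversed they are swapped (rotating theta by 90 deg)
    so the major >= minor invariant holds for the same ellipse.
    """
    out6 = np.asarray(out6, dtype=np.float64).reshape(-1)
    if out6.shape[0] != 6 or not np.isfinite(out6).all():
        raise ValueError("expected 6 finite values")
    x, y, major, minor, s, c = out6
    if major < 0 or minor < 0:
        warnings.warn("negative axis prediction clamped to 0")
        major, minor = max(major, 0.0), max(minor, 0.0)
    theta = np.degrees(np.arctan2(s, c)) % 360.0
    if major < minor:
        major, minor = minor, major
        theta = (theta + 90.0) % 360.0
    if np.hypot(s, c) < 1e-12:
        warnings.warn("degenerate (sin, cos) = (0, 0): direction unavailable")
        return UndirectedEllipse(x, y, major, minor, 0.0)
    return EllipseFit.from_angle(x, y, major, minor, theta)


def segmentation_to_ellipse(mask_scores: np.ndarray, dir_scores: np.ndarray,
                            threshold: float = 0.5):
    """Scores -> thresholded mask -> largest blob -> moment fit -> direction.

    ``mask_scores`` is (2, H, W) logits or probabilities; the foreground
    channel (index 1) is softmaxed against background and thresholded.
    Returns NO_DETECTION on an empty mask.  Tied direction scores resolve to
    the lowest class index.
    """
    mask_scores = np.asarray(mask_scores)
    if mask_scores.ndim != 3 or mask_scores.shape[0] != 2:
        raise ValueError("mask_scores must be (2, H, W)")
    prob_fg = softmax(mask_scores, axis=0)[1]
    mask = (prob_fg > threshold).astype(np.uint8)
    und = fit_ellipse_to_mask(mask)
    if und is NO_DETECTION:
        return NO_DETECTION
    q = CardinalDirection(int(np.argmax(np.asarray(dir_scores).reshape(-1))))
    return resolve_direction(und, q)


# ---------------------------------------------------------------------------
# Checkpoints (.npz: parameter arrays + batch-norm buffers + arch JSON)


def save_model(model, path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.bn_layers()):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    arrays["arch"] = np.frombuffer(
        json.dumps(model.arch()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    data = np.load(path)
    arch = json.loads(bytes(data["arch"]).decode())
    if arch["family"] == "segmentation":
        model = SegmentationNet(arch["input_size"])
    elif arch["family"] == "binned":
        heads = BinnedHeadSpec({k: tuple(v) for k, v in arch["heads"].items()})
        model = BinnedNet(heads, arch["input_size"])
    else:
        model = RegressionNet(arch["input_size"], arch["encoder"])
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, bn in enumerate(model.bn_layers()):
        bn.running_mean[...] = data[f"bn{i}_mean"]
        bn.running_var[...] = data[f"bn{i}_var"]
    return model


def copy_weights(src, dst) -> None:
    for ps, pd in zip(src.params(), dst.params()):
        pd.value[...] = ps.value
    for bs, bd in zip(src.bn_layers(), dst.bn_layers()):
        bd.running_mean[...] = bs.running_mean
        bd.running_var[...] = bs.running_var
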