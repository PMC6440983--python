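"""Dataset store: directory of PNG frames + PNG masks + one labels CSV,
or a single HDF5 file with the same fields."""

from __future__ import annotations

import os
from typing import List, Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .augmentation import TrainingSample
from .geometry import CardinalDirection, EllipseFit

LABEL_COLUMNS = ["sample_id", "x", "y", "major", "minor", "theta_deg", "direction"]


def save_dataset(samples: Sequence[TrainingSample], out_dir: str) -> None:
    frames_dir = os.path.join(out_dir, "frames")
    masks_dir = os.path.join(out_dir, "masks")
    os.makedirs(frames_dir, exist_ok=True)
    os.makedirs(masks_dir, exist_ok=True)
    rows = []
    for s in samples:
        iio.imwrite(os.path.join(frames_dir, f"{s.sample_id}.png"), s.frame)
        iio.imwrite(os.path.join(masks_dir, f"{s.sample_id}.png"),
                    (s.mask * 255).astype(np.uint8))
        e = s.ellipse
        rows.append([s.sample_id, e.x, e.y, e.major, e.minor, e.theta_deg,
                     s.direction.name.lower()])
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(
        os.path.join(out_dir, "labels.csv"), index=False)


def load_dataset(in_dir: str) -> List[TrainingSample]:
    labels = pd.read_csv(os.path.join(in_dir, "labels.csv"))
    missing = set(LABEL_COLUMNS) - set(labels.columns)
    if missing:
        raise ValueError(f"labels.csv missing columns: {sorted(missing)}")
    samples = []
    for row in labels.itertuples(index=False):
        sid = str(row.sample_id)
        frame = iio.imread(os.path.join(in_dir, "frames", f"{sid}.png"))
        mask = (iio.imread(os.path.join(in_dir, "masks", f"{sid}.png")) > 127
                ).astype(np.uint8)
        samples.append(TrainingSample(
            frame=np.asarray(frame, dtype=np.uint8), mask=mask,
            ellipse=EllipseFit.from_angle(row.x, row.y, row.major, row.minor,
                                          row.theta_deg),
            direction=CardinalDirection.from_name(row.direction),
            sample_id=sid))
    return samples


def save_dataset_hdf5(samples: Sequence[TrainingSample], path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.stack([s.frame for s in samples]))
        f.create_dataset("masks", data=np.stack([s.mask for s in samples]))
        f.create_dataset("labels", data=np.array(
            [[s.ellipse.x, s.ellipse.y, s.ellipse.major, s.ellipse.minor,
              s.ellipse.theta_deg, float(int(s.direction))] for s in samples]))
        f.create_dataset("sample_ids", data=np.array(
            [s.sample_id for s in samples], dtype="S"))


def load_dataset_hdf5(path: str) -> List[TrainingSample]:
    with h5py.File(path, "r") as f:
        frames = f["frames"][...]
        masks = f["masks"][...]
        labels = f["labels"][...]
        ids = [b.decode() for b in f["sample_ids"][...]]
    return [TrainingSample(
        frame=frames[i], mask=masks[i],
        ellipse=EllipseFit.from_angle(*labels[i, :5]),
        direction=CardinalDirection(int(labels[i, 5])),
        sample_id=ids[i]) for i in range(len(ids))]


def train_val_split(samples: Sequence[TrainingSample], n_val: int,
                    seed: int = 0):
    """Deterministic split, disjoint by sample id; validation is the tail."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    val_idx = set(order[len(samples) - n_val:].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val
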