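"""Static-posture classification from grey-scale pressure images.

Static (non-transition) frames are converted to 8-bit grey-scale images
with a fixed full-range mapping - 0 mmHg -> 0, the 200 mmHg sensor
ceiling -> 255 - so that absolute pressure magnitude survives the
conversion and remains available to the classifier (per-image
normalization would erase peak-pressure differences between postures).
A small convolutional network is trained per spatial resolution on an
80/20 split drawn within each subject (every subject contributes to both
splits, stratified by posture), and total accuracy on the held-out 20% is
the reported figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import (
    POSTURES,
    TRANSITION_LABEL,
    FrameSequence,
    PressureFrame,
    ValidationError,
)
from .nn import CNNConfig, SmallCNN
from .resample import block_pool

#: Fixed class order used for integer-encoding posture labels.
CLASS_ORDER = POSTURES


@dataclass(frozen=True)
class PostureImage:
    """One grey-scale pressure image with its ground-truth posture."""

    pixels: np.ndarray  # uint8, shape = the configuration's sensor grid
    label: str
    subject: str

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.dtype != np.uint8:
            raise ValidationError("pixels must be uint8")
        object.__setattr__(self, "pixels", pixels)
        if self.label not in CLASS_ORDER:
            raise ValidationError(f"unknown posture label {self.label!r}")


@dataclass(frozen=True)
class SplitPlan:
    """How to partition images into train and test sets.

    ``per_subject=True`` (default) draws the split within every subject,
    stratified by posture, so each subject contributes to both sets;
    ``per_subject=False`` holds out whole subjects instead.
    """

    train_fraction: float = 0.8
    per_subject: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")


def to_grayscale(
    frame: PressureFrame, label: str = "supine", subject: str = "s00"
) -> PostureImage:
    """Map a pressure frame to an 8-bit image.

    ``intensity = round(255 * p / ceiling)``, rounding half up, so 0 mmHg
    -> 0 and the ceiling -> 255.  The mapping is monotone and uses the
    fixed sensor range, never the per-frame maximum.
    """
    scaled = 255.0 * frame.values / frame.ceiling
    pixels = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)
    return PostureImage(pixels=pixels, label=label, subject=subject)


def build_dataset(cohort: list[FrameSequence], k: int = 1) -> list[PostureImage]:
    """Grey-scale images of every static (non-transition) frame in a
    cohort, block-pooled at spatial factor ``k``."""
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    images: list[PostureImage] = []
    for seq in cohort:
        for frame, label in zip(seq.frames, seq.posture_labels):
            if label == TRANSITION_LABEL:
                continue
            images.append(
                to_grayscale(block_pool(frame, k), label=label, subject=seq.subject)
            )
    if not images:
        raise ValidationError("cohort contains no static frames")
    return images


def split_dataset(
    images: list[PostureImage], split: SplitPlan
) -> tuple[list[int], list[int]]:
    """Deterministic train/test index partition according to ``split``.

    Groups are (subject, label) under the per-subject plan, whole
    subjects otherwise; within each group indices are shuffled with the
    plan's seed and the first ``train_fraction`` go to training.  Every
    group keeps at least one image on each side where its size permits.
    """
    rng = np.random.default_rng(split.seed)
    groups: dict[tuple, list[int]] = {}
    for idx, img in enumerate(images):
        key = (img.subject, img.label) if split.per_subject else (img.subject,)
        groups.setdefault(key, []).append(idx)

    train_idx: list[int] = []
    test_idx: list[int] = []
    if split.per_subject:
        for key in sorted(groups):
            members = np.array(groups[key])
            rng.shuffle(members)
            n_train = int(round(split.train_fraction * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1) if len(members) > 1 else 1
            train_idx.extend(members[:n_train].tolist())
            test_idx.extend(members[n_train:].tolist())
    else:
        subjects = sorted(groups)
        order = rng.permutation(len(subjects))
        n_train = int(round(split.train_fraction * len(subjects)))
        n_train = min(max(n_train, 1), len(subjects) - 1)
        for pos, s_idx in enumerate(order):
            target = train_idx if pos < n_train else test_idx
            target.extend(groups[subjects[s_idx]])
    return sorted(train_idx), sorted(test_idx)


def train_and_evaluate(
    images: list[PostureImage],
    split: SplitPlan | None = None,
    arch: CNNConfig | None = None,
    seed: int = 0,
) -> float:
    """Train the network on the 80% split and return total accuracy
    (correct / total) on the held-out 20%.

    Deterministic given ``seed`` (weight init and batch order) and the
    split plan's seed.  Requires at least two posture classes and a
    consistent image shape.
    """
    if split is None:
        split = SplitPlan(seed=seed)
    shape = images[0].pixels.shape
    if any(img.pixels.shape != shape for img in images):
        raise ValidationError("all images must share one shape")
    labels = sorted({img.label for img in images})
    if len(labels) < 2:
        raise ValidationError("need at least two posture classes")

    x = np.stack([img.pixels for img in images]).astype(float) / 255.0
    y = np.array([CLASS_ORDER.index(img.label) for img in images])
    train_idx, test_idx = split_dataset(images, split)
    if not test_idx:
        raise ValidationError("empty test split")
    if split.per_subject:
        for subject in {images[i].subject for i in range(len(images))}:
            train_classes = {images[i].label for i in train_idx if images[i].subject == subject}
            if train_classes != set(labels):
                raise ValidationError(
                    f"subject {subject} is missing a class in the training split"
                )

    net = SmallCNN(shape, n_classes=len(CLASS_ORDER), config=arch, seed=seed)
    net.fit(x[train_idx], y[train_idx])
    predictions = net.predict(x[test_idx])
    return float(np.mean(predictions == y[test_idx]))


def accuracy_by_resolution(
    cohort: list[FrameSequence],
    ks: tuple[int, ...] = (1, 2, 3, 4, 5),
    split: SplitPlan | None = None,
    arch: CNNConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Total classification accuracy at each spatial resolution.

    Each resolution is trained and evaluated independently (results do
    not depend on the order of ``ks``).  Returns a table with columns
    ``regime, block, n_sensors, accuracy``.
    """
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    regime = cohort[0].mattress
    rows, cols = cohort[0].shape
    records = []
    for k in ks:
        images = build_dataset(cohort, k)
        acc = train_and_evaluate(images, split=split, arch=arch, seed=seed)
        records.append(
            {
                "regime": regime,
                "block": k,
                "n_sensors": (rows // k) * (cols // k),
                "accuracy": acc,
            }
        )
    return pd.DataFrame.from_records(records)
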