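"""Synthetic two-class imbalanced datasets with a controllable signal.

The generators stand in for curated image benchmarks at desk scale: the
quantity under study is how a loss function copes with class imbalance, so
what matters is a binary dataset whose majority:minority proportion, class
separability (hence Bayes error) and random seed are all explicit knobs.

Two modes are provided:

* ``features`` -- two isotropic Gaussian clouds in ``dims`` dimensions whose
  centers are ``signal`` apart (unit noise), i.e. a problem with a known,
  tunable Bayes error.
* ``images``   -- small single-channel images in [0, 1] where the two
  classes carry a class-specific Gaussian blob at different positions, plus
  pixel noise with standard deviation ``1 / signal``.

The canonical scenario grid spans 50:50 through 98:2.  Splits are 70/30 and
stratified, so even the 98:2 scenario keeps minority samples in the test
set and the unweighted accuracy stays defined.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "CANONICAL_SCENARIOS",
    "ScenarioSpec",
    "LabeledDataset",
    "generate_feature_clouds",
    "generate_pattern_images",
    "generate",
    "stratified_split",
    "augment_images",
    "save_dataset",
    "load_dataset",
]

#: the 11 canonical majority fractions, 50:50 ... 98:2
CANONICAL_SCENARIOS = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.98)


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one imbalance scenario.

    ``majority_fraction`` 0.90 means a 90:10 split between class 0 (the
    majority) and class 1 (the minority).  ``signal`` is the separation of
    the class centers in feature mode and the inverse pixel-noise scale in
    image mode.
    """

    n_total: int = 1000
    majority_fraction: float = 0.90
    seed: int = 0
    mode: str = "features"
    signal: float = 2.0
    dims: int | tuple[int, int] = 16

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not (0.5 <= self.majority_fraction < 1.0):
            raise ValueError("majority_fraction must lie in [0.5, 1)")
        if self.mode not in ("features", "images"):
            raise ValueError("mode must be 'features' or 'images'")
        if self.signal < 0 or (self.mode == "images" and self.signal <= 0):
            # image noise scales as 1/signal, so images need signal > 0;
            # feature clouds accept signal = 0 (pure-noise control)
            raise ValueError("signal must be >= 0 (strictly positive for images)")
        if self.minority_count < 1:
            raise ValueError(
                f"scenario yields no minority samples "
                f"(n_total={self.n_total}, majority_fraction={self.majority_fraction})"
            )

    @property
    def majority_count(self) -> int:
        return int(round(self.n_total * self.majority_fraction))

    @property
    def minority_count(self) -> int:
        return self.n_total - self.majority_count

    @property
    def name(self) -> str:
        maj = round(100 * self.majority_fraction)
        return f"{maj}:{100 - maj}"


@dataclass(frozen=True)
class LabeledDataset:
    """Samples, binary labels and a train/test partition.

    ``samples`` is (n, dims) in feature mode or (n, H, W) in image mode.
    Class 0 is the majority class.
    """

    samples: np.ndarray
    labels: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def X_train(self) -> np.ndarray:
        return self.samples[self.train_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        return self.samples[self.test_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels[self.test_idx]


def _labels_for(spec: ScenarioSpec) -> np.ndarray:
    y = np.zeros(spec.n_total, dtype=int)
    y[spec.majority_count :] = 1
    return y


def generate_feature_clouds(spec: ScenarioSpec) -> LabeledDataset:
    """Two Gaussian clouds with centers ``signal`` apart and unit noise.

    The center offset direction is a seeded random unit vector, so the
    discriminative direction is not axis-aligned.
    """
    if spec.mode != "features":
        raise ValueError("spec.mode must be 'features'")
    dims = int(spec.dims) if np.isscalar(spec.dims) else int(np.prod(spec.dims))
    rng = np.random.default_rng(spec.seed)
    direction = rng.standard_normal(dims)
    direction /= np.linalg.norm(direction)
    y = _labels_for(spec)
    X = rng.standard_normal((spec.n_total, dims))
    X[y == 1] += spec.signal * direction
    return stratified_split(
        LabeledDataset(X, y, np.empty(0, int), np.empty(0, int)), seed=spec.seed
    )


def generate_pattern_images(spec: ScenarioSpec) -> LabeledDataset:
    """Single-channel images whose classes differ by blob position.

    Each class has a Gaussian bump at a class-specific, seed-jittered
    location; pixel noise has standard deviation ``1 / signal``; pixel
    values are clipped to [0, 1].
    """
    if spec.mode != "images":
        raise ValueError("spec.mode must be 'images'")
    if np.isscalar(spec.dims):
        H = W = int(spec.dims)
    else:
        H, W = (int(v) for v in spec.dims)
    rng = np.random.default_rng(spec.seed)
    y = _labels_for(spec)
    ii, jj = np.mgrid[0:H, 0:W]
    # class-specific blob centers in opposite image quadrants
    centers = {
        0: (H * 0.32 + rng.uniform(-1, 1), W * 0.32 + rng.uniform(-1, 1)),
        1: (H * 0.68 + rng.uniform(-1, 1), W * 0.68 + rng.uniform(-1, 1)),
    }
    width = max(H, W) / 6.0
    X = rng.standard_normal((spec.n_total, H, W)) / spec.signal
    for cls, (ci, cj) in centers.items():
        blob = np.exp(-(((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * width**2)))
        X[y == cls] += blob
    X = np.clip(X, 0.0, 1.0)
    return stratified_split(
        LabeledDataset(X, y, np.empty(0, int), np.empty(0, int)), seed=spec.seed
    )


def generate(spec: ScenarioSpec) -> LabeledDataset:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "features":
        return generate_feature_clouds(spec)
    return generate_pattern_images(spec)


def stratified_split(
    dataset: LabeledDataset, train_fraction: float = 0.7, seed: int = 0
) -> LabeledDataset:
    """70/30 (by default) stratified train/test partition.

    Stratification preserves the class proportions in both partitions;
    without it a 98:2 scenario can easily lose every minority test sample.
    """
    counts = np.bincount(dataset.labels, minlength=2)
    if (counts < 2).any():
        raise ValueError("both classes need >= 2 samples to stratify a split")
    idx = np.arange(dataset.n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=dataset.labels,
        random_state=seed % (2**32),
    )
    return replace(
        dataset, train_idx=np.sort(train_idx), test_idx=np.sort(test_idx)
    )


def augment_images(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flips and quarter-turn rotations, independently per image.

    Optional stage-1 transform for image mode; off by default.
    """
    out = images.copy()
    flips_lr = rng.random(len(out)) < 0.5
    flips_ud = rng.random(len(out)) < 0.5
    rots = rng.integers(0, 4, len(out))
    for i in range(len(out)):
        img = out[i]
        if flips_lr[i]:
            img = img[:, ::-1]
        if flips_ud[i]:
            img = img[::-1, :]
        out[i] = np.rot90(img, k=int(rots[i]))
    return out


def save_dataset(dataset: LabeledDataset, path: str | os.PathLike) -> None:
    """Persist a dataset.

    Feature mode: one CSV with feature columns, a label column and a split
    column.  Image mode: PNG files under class-named directories plus a
    ``labels.csv`` (filename, label, split).
    """
    path = Path(path)
    split = np.full(dataset.n, "train", dtype=object)
    split[dataset.test_idx] = "test"
    if dataset.samples.ndim == 2:
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            dataset.samples,
            columns=[f"f{i}" for i in range(dataset.samples.shape[1])],
        )
        df["label"] = dataset.labels
        df["split"] = split
        df.to_csv(path, index=False)
    else:
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, lab) in enumerate(zip(dataset.samples, dataset.labels)):
            sub = path / f"class_{lab}"
            sub.mkdir(exist_ok=True)
            fname = f"class_{lab}/img_{i:05d}.png"
            Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path / fname)
            rows.append((fname, int(lab), split[i]))
        pd.DataFrame(rows, columns=["filename", "label", "split"]).to_csv(
            path / "labels.csv", index=False
        )


def load_dataset(path: str | os.PathLike) -> LabeledDataset:
    """Inverse of :func:`save_dataset` (images are rescaled back to [0, 1])."""
    path = Path(path)
    if path.is_dir():
        from PIL import Image

        meta = pd.read_csv(path / "labels.csv")
        samples = np.stack(
            [
                np.asarray(Image.open(path / fname), dtype=float) / 255.0
                for fname in meta["filename"]
            ]
        )
        labels = meta["label"].to_numpy()
        split = meta["split"].to_numpy()
    else:
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f")]
        samples = df[feat_cols].to_numpy(dtype=float)
        labels = df["label"].to_numpy()
        split = df["split"].to_numpy()
    return LabeledDataset(
        samples,
        labels.astype(int),
        train_idx=np.flatnonzero(split == "train"),
        test_idx=np.flatnonzero(split == "test"),
    )
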