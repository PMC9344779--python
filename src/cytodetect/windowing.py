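"""Sliding-window dataset construction for the patch classifier.

The image is tiled into fixed-size windows (default 96 × 96 px, stride =
window, partial edge windows dropped).  A window is a positive "nucleus"
sample iff some blue-lineage nucleus has strictly more than half of its
total mask area inside the window; red-lineage nuclei never label a window
positive, because the basal (blue-stained) lineage is the diagnostically
relevant one.  Balanced datasets are assembled without replacement and split
into stratified train/test groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import SyntheticScene

WINDOW_SIZE = 96  # px, classifier input side

LABEL_NUCLEUS = "nucleus"
LABEL_NON_NUCLEUS = "non_nucleus"


@dataclass
class WindowSample:
    """One window: pixels, label, and provenance."""

    patch: np.ndarray  # uint8, window x window x 3
    label: str
    origin: tuple[int, int]  # (row, col) of top-left, 0-based
    source_id: str
    covered_instance_ids: list[int] = field(default_factory=list)


@dataclass
class WindowDataset:
    """Stratified train/test split of window samples."""

    train: list[WindowSample]
    test: list[WindowSample]
    split_seed: int

    @property
    def class_counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for name, split in (("train", self.train), ("test", self.test)):
            counts: dict[str, int] = {}
            for s in split:
                counts[s.label] = counts.get(s.label, 0) + 1
            out[name] = counts
        return out


def tile_image(image: np.ndarray, window: int = WINDOW_SIZE,
               stride: int | None = None) -> list[tuple[tuple[int, int], np.ndarray]]:
    """All fully-contained windows with top-left on the stride grid.

    Returns ``[((row, col), patch), ...]`` in row-major order; windows that
    would extend past the image edge are dropped (the classifier takes a
    fixed input size, and padding would inject synthetic borders).
    """
    if stride is None:
        stride = window
    H, W = image.shape[:2]
    if window > min(H, W):
        raise ValueError(f"window {window} larger than image {H}x{W}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    tiles = []
    for r in range(0, H - window + 1, stride):
        for c in range(0, W - window + 1, stride):
            tiles.append(((r, c), image[r:r + window, c:c + window]))
    return tiles


def label_window(origin: tuple[int, int], scene: SyntheticScene,
                 window: int = WINDOW_SIZE,
                 coverage_threshold: float = 0.5) -> tuple[str, list[int]]:
    """Label one window by the strict more-than-half-of-the-nucleus rule.

    A blue-lineage instance qualifies when (mask area inside the window) /
    (total mask area) is *strictly* greater than ``coverage_threshold``;
    exactly half does not qualify.  Red-lineage instances never do.
    """
    r, c = origin
    H, W = scene.shape
    if r < 0 or c < 0 or r + window > H or c + window > W:
        raise ValueError(f"window at {origin} not fully inside {H}x{W} image")
    covered = []
    for inst in scene.instances:
        if inst.lineage != "blue":
            continue
        r0, c0, r1, c1 = inst.bbox
        if r1 <= r or r0 >= r + window or c1 <= c or c0 >= c + window:
            continue
        inside = int(inst.mask[r:r + window, c:c + window].sum())
        if inside / inst.area > coverage_threshold:
            covered.append(inst.id)
    label = LABEL_NUCLEUS if covered else LABEL_NON_NUCLEUS
    return label, covered


def iter_window_samples(scene: SyntheticScene, window: int = WINDOW_SIZE,
                        stride: int | None = None,
                        coverage_threshold: float = 0.5) -> Iterable[WindowSample]:
    """Every tiled window of one scene, labelled."""
    for origin, patch in tile_image(scene.image, window, stride):
        label, covered = label_window(origin, scene, window, coverage_threshold)
        yield WindowSample(patch=patch.copy(), label=label, origin=origin,
                           source_id=scene.source_id,
                           covered_instance_ids=covered)


def assemble_balanced_dataset(scenes: Iterable[SyntheticScene],
                              n_per_class: int, seed: int,
                              window: int = WINDOW_SIZE,
                              stride: int | None = None) -> list[WindowSample]:
    """Draw exactly ``n_per_class`` windows of each label without replacement.

    Scenes may be any iterable (a generator keeps memory flat); candidate
    windows are collected across all scenes, then sampled reproducibly and
    shuffled under ``seed``.  Raises ``ValueError`` naming the deficient
    class when a label has too few candidates.
    """
    pos: list[WindowSample] = []
    neg: list[WindowSample] = []
    for scene in scenes:
        for sample in iter_window_samples(scene, window, stride):
            (pos if sample.label == LABEL_NUCLEUS else neg).append(sample)
    for name, pool in ((LABEL_NUCLEUS, pos), (LABEL_NON_NUCLEUS, neg)):
        if len(pool) < n_per_class:
            raise ValueError(
                f"insufficient '{name}' candidates: have {len(pool)}, "
                f"need {n_per_class}")
    rng = np.random.default_rng(seed)
    chosen = [pos[i] for i in rng.choice(len(pos), n_per_class, replace=False)]
    chosen += [neg[i] for i in rng.choice(len(neg), n_per_class, replace=False)]
    rng.shuffle(chosen)
    return chosen


def split_dataset(samples: Sequence[WindowSample], train_fraction: float = 0.75,
                  seed: int = 0) -> WindowDataset:
    """Stratified train/test split.

    The total training count is ``floor(train_fraction * n)``, apportioned
    across labels by largest remainder so per-label train fractions deviate
    from ``train_fraction`` by less than one sample.  788 balanced samples at
    fraction 3/4 therefore split 591 / 197.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_label: dict[str, list[WindowSample]] = {}
    for s in samples:
        by_label.setdefault(s.label, []).append(s)
    for label, group in by_label.items():
        if len(group) < 2:
            raise ValueError(f"label '{label}' has fewer than 2 samples")

    n_total = len(samples)
    n_train_total = int(np.floor(train_fraction * n_total))
    labels = sorted(by_label)  # deterministic apportionment order
    quotas = {lb: train_fraction * len(by_label[lb]) for lb in labels}
    alloc = {lb: int(np.floor(quotas[lb])) for lb in labels}
    remainder = n_train_total - sum(alloc.values())
    by_frac = sorted(labels, key=lambda lb: (-(quotas[lb] - alloc[lb]), lb))
    for lb in by_frac[:remainder]:
        alloc[lb] += 1

    rng = np.random.default_rng(seed)
    train: list[WindowSample] = []
    test: list[WindowSample] = []
    for lb in labels:
        group = by_label[lb]
        order = rng.permutation(len(group))
        k = alloc[lb]
        train += [group[i] for i in order[:k]]
        test += [group[i] for i in order[k:]]
    return WindowDataset(train=train, test=test, split_seed=seed)


def export_patches(dataset: WindowDataset, directory: str | Path) -> pd.DataFrame:
    """Write each patch as PNG and a CSV index of the whole dataset."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for split_name, split in (("train", dataset.train), ("test", dataset.test)):
        for s in split:
            name = f"{s.source_id}_{s.origin[0]}_{s.origin[1]}_{s.label}.png"
            iio.imwrite(directory / name, s.patch)
            rows.append({"source_id": s.source_id, "origin_row": s.origin[0],
                         "origin_col": s.origin[1], "label": s.label,
                         "split": split_name, "file": name})
    index = pd.DataFrame(rows)
    index.to_csv(directory / "dataset_index.csv", index=False)
    return index
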