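"""Instance-level nucleus detection.

Two pluggable backends share one output contract (a :class:`DetectionSet`
of scored, mask-carrying detections):

* :func:`oracle_detect` — a closed-form hue-threshold detector.  Blue-stained
  nuclei are saturated and dark inside a known hue band, so thresholding hue
  and saturation and taking connected components recovers them exactly on
  clean material.  It serves as the brute-force reference detector.

* :class:`InstanceSegmenter` — a *trainable* propose-and-score detector in
  the spirit of two-stage instance segmentation: a per-pixel softmax
  classifier over colour/texture features produces a "nucleusness"
  probability map (the proposal stage), connected regions above threshold
  become candidate instances, each scored by its mean probability, and
  overlapping candidates are pruned by non-maximum suppression.  It is
  trained on image + mask pairs by minimising pixel-wise cross-entropy with
  Adam, and reports per-epoch training and validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv

from .synthetic import BLUE_HUE_BAND

DEFAULT_MIN_AREA = 20  # px, matches the minimum nucleus area of the generator


@dataclass
class Detection:
    """One detected instance: half-open box, full-image mask, score, class."""

    box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray  # bool, image-sized
    score: float
    predicted_class: str = "blue_nucleus"


@dataclass
class DetectionSet:
    detections: list[Detection]
    source_id: str = ""
    backend: str = ""
    score_threshold: float = 0.5
    nms_threshold: float = 0.5

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class MaskTrainingPair:
    """One teacher image with its instance masks (possibly none = pure negative)."""

    image: np.ndarray  # uint8 RGB
    masks: list[np.ndarray] = field(default_factory=list)  # bool rasters
    class_tags: list[str] = field(default_factory=list)  # e.g. cytology class


def _mask_to_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _box_iou(a: tuple, b: tuple) -> float:
    r0 = max(a[0], b[0]); c0 = max(a[1], b[1])
    r1 = min(a[2], b[2]); c1 = min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def nms(detections: list[Detection], threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression on box IoU; idempotent."""
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, detections[i].box))
    kept: list[Detection] = []
    for i in order:
        det = detections[i]
        if all(_box_iou(det.box, k.box) <= threshold for k in kept):
            kept.append(det)
    return kept


def components_to_detections(binary: np.ndarray, score_map: np.ndarray | None,
                             min_area: int,
                             predicted_class: str = "blue_nucleus",
                             ) -> list[Detection]:
    """4-connected components of a binary map become scored detections."""
    labels = measure.label(binary, connectivity=1)
    dets = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        mask = labels == region.label
        score = 1.0 if score_map is None else float(score_map[mask].mean())
        dets.append(Detection(box=_mask_to_box(mask), mask=mask, score=score,
                              predicted_class=predicted_class))
    return dets


def oracle_detect(image: np.ndarray,
                  blue_hue_band: tuple[float, float] = BLUE_HUE_BAND,
                  min_area: int = DEFAULT_MIN_AREA,
                  min_saturation: float = 0.45,
                  source_id: str = "") -> DetectionSet:
    """Closed-form hue-threshold nucleus detector (score 1.0 per component).

    Nucleus pixels are those whose hue lies in the blue band *and* whose
    saturation exceeds ``min_saturation`` — the saturation gate separates
    the deeply stained nucleus from its paler cytoplasm halo of the same
    hue.  The predicate depends only on hue and saturation, so it is
    invariant to image-wide brightness (value) shifts.
    """
    hsv = rgb2hsv(image.astype(np.float64) / 255.0)
    binary = ((hsv[..., 0] >= blue_hue_band[0])
              & (hsv[..., 0] <= blue_hue_band[1])
              & (hsv[..., 1] >= min_saturation))
    dets = components_to_detections(binary, None, min_area)
    return DetectionSet(detections=dets, source_id=source_id,
                        backend="oracle", score_threshold=1.0,
                        nms_threshold=1.0)


# ---------------------------------------------------------------------------
# Trainable backend
# ---------------------------------------------------------------------------

def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: RGB, HSV and a 5×5 local RGB mean (9 channels)."""
    rgb = image.astype(np.float32) / 255.0
    hsv = rgb2hsv(rgb).astype(np.float32)
    local = np.stack([ndimage.uniform_filter(rgb[..., c], size=5)
                      for c in range(3)], axis=-1)
    return np.concatenate([rgb, hsv, local], axis=-1)


class NotTrainedError(RuntimeError):
    pass


class InstanceSegmenter:
    """Propose-and-score instance detector trained on image + mask pairs."""

    N_FEATURES = 9

    def __init__(self, seed: int = 0) -> None:
        self.rng = np.random.default_rng(seed)
        self.W = np.zeros((self.N_FEATURES + 1, 2), dtype=np.float32)
        self.trained = False

    def _scores(self, feats: np.ndarray) -> np.ndarray:
        z = feats @ self.W[:-1] + self.W[-1]
        z -= z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def probability_map(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel nucleusness in [0, 1]."""
        if not self.trained:
            raise NotTrainedError("backend has not been trained")
        return self._scores(_pixel_features(image))[..., 1]


def _pair_pixels(pair: MaskTrainingPair, rng: np.random.Generator,
                 max_per_class: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    feats = _pixel_features(pair.image).reshape(-1, InstanceSegmenter.N_FEATURES)
    fg = np.zeros(pair.image.shape[:2], dtype=bool)
    for m in pair.masks:
        if m.shape != pair.image.shape[:2]:
            raise ValueError("mask shape differs from image shape")
        fg |= m
    fg = fg.ravel()
    pos_idx = np.flatnonzero(fg)
    neg_idx = np.flatnonzero(~fg)
    if len(pos_idx) > max_per_class:
        pos_idx = rng.choice(pos_idx, max_per_class, replace=False)
    n_neg = min(len(neg_idx), max(len(pos_idx), 1) if len(pos_idx) else max_per_class)
    neg_idx = rng.choice(neg_idx, n_neg, replace=False)
    idx = np.concatenate([pos_idx, neg_idx])
    y = np.concatenate([np.ones(len(pos_idx), dtype=np.int64),
                        np.zeros(len(neg_idx), dtype=np.int64)])
    return feats[idx], y


def train_instance_segmenter(pairs: list[MaskTrainingPair], epochs: int = 10,
                             seed: int = 0, val_fraction: float = 0.2,
                             learning_rate: float = 0.05, batch_size: int = 1024,
                             ) -> tuple[InstanceSegmenter, list[dict]]:
    """Fit the per-pixel classifier on teacher pairs; return per-epoch losses.

    Pixels are sampled class-balanced from each pair (images without masks
    contribute background pixels only, i.e. act as pure negatives).  The
    last ``val_fraction`` of the pairs is held out for the validation loss.
    History entries carry ``train_loss`` and ``val_loss``; on any learnable
    corpus the final validation loss falls below the initial one.
    """
    if not pairs:
        raise ValueError("training pairs must be non-empty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    from . import _nn

    model = InstanceSegmenter(seed=seed)
    rng = model.rng
    n_val = max(1, int(round(val_fraction * len(pairs)))) if len(pairs) > 1 else 0
    train_pairs = pairs[:len(pairs) - n_val]
    val_pairs = pairs[len(pairs) - n_val:]
    if not train_pairs:
        train_pairs, val_pairs = pairs, pairs

    xt, yt = map(np.concatenate, zip(*[_pair_pixels(p, rng) for p in train_pairs]))
    if val_pairs:
        xv, yv = map(np.concatenate, zip(*[_pair_pixels(p, rng) for p in val_pairs]))
    else:  # pragma: no cover
        xv, yv = xt, yt

    model.W[...] = rng.normal(0, 0.01, size=model.W.shape)
    grads = np.zeros_like(model.W)
    opt = _nn.Adam([model.W], [grads], lr=learning_rate)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(xt))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb, yb = xt[idx], yt[idx]
            probs = model._scores(xb)
            _, g = _nn.softmax_cross_entropy(probs, yb)
            grads[:-1] = xb.T @ g
            grads[-1] = g.sum(axis=0)
            opt.step()
        tr_loss, _ = _nn.softmax_cross_entropy(model._scores(xt), yt)
        val_loss, _ = _nn.softmax_cross_entropy(model._scores(xv), yv)
        history.append({"train_loss": tr_loss, "val_loss": val_loss})
    model.trained = True
    return model, history


def detect(model: InstanceSegmenter, image: np.ndarray,
           score_threshold: float = 0.5, nms_threshold: float = 0.5,
           min_area: int = DEFAULT_MIN_AREA, mask_threshold: float = 0.5,
           source_id: str = "") -> DetectionSet:
    """Run the trained backend: probability map → regions → score filter → NMS."""
    pmap = model.probability_map(image)  # raises NotTrainedError if untrained
    dets = components_to_detections(pmap > mask_threshold, pmap, min_area)
    dets = [d for d in dets if d.score >= score_threshold]
    dets = nms(dets, nms_threshold)
    return DetectionSet(detections=dets, source_id=source_id,
                        backend="instance_segmenter",
                        score_threshold=score_threshold,
                        nms_threshold=nms_threshold)


def save_segmenter(model: InstanceSegmenter, path) -> None:
    np.savez(path, W=model.W, trained=np.array(model.trained))


def load_segmenter(path) -> InstanceSegmenter:
    model = InstanceSegmenter()
    with np.load(path) as data:
        model.W = data["W"].astype(np.float32)
        model.trained = bool(data["trained"])
    return model


def detections_to_coco(dset: DetectionSet, image_id: int = 1) -> list[dict]:
    """COCO-results-style records (bbox is [x, y, w, h])."""
    out = []
    for det in dset.detections:
        r0, c0, r1, c1 = det.box
        out.append({"image_id": image_id, "category_id": 1,
                    "bbox": [c0, r0, c1 - c0, r1 - r0],
                    "score": det.score,
                    "category_name": det.predicted_class})
    return out


def detections_labeled_mask(dset: DetectionSet,
                            shape: tuple[int, int]) -> np.ndarray:
    """uint16 raster labelling each detection 1..K in score order."""
    lab = np.zeros(shape, dtype=np.uint16)
    for k, det in enumerate(sorted(dset.detections, key=lambda d: -d.score)):
        lab[det.mask & (lab == 0)] = k + 1
    return lab


def windows_to_detections(pmap, image_shape: tuple[int, int],
                          threshold: float = 0.5) -> DetectionSet:
    """Window-level classifier output as a DetectionSet (square masks).

    Every window whose nucleus probability strictly exceeds ``threshold``
    becomes one detection — the counting unit of the sliding-window method.
    """
    dets = []
    w = pmap.window
    for (r, c), p in sorted(pmap.probs.items()):
        if p > threshold:
            mask = np.zeros(image_shape, dtype=bool)
            mask[r:r + w, c:c + w] = True
            dets.append(Detection(box=(r, c, r + w, c + w), mask=mask,
                                  score=float(p)))
    return DetectionSet(detections=dets, source_id=pmap.source_id,
                        backend="swm", score_threshold=threshold,
                        nms_threshold=1.0)
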