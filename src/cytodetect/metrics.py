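"""The four-criterion comparison protocol for nucleus detectors.

Detections from either backend are matched to blue-lineage ground-truth
nuclei and summarised by four criteria:

1. number of detections (D);
2. fraction of detections incorrectly raised from background (B / D);
3. average number of undetectable nuclear regions per nucleus (U / N);
4. average number of regions detected per nucleus (M / N, with M = D − B).

A detection is *background* when its region overlaps no blue-lineage
nucleus under the matching criterion.  The default criterion is permissive
— at least 25 % of the detection's area on a nucleus, or the nucleus
centroid inside the detection mask — approximating the visual matching a
human assessor performs; strict IoU ≥ 0.5 is available as an alternative.

"Undetectable regions" differ per backend.  For instance-level detectors
every nucleus has exactly one expected region.  For the sliding-window
method a nucleus's expected regions are its positively-labelled windows
(the windows holding more than half of it), and a region is undetected when
that window is absent from the detection set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .detection import DetectionSet
from .synthetic import SyntheticScene
from .windowing import WINDOW_SIZE, LABEL_NUCLEUS, label_window, tile_image


@dataclass
class MatchResult:
    """Raw matched-region accounting for one image (or a pooled set)."""

    n_detections: int  # D
    n_background_detections: int  # B
    n_gt_nuclei: int  # N
    n_undetected_regions_total: int  # U
    n_matched_regions_total: int  # M = D - B
    per_nucleus_regions: dict[int, list[int]] = field(default_factory=dict)
    per_nucleus_undetected: dict[int, int] = field(default_factory=dict)
    mode: str = "instance"
    image_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.n_background_detections <= self.n_detections
        assert self.n_matched_regions_total <= self.n_detections
        assert self.n_undetected_regions_total >= 0


@dataclass
class ComparisonMetrics:
    n_detections: int
    background_fraction: float
    avg_undetected_per_nucleus: float
    avg_regions_per_nucleus: float


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def detection_matches_nucleus(det_mask: np.ndarray, gt_mask: np.ndarray,
                              criterion: str = "permissive",
                              min_fraction: float = 0.25,
                              iou_threshold: float = 0.5) -> bool:
    """Does one detection region match one ground-truth nucleus?

    ``permissive``: |det ∩ gt| / |det| >= ``min_fraction`` OR the nucleus
    centroid lies inside the detection mask.  ``iou``: IoU >= threshold.
    """
    inter = int(np.logical_and(det_mask, gt_mask).sum())
    if criterion == "iou":
        union = int(np.logical_or(det_mask, gt_mask).sum())
        return union > 0 and inter / union >= iou_threshold
    if criterion != "permissive":
        raise ValueError(f"unknown overlap criterion: {criterion!r}")
    det_area = int(det_mask.sum())
    if det_area and inter / det_area >= min_fraction:
        return True
    rows, cols = np.nonzero(gt_mask)
    cr, cc = int(round(rows.mean())), int(round(cols.mean()))
    return bool(det_mask[cr, cc])


def match_detections(detections: DetectionSet, scene: SyntheticScene,
                     overlap_criterion: str = "permissive",
                     mode: str | None = None,
                     window: int = WINDOW_SIZE,
                     stride: int | None = None) -> MatchResult:
    """Assign every detection to ground-truth nuclei or background.

    ``mode`` is "swm" (window detections; expected regions per nucleus are
    its positively-labelled windows) or "instance" (expected regions per
    nucleus = 1); by default it follows the DetectionSet's backend name.
    Raises on a coordinate-frame mismatch between masks and the scene.
    """
    if mode is None:
        mode = "swm" if detections.backend == "swm" else "instance"
    H, W = scene.shape
    for det in detections.detections:
        if det.mask.shape != (H, W):
            raise ValueError(
                f"coordinate-frame mismatch: detection mask {det.mask.shape} "
                f"vs scene {scene.shape}")

    blue = scene.blue_instances()
    per_nucleus: dict[int, list[int]] = {inst.id: [] for inst in blue}
    n_background = 0
    for d_idx, det in enumerate(detections.detections):
        matched = False
        r0, c0, r1, c1 = det.box
        for inst in blue:
            ir0, ic0, ir1, ic1 = inst.bbox
            if ir1 <= r0 or ir0 >= r1 or ic1 <= c0 or ic0 >= c1:
                continue  # disjoint boxes cannot match under either criterion
            if detection_matches_nucleus(det.mask, inst.mask, overlap_criterion):
                per_nucleus[inst.id].append(d_idx)
                matched = True
        if not matched:
            n_background += 1

    D = len(detections.detections)
    M = D - n_background
    per_nucleus_undetected: dict[int, int] = {}
    if mode == "swm":
        # expected regions: the positively-labelled windows of the full tiling
        detected_origins = {(d.box[0], d.box[1])
                            for d in detections.detections}
        for inst in blue:
            expected = []
            for origin, _ in tile_image(scene.image, window, stride):
                label, covered = label_window(origin, scene, window)
                if label == LABEL_NUCLEUS and inst.id in covered:
                    expected.append(origin)
            per_nucleus_undetected[inst.id] = sum(
                1 for o in expected if o not in detected_origins)
    else:
        for inst in blue:
            per_nucleus_undetected[inst.id] = 0 if per_nucleus[inst.id] else 1

    return MatchResult(
        n_detections=D, n_background_detections=n_background,
        n_gt_nuclei=len(blue),
        n_undetected_regions_total=sum(per_nucleus_undetected.values()),
        n_matched_regions_total=M,
        per_nucleus_regions=per_nucleus,
        per_nucleus_undetected=per_nucleus_undetected,
        mode=mode, image_ids=(detections.source_id or scene.source_id,))


def combine_matches(results: list[MatchResult]) -> MatchResult:
    """Pool per-image match results (e.g. over a 10-image evaluation set)."""
    if not results:
        raise ValueError("no results to combine")
    modes = {r.mode for r in results}
    if len(modes) > 1:
        raise ValueError(f"cannot combine mixed modes: {modes}")
    return MatchResult(
        n_detections=sum(r.n_detections for r in results),
        n_background_detections=sum(r.n_background_detections for r in results),
        n_gt_nuclei=sum(r.n_gt_nuclei for r in results),
        n_undetected_regions_total=sum(r.n_undetected_regions_total
                                       for r in results),
        n_matched_regions_total=sum(r.n_matched_regions_total for r in results),
        mode=modes.pop(),
        image_ids=tuple(i for r in results for i in r.image_ids))


def compute_metrics(match: MatchResult, decimals: int = 4) -> ComparisonMetrics:
    """The four criteria from raw counts, rounded half-up to ``decimals``.

    ``background_fraction`` is B/D with the convention 0 when D = 0 (no
    detections means no false detections).  The per-nucleus averages require
    N >= 1.
    """
    D, B = match.n_detections, match.n_background_detections
    N, U, M = (match.n_gt_nuclei, match.n_undetected_regions_total,
               match.n_matched_regions_total)
    if N < 1:
        raise ValueError("per-nucleus averages require at least one "
                         "ground-truth nucleus (N >= 1)")
    bf = 0.0 if D == 0 else B / D
    return ComparisonMetrics(
        n_detections=D,
        background_fraction=_round_half_up(bf, decimals),
        avg_undetected_per_nucleus=_round_half_up(U / N, decimals),
        avg_regions_per_nucleus=_round_half_up(M / N, decimals))


_ROW_NAMES = [
    "Number of detections",
    "Percentage of incorrectly detected from backgrounds",
    "Average number of undetectable cell nuclear regions per cell nucleus",
    "Average number of regions detected for each cell nucleus",
]


def _column(match: MatchResult, decimals: int) -> list[str]:
    m = compute_metrics(match, decimals)
    D, B = match.n_detections, match.n_background_detections
    N, U, M = (match.n_gt_nuclei, match.n_undetected_regions_total,
               match.n_matched_regions_total)

    def fmt(value: float) -> str:
        s = f"{value:.{decimals}f}".rstrip("0").rstrip(".")
        return s if s else "0"

    return [str(D),
            f"{fmt(m.background_fraction)} ({B}/{D})",
            f"{fmt(m.avg_undetected_per_nucleus)} ({U}/{N})",
            f"{fmt(m.avg_regions_per_nucleus)} ({M}/{N})"]


def compare_backends(swm_result: MatchResult, instance_result: MatchResult,
                     decimals: int = 4,
                     column_names: tuple[str, str] = ("Sliding window",
                                                      "Instance segmentation"),
                     ) -> pd.DataFrame:
    """Two-column, four-row comparison table with raw fractions in parentheses.

    Both results must cover the same image set (compared as unordered id
    sets); otherwise a ValueError is raised.
    """
    if set(swm_result.image_ids) != set(instance_result.image_ids):
        raise ValueError(
            "backends were evaluated on different image sets: "
            f"{sorted(set(swm_result.image_ids))} vs "
            f"{sorted(set(instance_result.image_ids))}")
    return pd.DataFrame(
        {column_names[0]: _column(swm_result, decimals),
         column_names[1]: _column(instance_result, decimals)},
        index=_ROW_NAMES)
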