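"""Synthetic Papanicolaou-style cytology fields with exact per-instance ground truth.

Liquid-based oral cytology fields are emulated as sparse, non-overlapping
cells on a pale background: basal-lineage cells stain blue/cyan and
superficial-lineage cells stain red/orange.  Each cell is a rotated
elliptical nucleus inside a concentric, lower-saturation cytoplasm ellipse;
the nucleus-to-cytoplasm (N/C) area ratio is sampled per cell.  Small
gray/green blobs model debris and carry no instance identity.

Every nucleus comes with a full-resolution binary mask, so window labelling,
detection and matching downstream are all testable against exact truth.
Generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import draw as skdraw
from skimage import measure
from skimage.color import rgb2hsv

#: Hue bands (fraction of the hue circle) that define the two stain lineages.
BLUE_HUE_BAND = (0.55, 0.72)
RED_HUE_BAND = ((0.0, 0.12), (0.9, 1.0))

_MIN_NUCLEUS_AREA = 20  # px
_MAX_PLACEMENT_ATTEMPTS = 200


class SceneCapacityError(RuntimeError):
    """Requested cell count cannot be placed without violating overlap rules."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic cytology field.

    ``stain_noise_sd`` is the standard deviation of additive Gaussian pixel
    noise on the 0–1 intensity scale.  ``debris_density`` is a Poisson rate
    per megapixel.  ``overlap_fraction`` = 0 means cells (cytoplasm
    included) are pairwise disjoint; values in (0, 1] progressively allow
    cell footprints to approach and overlap, as a stress knob.
    """

    n_blue: int = 4
    n_red: int = 3
    height: int = 1024
    width: int = 1280
    nucleus_radius_range: tuple[float, float] = (12.0, 24.0)
    nc_ratio_range: tuple[float, float] = (0.2, 0.6)
    debris_density: float = 5.0
    overlap_fraction: float = 0.0
    stain_noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_blue < 0 or self.n_red < 0:
            raise ValueError("cell counts must be >= 0")
        if self.height < 8 or self.width < 8:
            raise ValueError("image too small")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo < hi):
            raise ValueError("nucleus_radius_range must be non-degenerate (lo < hi)")
        if lo < 4.0:
            raise ValueError(
                "minimum nucleus radius must be >= 4 px so rasterized masks "
                f"have area >= {_MIN_NUCLEUS_AREA} px"
            )
        rlo, rhi = self.nc_ratio_range
        if not (0 < rlo < rhi <= 1):
            raise ValueError("nc_ratio_range must satisfy 0 < lo < hi <= 1")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.debris_density < 0 or self.stain_noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")


@dataclass
class NucleusInstance:
    """One nucleus: identity, lineage, geometry and a full-image binary mask."""

    id: int
    lineage: str  # "blue" | "red"
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b) px
    rotation: float  # radians
    mask: np.ndarray  # bool, image-sized

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Half-open (row0, col0, row1, col1) bounding box of the mask."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


@dataclass
class SyntheticScene:
    """A generated image plus its exhaustive ground truth."""

    image: np.ndarray  # uint8, H x W x 3
    instances: list[NucleusInstance]
    debris_count: int
    seed: int
    config: SceneConfig | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.source_id:
            self.source_id = f"scene_{self.seed:06d}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def blue_instances(self) -> list[NucleusInstance]:
        return [inst for inst in self.instances if inst.lineage == "blue"]

    def labeled_mask(self) -> np.ndarray:
        """uint16 raster: 0 = background, instance id elsewhere."""
        lab = np.zeros(self.shape, dtype=np.uint16)
        for inst in self.instances:
            lab[inst.mask] = inst.id
        return lab


def _hsv_fill(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray,
              h: float, s: float, v: float) -> None:
    canvas[rr, cc] = colorsys.hsv_to_rgb(h, s, v)


def _place_centers(rng: np.random.Generator, cfg: SceneConfig,
                   footprints: list[float]) -> list[tuple[float, float]]:
    """Rejection-sample centers so cell footprints respect the overlap rule."""
    centers: list[tuple[float, float]] = []
    shrink = 1.0 - cfg.overlap_fraction
    for i, radius in enumerate(footprints):
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(radius, cfg.height - radius)
            c = rng.uniform(radius, cfg.width - radius)
            ok = True
            for (pr, pc), prev_rad in zip(centers, footprints):
                if np.hypot(r - pr, c - pc) < shrink * (radius + prev_rad):
                    ok = False
                    break
            if ok:
                centers.append((r, c))
                break
        else:
            raise SceneCapacityError(
                f"could not place cell {i + 1}/{len(footprints)} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; reduce cell count or "
                "density, or allow overlap"
            )
    return centers


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one field and return it with exact instance ground truth.

    Blue-lineage instances get ids 1..n_blue, red-lineage the following ids.
    Raises :class:`SceneCapacityError` when the non-overlap constraint cannot
    be satisfied within a bounded number of placement attempts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width

    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = colorsys.hsv_to_rgb(0.12, 0.04, 0.94)  # pale slide background

    n_cells = config.n_blue + config.n_red
    lineages = ["blue"] * config.n_blue + ["red"] * config.n_red

    # Geometry is sampled up front so placement can respect cytoplasm extents.
    rlo, rhi = config.nucleus_radius_range
    a_axes = rng.uniform(rlo, rhi, size=n_cells)
    b_axes = a_axes * rng.uniform(0.6, 1.0, size=n_cells)
    rotations = rng.uniform(0.0, np.pi, size=n_cells)
    nc_ratios = rng.uniform(*config.nc_ratio_range, size=n_cells)
    cyto_scale = 1.0 / np.sqrt(nc_ratios)  # area ratio -> axis ratio
    footprints = [float(a * s) for a, s in zip(a_axes, cyto_scale)]
    centers = _place_centers(rng, config, footprints)

    # Cytoplasm halos first (pale, low saturation), nuclei drawn last so the
    # mask/image consistency contract holds for every labeled pixel.
    colors = []
    for lineage in lineages:
        if lineage == "blue":
            hue = rng.uniform(0.58, 0.68)
            nuc = (hue, rng.uniform(0.60, 0.80), rng.uniform(0.25, 0.42))
            cyt = (hue, rng.uniform(0.15, 0.30), rng.uniform(0.65, 0.80))
        else:
            hue = rng.uniform(0.01, 0.08)
            nuc = (hue, rng.uniform(0.60, 0.80), rng.uniform(0.30, 0.45))
            cyt = (hue, rng.uniform(0.15, 0.30), rng.uniform(0.70, 0.85))
        colors.append((nuc, cyt))

    for i in range(n_cells):
        rr, cc = skdraw.ellipse(
            centers[i][0], centers[i][1],
            a_axes[i] * cyto_scale[i], b_axes[i] * cyto_scale[i],
            shape=(H, W), rotation=rotations[i],
        )
        _hsv_fill(canvas, rr, cc, *colors[i][1])

    # Debris: small gray-green blobs, drawn before nuclei, no instance id.
    debris_count = int(rng.poisson(config.debris_density * H * W / 1e6))
    for _ in range(debris_count):
        dr = rng.uniform(4, H - 4)
        dc = rng.uniform(4, W - 4)
        rad = rng.uniform(2.0, 6.0)
        rr, cc = skdraw.ellipse(dr, dc, rad, rad * rng.uniform(0.5, 1.0),
                                shape=(H, W), rotation=rng.uniform(0, np.pi))
        _hsv_fill(canvas, rr, cc,
                  rng.uniform(0.20, 0.45), rng.uniform(0.10, 0.35),
                  rng.uniform(0.50, 0.75))

    instances: list[NucleusInstance] = []
    for i in range(n_cells):
        mask = np.zeros((H, W), dtype=bool)
        rr, cc = skdraw.ellipse(centers[i][0], centers[i][1],
                                a_axes[i], b_axes[i],
                                shape=(H, W), rotation=rotations[i])
        mask[rr, cc] = True
        if mask.sum() < _MIN_NUCLEUS_AREA:  # pragma: no cover - guarded by config
            raise SceneCapacityError("rasterized nucleus below minimum area")
        _hsv_fill(canvas, rr, cc, *colors[i][0])
        instances.append(NucleusInstance(
            id=i + 1, lineage=lineages[i],
            center=(float(centers[i][0]), float(centers[i][1])),
            semi_axes=(float(a_axes[i]), float(b_axes[i])),
            rotation=float(rotations[i]), mask=mask,
        ))

    if config.stain_noise_sd > 0:
        canvas += rng.normal(0.0, config.stain_noise_sd, size=canvas.shape)
    image = (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    return SyntheticScene(image=image, instances=instances,
                          debris_count=debris_count, seed=config.seed,
                          config=config)


def generate_corpus(base_config: SceneConfig, n_scenes: int,
                    seed_start: int) -> Iterator[SyntheticScene]:
    """Yield ``n_scenes`` scenes with consecutive seeds from ``seed_start``."""
    from dataclasses import replace
    for k in range(n_scenes):
        yield generate_scene(replace(base_config, seed=seed_start + k))


def mean_hue(image: np.ndarray, mask: np.ndarray) -> float:
    """Circular-safe mean hue of the masked pixels (fraction of hue circle)."""
    hsv = rgb2hsv(image[mask][None, :, :].astype(np.float64) / 255.0)
    h = hsv[0, :, 0]
    ang = h * 2 * np.pi
    m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)
    return float(m % 1.0)


def hue_in_band(h: float, band) -> bool:
    """True when hue ``h`` falls in a band given as (lo, hi) or a tuple of them."""
    if isinstance(band[0], (tuple, list)):
        return any(hue_in_band(h, b) for b in band)
    return band[0] <= h <= band[1]


def _mask_to_polygons(mask: np.ndarray) -> list[list[float]]:
    """COCO-style flat [x0, y0, x1, y1, ...] polygons for one binary mask."""
    polys = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        if len(contour) < 3:
            continue
        # contour is (row, col); COCO wants x=col, y=row
        flat = np.stack([contour[:, 1], contour[:, 0]], axis=1).ravel()
        polys.append([float(v) for v in flat])
    return polys


def export_ground_truth(scene: SyntheticScene, directory: str | Path) -> pd.DataFrame:
    """Write image (TIFF + PNG), per-instance masks, labeled mask and COCO JSON.

    Returns a manifest DataFrame (one row per written file) and writes it as
    ``manifest.csv`` alongside the other artifacts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = scene.source_id
    rows: list[dict] = []

    def _write(kind: str, path: Path, writer) -> None:
        try:
            writer(path)
        except OSError as exc:  # re-raise with path context
            raise OSError(f"failed writing {kind} to {path}: {exc}") from exc
        rows.append({"source_id": sid, "kind": kind, "path": str(path)})

    _write("image_tiff", directory / f"{sid}.tif",
           lambda p: tifffile.imwrite(p, scene.image))
    _write("image_png", directory / f"{sid}.png",
           lambda p: iio.imwrite(p, scene.image))

    mask_dir = directory / f"{sid}_masks"
    mask_dir.mkdir(exist_ok=True)
    for inst in scene.instances:
        _write("instance_mask", mask_dir / f"instance_{inst.id:03d}.png",
               lambda p, m=inst.mask: iio.imwrite(
                   p, (m.astype(np.uint8) * 255)))
    _write("labeled_mask", directory / f"{sid}_labels.png",
           lambda p: iio.imwrite(p, scene.labeled_mask()))

    categories = [{"id": 1, "name": "blue_nucleus"},
                  {"id": 2, "name": "red_nucleus"}]
    annotations = []
    for inst in scene.instances:
        r0, c0, r1, c1 = inst.bbox
        annotations.append({
            "id": inst.id,
            "image_id": 1,
            "category_id": 1 if inst.lineage == "blue" else 2,
            "bbox": [c0, r0, c1 - c0, r1 - r0],
            "area": inst.area,
            "segmentation": _mask_to_polygons(inst.mask),
            "iscrowd": 0,
        })
    coco = {
        "images": [{"id": 1, "file_name": f"{sid}.png",
                    "height": scene.shape[0], "width": scene.shape[1]}],
        "annotations": annotations,
        "categories": categories,
    }
    _write("annotations", directory / f"{sid}_annotations.json",
           lambda p: p.write_text(json.dumps(coco)))

    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / f"{sid}_manifest.csv", index=False)
    return manifest
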