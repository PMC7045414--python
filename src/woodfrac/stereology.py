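"""Grid-based point-count stereology of tissue fractions on labelled rasters.

A regular lattice of points is overlaid on a categorical cross-section image
and each node is classified by the tissue category of the pixel it falls in.
The per-category hit fraction is a binomial (unbiased, for a uniformly random
grid offset) estimator of the areal tissue fraction, with standard error
sqrt(f (1 - f) / n). A minimum intersection count is enforced by repeatedly
halving the grid spacing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TissueLabelMap",
    "GridSpec",
    "PointCountResult",
    "StereologyError",
    "DEFAULT_SPACING_UM",
    "build_grid",
    "point_count",
    "total_parenchyma",
    "write_label_map",
    "read_label_map",
]

#: Default grid spacings (um): midpoints of the working ranges for stem
#: (120-140 um) and twig (40-80 um) sections.
DEFAULT_SPACING_UM = {"stem": 130.0, "twig": 60.0}


class StereologyError(RuntimeError):
    pass


@dataclass(frozen=True)
class TissueLabelMap:
    """Categorical 2-D raster of a section with physical scale.

    Pixel convention is half-open with origin at the top-left corner, x
    rightward (columns) and y downward (rows): the point (x, y) in um lies in
    pixel (floor(y/s), floor(x/s)) for pixel pitch s.
    """

    raster: np.ndarray
    um_per_pixel: float
    region_mask: np.ndarray | None = None  # in-tissue indicator; None = all

    def __post_init__(self):
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.region_mask is not None:
            m = np.asarray(self.region_mask, dtype=bool)
            if m.shape != r.shape:
                raise ValueError("region_mask shape must match raster")
            object.__setattr__(self, "region_mask", m)
        object.__setattr__(self, "raster", r)

    @property
    def shape(self):
        return self.raster.shape

    @property
    def width_um(self) -> float:
        return self.raster.shape[1] * self.um_per_pixel

    @property
    def height_um(self) -> float:
        return self.raster.shape[0] * self.um_per_pixel

    def mask(self) -> np.ndarray:
        if self.region_mask is None:
            return np.ones(self.raster.shape, dtype=bool)
        return self.region_mask


@dataclass(frozen=True)
class GridSpec:
    """Regular point lattice: spacing and (x, y) offset in um.

    ``offset_um=None`` requests a seeded uniformly random offset in
    [0, spacing)^2, which makes the point-count estimator exactly unbiased and
    avoids aliasing with periodic structures.
    """

    spacing_um: float
    offset_um: tuple[float, float] | None = (0.0, 0.0)
    organ: str = "stem"

    def __post_init__(self):
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if self.offset_um is not None:
            ox, oy = self.offset_um
            if not (0 <= ox < self.spacing_um and 0 <= oy < self.spacing_um):
                raise ValueError("offset must lie in [0, spacing)")

    @classmethod
    def default(cls, organ: str = "stem") -> "GridSpec":
        return cls(spacing_um=DEFAULT_SPACING_UM[organ], organ=organ)


@dataclass(frozen=True)
class PointCountResult:
    counts: dict[str, int]
    n_total: int
    fractions: dict[str, float]
    se: dict[str, float]
    spacing_used_um: float
    offset_um: tuple[float, float]


def _resolve_offset(spec: GridSpec, spacing: float, rng) -> tuple[float, float]:
    if spec.offset_um is None:
        return tuple(rng.uniform(0.0, spacing, size=2))
    return (spec.offset_um[0] % spacing, spec.offset_um[1] % spacing)


def build_grid(label_map: TissueLabelMap, spec: GridSpec,
               offset_um: tuple[float, float] | None = None) -> np.ndarray:
    """All lattice nodes (x, y) in um falling on the in-tissue region.

    For a w x h rectangle with zero offset the lattice holds
    (floor(w/spacing)+1) * (floor(h/spacing)+1) nodes.
    """
    if spec.spacing_um < 2 * label_map.um_per_pixel:
        raise StereologyError(
            f"spacing {spec.spacing_um} um finer than twice the pixel pitch "
            f"{label_map.um_per_pixel} um")
    if offset_um is None:
        offset_um = spec.offset_um if spec.offset_um is not None else (0.0, 0.0)
    ox, oy = offset_um
    xs = np.arange(ox, label_map.width_um, spec.spacing_um)
    ys = np.arange(oy, label_map.height_um, spec.spacing_um)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cols = np.floor(pts[:, 0] / label_map.um_per_pixel).astype(int)
    rows = np.floor(pts[:, 1] / label_map.um_per_pixel).astype(int)
    keep = label_map.mask()[rows, cols]
    return pts[keep]


def point_count(label_map: TissueLabelMap, spec: GridSpec | None = None,
                min_intersections: int = 300, include_other: bool = True,
                seed: int | None = 0,
                category_names: dict[int, str] | None = None) -> PointCountResult:
    """Classify every grid node by the pixel category under it.

    If fewer than ``min_intersections`` in-tissue nodes result, the spacing is
    halved (and logged) until the minimum is met. ``include_other`` controls
    whether the 'other' category enters the denominator of the reported
    fractions.
    """
    from .synthesis import CATEGORY_NAMES  # avoid circular import at load time

    names = CATEGORY_NAMES if category_names is None else category_names
    spec = spec or GridSpec.default()
    rng = np.random.default_rng(seed)
    spacing = spec.spacing_um
    base_offset = _resolve_offset(spec, spacing, rng)
    while True:
        cur = GridSpec(spacing_um=spacing, offset_um=None, organ=spec.organ)
        pts = build_grid(label_map, cur, offset_um=(base_offset[0] % spacing,
                                                    base_offset[1] % spacing))
        cols = np.floor(pts[:, 0] / label_map.um_per_pixel).astype(int)
        rows = np.floor(pts[:, 1] / label_map.um_per_pixel).astype(int)
        codes = label_map.raster[rows, cols]
        codes = codes[codes != 0]  # drop nodes on background/outside pixels
        if len(codes) >= min_intersections:
            break
        new_spacing = spacing / 2.0
        if new_spacing < 2 * label_map.um_per_pixel:
            raise StereologyError(
                f"region too small: {len(codes)} intersections at spacing "
                f"{spacing:.1f} um and halving would go below twice the pixel "
                f"pitch")
        log.info("only %d < %d intersections at %.1f um; halving spacing",
                 len(codes), min_intersections, spacing)
        spacing = new_spacing
        # re-randomise within the finer cell to keep the offset valid
        if spec.offset_um is None:
            base_offset = tuple(rng.uniform(0.0, spacing, size=2))

    present = sorted(set(names) - {0})
    counts = {names[c]: int(np.sum(codes == c)) for c in present}
    denom_cats = [n for n in counts if include_other or n != "other"]
    n_denom = sum(counts[n] for n in denom_cats)
    if n_denom == 0:
        raise StereologyError("no in-tissue intersections")
    fractions = {n: counts[n] / n_denom for n in denom_cats}
    se = {n: float(np.sqrt(f * (1.0 - f) / n_denom))
          for n, f in fractions.items()}
    result = PointCountResult(counts=counts, n_total=len(codes),
                              fractions=fractions, se=se,
                              spacing_used_um=spacing,
                              offset_um=(base_offset[0] % spacing,
                                         base_offset[1] % spacing))
    log.info("point count: n_total=%d spacing_used=%.1f um", result.n_total,
             spacing)
    return result


def total_parenchyma(result: PointCountResult) -> float:
    """Axial + ray parenchyma fraction (the 'total parenchyma' trait)."""
    return (result.fractions.get("axial_parenchyma", 0.0)
            + result.fractions.get("ray_parenchyma", 0.0))


# ----------------------------------------------------------------- file I/O
def write_label_map(label_map: TissueLabelMap, path, seed: int | None = None,
                    category_codes: dict[str, int] | None = None) -> None:
    """Write a label raster as single-channel 8-bit PNG plus a JSON sidecar."""
    from .synthesis import CATEGORY_CODES
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, label_map.raster.astype(np.uint8))
    sidecar = {
        "um_per_pixel": label_map.um_per_pixel,
        "category_codes": category_codes or CATEGORY_CODES,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_label_map(path) -> TissueLabelMap:
    import imageio.v3 as iio

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raster = iio.imread(path)
    return TissueLabelMap(raster=np.asarray(raster),
                          um_per_pixel=float(sidecar["um_per_pixel"]))
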