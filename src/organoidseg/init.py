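"""Automatic initial-contour generation.

Workflow: Chan–Vese pre-segmentation of the whole image, Canny edge
extraction of the resulting mask, then a rectangle anchored at a
user-supplied seed point inside the target object.  The rectangle's
half-extents are the distances from the seed to the nearest edge pixel on
its raster row / column, expanded by 20 %.

Coordinates are 0-based with x = column and y = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .core import ImageGrid, LevelSetField
from .errors import ContractError, InitializationError
from .models import CVParams, SegmentationResult, cv_evolve

__all__ = [
    "SeedPoint",
    "InitRectangle",
    "EdgePixelSet",
    "presegment_cv",
    "extract_edges",
    "generate_init_rectangle",
    "rectangle_to_levelset",
    "auto_initialize",
]

SEED_MARGIN = 2
DEFAULT_EXPANSION = 0.2
#: objects smaller than this (px) are dropped from the pre-segmentation mask
MIN_OBJECT_AREA = 100


@dataclass(frozen=True)
class SeedPoint:
    """User click at the inner center of the target object (x = col, y = row)."""

    x: int
    y: int

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if not (SEED_MARGIN <= self.x < w - SEED_MARGIN):
            raise InitializationError(
                f"seed x={self.x} must be within [{SEED_MARGIN}, {w - SEED_MARGIN - 1}]"
            )
        if not (SEED_MARGIN <= self.y < h - SEED_MARGIN):
            raise InitializationError(
                f"seed y={self.y} must be within [{SEED_MARGIN}, {h - SEED_MARGIN - 1}]"
            )


@dataclass(frozen=True)
class InitRectangle:
    """Axis-aligned rectangle centered on the seed point."""

    center: SeedPoint
    half_width: float
    half_height: float

    def __post_init__(self):
        if self.half_width <= 0 or self.half_height <= 0:
            raise InitializationError("rectangle half-extents must be positive")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (
            self.center.x - self.half_width,
            self.center.y - self.half_height,
            self.center.x + self.half_width,
            self.center.y + self.half_height,
        )

    def clipped(self, shape: tuple[int, int], margin: int = 1) -> "InitRectangle":
        """Clip to the image bounds leaving ``margin`` exterior pixels."""
        h, w = shape
        x0, y0, x1, y1 = self.corners
        x0 = max(x0, margin)
        y0 = max(y0, margin)
        x1 = min(x1, w - 1 - margin)
        y1 = min(y1, h - 1 - margin)
        if x1 <= x0 or y1 <= y0:
            raise InitializationError("rectangle degenerates after clipping")
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        rect = InitRectangle.__new__(InitRectangle)
        object.__setattr__(rect, "center", SeedPoint(int(round(cx)), int(round(cy))))
        object.__setattr__(rect, "half_width", 0.5 * (x1 - x0))
        object.__setattr__(rect, "half_height", 0.5 * (y1 - y0))
        # keep exact float center for the signed distance
        object.__setattr__(rect, "_cx", cx)
        object.__setattr__(rect, "_cy", cy)
        return rect


@dataclass(frozen=True)
class EdgePixelSet:
    """Pixel coordinates flagged as edges, plus the source mask shape."""

    coords: np.ndarray  # (n, 2) array of (y, x)
    shape: tuple[int, int]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if coords.size:
            h, w = self.shape
            if (
                coords[:, 0].min() < 0
                or coords[:, 0].max() >= h
                or coords[:, 1].min() < 0
                or coords[:, 1].max() >= w
            ):
                raise ContractError("edge coordinates out of bounds")

    def __len__(self) -> int:
        return len(self.coords)


def default_preseg_phi(shape: tuple[int, int], period: int = 40) -> LevelSetField:
    """Tiled-rectangles initial phi so every object is near an initial contour."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    values = -np.cos(2.0 * np.pi * xx / period) * np.cos(2.0 * np.pi * yy / period)
    return LevelSetField(2.0 * values)


def presegment_cv(
    grid: ImageGrid, cv_params: CVParams | None = None
) -> np.ndarray:
    """Whole-image Chan–Vese pre-segmentation.

    Starts from a tiled-rectangles phi, runs the C-V baseline, orients the
    mask so that the darker phase is foreground (bright-field objects are
    darker than the dish background), fills holes caused by interior
    speckle and drops sub-``MIN_OBJECT_AREA`` noise specks.
    """
    if cv_params is None:
        cv_params = CVParams(mu_cv=0.05, lambda1=1.0, lambda2=1.0, max_iterations=300)
    phi0 = default_preseg_phi(grid.shape)
    result: SegmentationResult = cv_evolve(phi0, grid, cv_params)
    mask = result.mask
    if not mask.any() or mask.all():
        raise InitializationError(
            "pre-segmentation produced an empty partition; adjust C-V parameters"
        )
    inside_mean = grid.intensities[mask].mean()
    outside_mean = grid.intensities[~mask].mean()
    if abs(inside_mean - outside_mean) < 0.02:
        raise InitializationError(
            "image has no two-phase contrast; nothing to segment"
        )
    if inside_mean > outside_mean:
        mask = ~mask
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < MIN_OBJECT_AREA) + 1
        mask &= ~np.isin(labels, small)
    if not mask.any():
        raise InitializationError(
            "pre-segmentation mask is empty after cleanup; nothing to segment"
        )
    return mask


def extract_edges(
    mask: np.ndarray, canny_low: float = 0.1, canny_high: float = 0.2
) -> EdgePixelSet:
    """Canny edges of a binary mask (for a filled shape: its outline)."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ContractError("extract_edges expects a binary mask")
        mask = mask.astype(bool)
    if not mask.any():
        return EdgePixelSet(np.empty((0, 2), dtype=np.int64), mask.shape)
    edges = feature.canny(
        mask.astype(np.float64),
        sigma=1.0,
        low_threshold=canny_low,
        high_threshold=canny_high,
    )
    coords = np.argwhere(edges)
    return EdgePixelSet(coords, mask.shape)


def _nearest_on_line(
    coords: np.ndarray, fixed_axis: int, fixed_value: int, moving_value: int
) -> int | None:
    """Distance to the nearest edge pixel sharing the given row/column.

    ``fixed_axis`` 0 = same row (horizontal search), 1 = same column.
    Ties break toward the smaller coordinate.
    """
    on_line = coords[coords[:, fixed_axis] == fixed_value]
    if len(on_line) == 0:
        return None
    moving = on_line[:, 1 - fixed_axis]
    dist = np.abs(moving - moving_value)
    order = np.lexsort((moving, dist))
    return int(dist[order[0]])


def generate_init_rectangle(
    edges: EdgePixelSet,
    seed: SeedPoint,
    expansion: float = DEFAULT_EXPANSION,
) -> InitRectangle:
    """Seed-anchored rectangle through the nearest row/column edge pixels.

    B is the nearest edge pixel on the seed's row (either direction), C the
    nearest on its column; half-extents are ``(1 + expansion)`` times |AB|
    and |AC|.
    """
    if len(edges) == 0:
        raise InitializationError(
            "edge set is empty; re-click the seed or supply a manual rectangle"
        )
    seed.validate(edges.shape)
    d_horizontal = _nearest_on_line(edges.coords, 0, seed.y, seed.x)
    d_vertical = _nearest_on_line(edges.coords, 1, seed.x, seed.y)
    if d_horizontal is None or d_vertical is None:
        raise InitializationError(
            "no edge pixel on the seed's row or column; re-click the seed "
            "or supply a manual rectangle"
        )
    if d_horizontal == 0 or d_vertical == 0:
        raise InitializationError(
            "seed point lies on an edge pixel; re-click inside the object"
        )
    return InitRectangle(
        center=seed,
        half_width=(1.0 + expansion) * d_horizontal,
        half_height=(1.0 + expansion) * d_vertical,
    )


def rectangle_to_levelset(rect: InitRectangle, grid: ImageGrid) -> LevelSetField:
    """Signed distance to the rectangle boundary, negative inside."""
    clipped = rect.clipped(grid.shape, margin=1)
    cx = getattr(clipped, "_cx", clipped.center.x)
    cy = getattr(clipped, "_cy", clipped.center.y)
    h, w = grid.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx = np.abs(xx - cx) - clipped.half_width
    dy = np.abs(yy - cy) - clipped.half_height
    outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
    inside = np.minimum(np.maximum(dx, dy), 0.0)
    phi = LevelSetField(outside + inside)
    if not phi.has_both_signs():
        raise InitializationError("rectangle level set has a single sign")
    return phi


def auto_initialize(
    grid: ImageGrid,
    seed: SeedPoint,
    cv_params: CVParams | None = None,
    expansion: float = DEFAULT_EXPANSION,
) -> tuple[LevelSetField, InitRectangle]:
    """Full click-to-rectangle pipeline; returns (phi0, rectangle)."""
    seed.validate(grid.shape)
    mask = presegment_cv(grid, cv_params)
    edges = extract_edges(mask)
    rect = generate_init_rectangle(edges, seed, expansion)
    phi0 = rectangle_to_levelset(rect, grid)
    return phi0, rect
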