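"""Grid-level numerical primitives of the level-set framework.

Everything here operates on plain ``float64`` arrays wrapped in light
dataclasses.  The package-wide orientation is *inside-negative*: the
segmented region is ``{phi < 0}`` and, with that convention, the boundary
of a convex region has nonnegative curvature ``kappa = div(grad phi /
|grad phi|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateRegionError, ParameterError

__all__ = [
    "ImageGrid",
    "LevelSetField",
    "SmoothingParams",
    "RegionStats",
    "CurvatureField",
    "EdgeMap",
    "smoothed_heaviside",
    "smoothed_dirac",
    "compute_region_means",
    "compute_curvature",
    "edge_indicator",
    "gradient",
    "divergence",
]

#: floor applied to |grad phi| before any division by it
GRAD_FLOOR = 1e-8

MIN_SIDE = 16


@dataclass(frozen=True)
class ImageGrid:
    """Discrete image domain with intensities normalized to [0, 1]."""

    intensities: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 2:
            raise ContractError(f"image must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
            raise ContractError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ContractError("image intensities must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ContractError("image intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class LevelSetField:
    """Evolving scalar field ``phi``; the contour is its zero level set.

    Sign convention: ``phi < 0`` inside the contour (inside-negative).
    """

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ContractError(f"level-set field must be 2-D, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ContractError("level-set values must be finite")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def inside_mask(self) -> np.ndarray:
        return self.values < 0

    def has_both_signs(self) -> bool:
        return bool((self.values < 0).any() and (self.values > 0).any())


@dataclass(frozen=True)
class SmoothingParams:
    """Half-width of the smoothed Heaviside/Dirac band and the edge-map sigma."""

    epsilon: float = 1.5
    sigma: float = 1.5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class RegionStats:
    """Mean intensity inside (c1) and outside (c2) the contour."""

    c1: float
    c2: float


@dataclass
class CurvatureField:
    """Curvature ``kappa`` and the binary curvature-sign indicator ``s``."""

    kappa: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        if self.s is None:
            self.s = (self.kappa >= 0).astype(np.float64)
        else:
            self.s = np.asarray(self.s, dtype=np.float64)


@dataclass(frozen=True)
class EdgeMap:
    """Edge-indicator field ``g`` in (0, 1]; ~1 in flat areas, small at edges."""

    g: np.ndarray
    sigma: float = 1.5
    gradient_scale: float = 1.0


def smoothed_heaviside(x, epsilon: float):
    """Smoothed Heaviside: ramp of half-width ``epsilon`` with a sine correction.

    Returns 0 for ``x < -epsilon``, 1 for ``x > epsilon`` and
    ``(1 + x/eps + sin(pi x/eps)/pi) / 2`` in between.  Works on scalars
    and arrays alike.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    x = np.asarray(x, dtype=np.float64)
    ramp = 0.5 * (1.0 + x / epsilon + np.sin(np.pi * x / epsilon) / np.pi)
    out = np.where(x > epsilon, 1.0, np.where(x < -epsilon, 0.0, ramp))
    if out.ndim == 0:
        return float(out)
    return out


def smoothed_dirac(x, epsilon: float):
    """Smoothed Dirac delta: raised cosine of half-width ``epsilon``.

    ``(1 + cos(pi x/eps)) / (2 eps)`` on ``|x| <= epsilon``, zero outside;
    integrates to one over its support.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    x = np.asarray(x, dtype=np.float64)
    bump = (1.0 + np.cos(np.pi * x / epsilon)) / (2.0 * epsilon)
    out = np.where(np.abs(x) <= epsilon, bump, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def compute_region_means(
    grid: ImageGrid, phi: LevelSetField, epsilon: float
) -> RegionStats:
    """Smoothed mean intensity inside and outside the contour.

    The inside weight is the smoothed indicator of ``{phi < 0}`` (i.e.
    ``H_eps(-phi)``); the outside weight is its complement.
    """
    if grid.shape != phi.shape:
        raise ContractError(
            f"shape mismatch: image {grid.shape} vs level set {phi.shape}"
        )
    w_in = smoothed_heaviside(-phi.values, epsilon)
    w_out = 1.0 - w_in
    total_in = float(np.sum(w_in))
    total_out = float(np.sum(w_out))
    if total_in < 1e-12 or total_out < 1e-12:
        raise DegenerateRegionError(
            "one region has (almost) zero weight: the contour has collapsed "
            "or filled the image"
        )
    intens = grid.intensities
    c1 = float(np.sum(intens * w_in) / total_in)
    c2 = float(np.sum(intens * w_out) / total_out)
    return RegionStats(c1=c1, c2=c2)


def gradient(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (one-sided at the image border).

    Returns ``(gx, gy)`` where x indexes columns and y rows.
    """
    gy, gx = np.gradient(arr)
    return gx, gy


def divergence(fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    """Central-difference divergence, the adjoint companion of :func:`gradient`."""
    dfx_dx = np.gradient(fx, axis=1)
    dfy_dy = np.gradient(fy, axis=0)
    return dfx_dx + dfy_dy


def compute_curvature(phi: LevelSetField, csi_sigma: float = 1.0) -> CurvatureField:
    """Curvature ``kappa = div(grad phi / |grad phi|)`` and its sign indicator.

    ``csi_sigma > 0`` smooths kappa with a Gaussian of that standard
    deviation before anything else; raw discrete curvature flips sign on
    single-pixel noise, which would chatter the convexity switch.  The
    returned ``s`` is the exact indicator of ``kappa >= 0`` on the
    returned (possibly smoothed) kappa.
    """
    values = phi.values
    gx, gy = gradient(values)
    norm = np.sqrt(gx * gx + gy * gy)
    norm = np.maximum(norm, GRAD_FLOOR)
    kappa = divergence(gx / norm, gy / norm)
    if csi_sigma > 0:
        kappa = ndimage.gaussian_filter(kappa, sigma=csi_sigma, mode="nearest")
    return CurvatureField(kappa=kappa)


def edge_indicator(
    grid: ImageGrid, sigma: float, gradient_scale: float = 1.0
) -> EdgeMap:
    """Edge-detector function ``g = 1 / (1 + |grad(G_sigma * I)|^2)``.

    ``gradient_scale`` multiplies the smoothed gradient before squaring;
    passing the dtype maximum (e.g. 255) evaluates g on the raw intensity
    scale of the source image, which is the scale the default area-term
    weight was calibrated on.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    smoothed = ndimage.gaussian_filter(
        grid.intensities, sigma=sigma, mode="nearest", truncate=4.0
    )
    gx, gy = gradient(smoothed)
    grad_sq = (gradient_scale * gx) ** 2 + (gradient_scale * gy) ** 2
    g = 1.0 / (1.0 + grad_sq)
    return EdgeMap(g=g, sigma=sigma, gradient_scale=gradient_scale)
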