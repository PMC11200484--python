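"""Level-set evolution models.

Three explicit time-stepping models over a :class:`~organoidseg.core.LevelSetField`:

* :func:`evolve_proposed` — convexity-preserving region model: a
  curvature-sign switch gates a Chan–Vese-style data force against a pure
  curvature (convexity-restoring) force, plus length and weighted-area
  (balloon) terms.
* :func:`cv_evolve` — the Chan–Vese two-phase baseline.
* :func:`cplse_evolve` — edge-based convexity-preserving baseline built on
  the DRLSE double-well distance regularizer.

All models use the inside-negative convention (region = ``{phi < 0}``);
with it, a positive area-term weight drives the contour inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .core import (
    CurvatureField,
    EdgeMap,
    ImageGrid,
    LevelSetField,
    RegionStats,
    SmoothingParams,
    GRAD_FLOOR,
    compute_curvature,
    compute_region_means,
    divergence,
    gradient,
    smoothed_dirac,
)
from .errors import (
    ContractError,
    DegenerateRegionError,
    NumericalInstabilityError,
    ParameterError,
)

__all__ = [
    "EvolutionParams",
    "CVParams",
    "CPLSEParams",
    "SegmentationResult",
    "proposed_rhs",
    "evolve_proposed",
    "cv_rhs",
    "cv_evolve",
    "drlse_dp",
    "cplse_evolve",
    "contour_curvature",
    "suggest_time_step",
]

CONVERGED = "converged"
BUDGET = "budget"
CONTOUR_VANISHED = "contour_vanished"

#: CFL advective bound: at most this many pixels of motion per step
MAX_DISPLACEMENT = 0.5
#: parabolic bound dt * diffusion_weight <= this
PARABOLIC_BOUND = 0.25


@dataclass(frozen=True)
class EvolutionParams:
    """Coefficients of the convexity-preserving model.

    ``gradient_scale`` rescales the image gradient inside the edge
    indicator to the raw bit-depth scale (default 255); the published
    defaults ``alpha=1, mu=10, lambda1 in [1, 5]`` are only mutually
    consistent when the data residuals act on [0, 1] intensities while g
    sees 8-bit-scale gradients.
    """

    lambda1: float = 3.0
    lambda2: float = 1.0
    alpha: float = 1.0
    mu: float = 10.0
    beta: float = 1.0
    smoothing: SmoothingParams = dc_field(default_factory=SmoothingParams)
    dt: Optional[float] = 0.25
    max_iterations: int = 1500
    tolerance: float = 2e-3
    checkpoint_stride: int = 25
    csi_sigma: float = 1.0
    gradient_scale: float = 255.0
    reinit_every: int = 25

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("lambda1 and lambda2 must be nonnegative")
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.tolerance < 0:
            raise ParameterError("tolerance must be nonnegative")
        if self.checkpoint_stride < 1:
            raise ParameterError("checkpoint_stride must be >= 1")


@dataclass(frozen=True)
class CVParams:
    """Coefficients of the Chan–Vese baseline."""

    mu_cv: float = 0.05
    v: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 1.5
    dt: Optional[float] = None
    max_iterations: int = 1500
    tolerance: float = 2e-3
    checkpoint_stride: int = 25
    csi_sigma: float = 1.0
    reinit_every: int = 25

    def __post_init__(self):
        if self.mu_cv < 0:
            raise ParameterError("mu_cv must be nonnegative")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ParameterError("lambda1 and lambda2 must be positive")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass(frozen=True)
class CPLSEParams:
    """Coefficients of the CPLSE baseline (DRLSE + curvature-sign switch)."""

    mu_reg: float = 0.2
    lambda_len: float = 5.0
    alpha_area: float = 3.0
    epsilon: float = 1.5
    sigma: float = 1.5
    dt: Optional[float] = 1.0
    max_iterations: int = 1500
    tolerance: float = 2e-3
    checkpoint_stride: int = 25
    csi_sigma: float = 1.0
    gradient_scale: float = 255.0
    reinit_every: int = 5

    def __post_init__(self):
        if self.mu_reg <= 0:
            raise ParameterError("mu_reg must be positive")
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ParameterError("epsilon and sigma must be positive")
        if self.dt is not None:
            if self.dt <= 0:
                raise ParameterError("dt must be positive")
            if self.dt * self.mu_reg >= PARABOLIC_BOUND:
                raise ParameterError(
                    f"dt * mu_reg = {self.dt * self.mu_reg:g} violates the "
                    f"double-well stability bound < {PARABOLIC_BOUND}"
                )
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass
class SegmentationResult:
    """Final state of an evolution run."""

    phi: LevelSetField
    mask: np.ndarray
    iterations: int
    reason: str
    snapshots: list = dc_field(default_factory=list)
    diagnostics: dict = dc_field(default_factory=dict)


def suggest_time_step(params, max_speed: float) -> float:
    """CFL-safe explicit time step.

    Advective bound ``dt * max|R| <= 0.5`` px/step and parabolic bound
    ``dt * w <= 0.25`` where ``w`` is the model's diffusion-like weight;
    the stricter wins.  A zero speed field returns the parabolic bound
    alone.
    """
    if isinstance(params, EvolutionParams):
        diffusion = params.alpha
    elif isinstance(params, CVParams):
        diffusion = max(params.mu_cv, 1e-12)
    elif isinstance(params, CPLSEParams):
        diffusion = max(params.mu_reg, params.lambda_len / 8.0)
    else:
        raise ContractError(f"unknown parameter type {type(params)!r}")
    parabolic = PARABOLIC_BOUND / diffusion
    if max_speed <= 0:
        return parabolic
    return min(MAX_DISPLACEMENT / max_speed, parabolic)


def proposed_rhs(
    phi: LevelSetField,
    grid: ImageGrid,
    stats: RegionStats,
    edges: EdgeMap,
    curv: CurvatureField,
    params: EvolutionParams,
) -> np.ndarray:
    """Per-pixel update of the convexity-preserving model.

    ``s * [l1 (I-c1)^2 - l2 (I-c2)^2] delta  +  alpha * kappa * delta
    + mu * g * delta  +  beta * (1-s) * kappa * delta``

    where ``s`` is the curvature-sign indicator.  Every term carries the
    smoothed Dirac, so the update vanishes outside the contour band.
    """
    shape = phi.shape
    for name, arr in (
        ("image", grid.intensities),
        ("edge map", edges.g),
        ("curvature", curv.kappa),
        ("CSI", curv.s),
    ):
        if arr.shape != shape:
            raise ContractError(f"{name} shape {arr.shape} != phi shape {shape}")
    eps = params.smoothing.epsilon
    delta = smoothed_dirac(phi.values, eps)
    intens = grid.intensities
    residual = params.lambda1 * (intens - stats.c1) ** 2 - params.lambda2 * (
        intens - stats.c2
    ) ** 2
    data = curv.s * residual * delta
    length = params.alpha * curv.kappa * delta
    area = params.mu * edges.g * delta
    convexity = params.beta * (1.0 - curv.s) * curv.kappa * delta
    return data + length + area + convexity


def cv_rhs(
    phi: LevelSetField,
    grid: ImageGrid,
    stats: RegionStats,
    curv: CurvatureField,
    params: CVParams,
    area_force=None,
) -> np.ndarray:
    """Chan–Vese update mapped to the inside-negative convention.

    ``delta * [mu_cv kappa + v + l1 (I-c1)^2 - l2 (I-c2)^2]``; a positive
    bracket raises phi, i.e. moves the contour inward.  ``area_force``
    may replace the scalar ``v`` with a per-pixel field (used by the
    reduction-equivalence check against the proposed model).
    """
    if grid.shape != phi.shape:
        raise ContractError("shape mismatch between image and level set")
    delta = smoothed_dirac(phi.values, params.epsilon)
    intens = grid.intensities
    v = params.v if area_force is None else area_force
    bracket = (
        params.mu_cv * curv.kappa
        + v
        + params.lambda1 * (intens - stats.c1) ** 2
        - params.lambda2 * (intens - stats.c2) ** 2
    )
    return delta * bracket


def drlse_dp(s):
    """``p'(s) / s`` for the DRLSE double-well potential.

    ``sin(2 pi s) / (2 pi s)`` for ``s <= 1`` (limit 1 as s -> 0) and
    ``(s - 1) / s`` for ``s > 1``.  Accepts scalars or arrays; negative
    input is a contract error.
    """
    arr = np.asarray(s, dtype=np.float64)
    if np.any(arr < 0):
        raise ContractError("drlse_dp requires nonnegative input")
    safe = np.maximum(arr, 1e-300)
    lower = np.where(arr < 1e-12, 1.0, np.sin(2.0 * np.pi * arr) / (2.0 * np.pi * safe))
    upper = (arr - 1.0) / safe
    out = np.where(arr <= 1.0, lower, upper)
    if out.ndim == 0:
        return float(out)
    return out


def _redistance(values: np.ndarray) -> np.ndarray:
    """EDT-based sign-preserving redistancing (half-pixel interface offset)."""
    inside = values < 0
    if not inside.any() or inside.all():
        return values
    d_in = ndimage.distance_transform_edt(inside)
    d_out = ndimage.distance_transform_edt(~inside)
    return np.where(inside, -(d_in - 0.5), d_out - 0.5)


def contour_curvature(phi: LevelSetField, csi_sigma: float = 1.0) -> CurvatureField:
    """Curvature/CSI of the *contour*, evaluated on a redistanced copy of phi.

    Discrete curvature of a band-evolved (non-distance) phi is noise around
    zero on flat contour segments, which makes the raw CSI flip sign on
    half of the band and chatter the convexity switch.  The signed
    distance of the current region has exactly zero curvature on flat
    fronts, so its CSI is a reliable convex/concave classifier.
    """
    return compute_curvature(LevelSetField(_redistance(phi.values)), csi_sigma)


class _CurvatureCache:
    """Refresh the (EDT-backed) contour curvature only every few steps.

    The convex/concave classification of the front changes on the scale of
    front motion (< 0.5 px/step), so a few-iteration-old CSI is still
    valid and saves the dominant distance-transform cost.
    """

    def __init__(self, csi_sigma: float, stride: int = 5):
        self.csi_sigma = csi_sigma
        self.stride = max(int(stride), 1)
        self._curv: CurvatureField | None = None
        self._at = -1

    def get(self, phi: LevelSetField, k: int) -> CurvatureField:
        if self._curv is None or k - self._at >= self.stride:
            self._curv = contour_curvature(phi, self.csi_sigma)
            self._at = k
        return self._curv


def _evolve_loop(
    phi0: LevelSetField,
    rhs: Callable[[LevelSetField, int], np.ndarray],
    params,
    epsilon: float,
    reinit_every: int = 0,
    record_snapshots: bool = False,
) -> SegmentationResult:
    """Shared explicit iteration ``phi <- phi + dt * R(phi)``.

    Stops on iteration budget, on the contour vanishing, or when the mean
    absolute change of phi over the band ``|phi| < epsilon`` between two
    checkpoints falls below ``tolerance`` (per iteration of the stride).
    The change is measured on redistanced copies of phi so that it tracks
    contour motion rather than in-band amplitude jitter.
    """
    if not phi0.has_both_signs():
        return SegmentationResult(
            phi=phi0,
            mask=phi0.inside_mask(),
            iterations=0,
            reason=CONTOUR_VANISHED,
        )
    phi = LevelSetField(phi0.values.copy())
    dt = params.dt
    stride = params.checkpoint_stride
    prev = _redistance(phi.values)
    snapshots = []
    area_history = []
    change_history = []
    reason = BUDGET
    iterations = 0
    for k in range(1, params.max_iterations + 1):
        try:
            update = rhs(phi, k)
        except DegenerateRegionError:
            reason = CONTOUR_VANISHED
            iterations = k - 1
            break
        if dt is None:
            dt = suggest_time_step(params, float(np.max(np.abs(update))))
        # pointwise CFL guard: no pixel moves more than half a cell per step
        phi.values += np.clip(dt * update, -MAX_DISPLACEMENT, MAX_DISPLACEMENT)
        iterations = k
        if not np.all(np.isfinite(phi.values)):
            raise NumericalInstabilityError(k)
        if reinit_every and k % reinit_every == 0:
            phi.values = _redistance(phi.values)
        if k % stride == 0 or k == params.max_iterations:
            if not phi.has_both_signs():
                reason = CONTOUR_VANISHED
                break
            band = np.abs(phi.values) < epsilon
            sdf = _redistance(phi.values)
            if band.any():
                change = float(np.mean(np.abs(sdf - prev)[band])) / stride
            else:
                change = 0.0
            change_history.append((k, change))
            area_history.append((k, int(np.count_nonzero(phi.values < 0))))
            if record_snapshots:
                snapshots.append((k, phi.values < 0))
            prev = sdf
            if change < params.tolerance:
                reason = CONVERGED
                break
    return SegmentationResult(
        phi=phi,
        mask=phi.inside_mask(),
        iterations=iterations,
        reason=reason,
        snapshots=snapshots,
        diagnostics={
            "dt": dt,
            "band_change": change_history,
            "inside_area": area_history,
        },
    )


def evolve_proposed(
    phi0: LevelSetField,
    grid: ImageGrid,
    params: EvolutionParams | None = None,
    record_snapshots: bool = False,
) -> SegmentationResult:
    """Run the convexity-preserving model from ``phi0``.

    Region means and the curvature/CSI fields are refreshed every
    iteration; the edge map is static.  Deterministic: identical inputs
    give bitwise-identical results.
    """
    if params is None:
        params = EvolutionParams()
    if grid.shape != phi0.shape:
        raise ContractError("phi0 shape does not match the image")
    from .core import edge_indicator  # local import avoids cycle at module load

    edges = edge_indicator(grid, params.smoothing.sigma, params.gradient_scale)
    eps = params.smoothing.epsilon
    cache = _CurvatureCache(params.csi_sigma)

    def rhs(phi: LevelSetField, k: int) -> np.ndarray:
        stats = compute_region_means(grid, phi, eps)
        curv = cache.get(phi, k)
        return proposed_rhs(phi, grid, stats, edges, curv, params)

    return _evolve_loop(
        phi0,
        rhs,
        params,
        eps,
        reinit_every=params.reinit_every,
        record_snapshots=record_snapshots,
    )


def cv_evolve(
    phi0: LevelSetField,
    grid: ImageGrid,
    params: CVParams | None = None,
    record_snapshots: bool = False,
) -> SegmentationResult:
    """Run the Chan–Vese baseline from ``phi0``."""
    if params is None:
        params = CVParams()
    if grid.shape != phi0.shape:
        raise ContractError("phi0 shape does not match the image")

    cache = _CurvatureCache(params.csi_sigma)

    def rhs(phi: LevelSetField, k: int) -> np.ndarray:
        stats = compute_region_means(grid, phi, params.epsilon)
        curv = cache.get(phi, k)
        return cv_rhs(phi, grid, stats, curv, params)

    return _evolve_loop(
        phi0,
        rhs,
        params,
        params.epsilon,
        reinit_every=params.reinit_every,
        record_snapshots=record_snapshots,
    )


def cplse_evolve(
    phi0: LevelSetField,
    grid: ImageGrid,
    params: CPLSEParams | None = None,
    record_snapshots: bool = False,
) -> SegmentationResult:
    """Run the CPLSE baseline (distance regularization + gated edge terms)."""
    if params is None:
        params = CPLSEParams()
    if grid.shape != phi0.shape:
        raise ContractError("phi0 shape does not match the image")
    from .core import edge_indicator

    edges = edge_indicator(grid, params.sigma, params.gradient_scale)
    g = edges.g

    cache = _CurvatureCache(params.csi_sigma)

    def rhs(phi: LevelSetField, k: int) -> np.ndarray:
        values = phi.values
        gx, gy = gradient(values)
        norm = np.sqrt(gx * gx + gy * gy)
        dp = drlse_dp(norm)
        regularization = params.mu_reg * divergence(dp * gx, dp * gy)
        safe = np.maximum(norm, GRAD_FLOOR)
        nx, ny = gx / safe, gy / safe
        curv = cache.get(phi, k)
        delta = smoothed_dirac(values, params.epsilon)
        edge_length = params.lambda_len * curv.s * delta * divergence(g * nx, g * ny)
        balloon = params.alpha_area * curv.s * g * delta
        convexity = (1.0 - curv.s) * curv.kappa * delta
        return regularization + edge_length + balloon + convexity

    return _evolve_loop(
        phi0,
        rhs,
        params,
        params.epsilon,
        reinit_every=params.reinit_every,
        record_snapshots=record_snapshots,
    )
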