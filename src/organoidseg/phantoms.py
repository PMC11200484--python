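"""Seeded synthetic bright-field organoid scenes with ground-truth masks.

The generator emulates the qualitative properties the segmentation models
exploit rather than photorealism: a relatively homogeneous bright
background, convex (disk/ellipse) organoids with a dark boundary ring and
a strongly inhomogeneous speckled interior, partially overlapping pairs
(both membrane arcs stay visible through the overlap, as in a projection
of translucent bodies), small dish impurities, blurry out-of-focus
distractors, and pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core import ImageGrid
from .errors import PhantomSpecError

__all__ = [
    "OrganoidSpec",
    "ImpuritySpec",
    "DistractorSpec",
    "PhantomSpec",
    "PhantomScene",
    "generate_phantom",
    "default_phantom_suite",
    "ARCHETYPES",
]

ARCHETYPES = (
    "overlap",
    "out_of_focus",
    "impurities",
    "adjacent",
    "weak_boundary",
)


@dataclass(frozen=True)
class OrganoidSpec:
    """One convex organoid: ellipse geometry plus appearance."""

    center: tuple[float, float]  # (x, y)
    axes: tuple[float, float]  # semi-axes (a, b) in px
    orientation: float = 0.0  # radians, CCW
    ring_intensity: float = 0.25
    ring_width: float = 3.0
    interior_level: float = 0.72
    texture_amplitude: float = 0.12
    texture_corr_length: float = 3.0


@dataclass(frozen=True)
class ImpuritySpec:
    """Small dark dish impurity (disk)."""

    center: tuple[float, float]
    radius: float = 3.0
    level: float = 0.55


@dataclass(frozen=True)
class DistractorSpec:
    """Blurry out-of-focus object rendered as a smoothed intensity bump."""

    center: tuple[float, float]
    radius: float = 28.0
    level: float = 0.72
    blur_sd: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one scene.

    ``target_index`` selects the organoid a benchmark run should segment;
    ``seed_point`` is the corresponding click; ``lambda1``/``beta`` are the
    per-scene weights the benchmark passes to the proposed model (the
    protocol tunes only those two per image).
    """

    shape: tuple[int, int] = (256, 256)
    background: float = 0.86
    noise_sd: float = 0.01
    organoids: tuple[OrganoidSpec, ...] = ()
    impurities: tuple[ImpuritySpec, ...] = ()
    distractors: tuple[DistractorSpec, ...] = ()
    global_blur_sd: float = 0.8
    seed: int = 0
    name: str = "phantom"
    archetype: str = "overlap"
    target_index: int = 0
    seed_point: tuple[int, int] | None = None  # (x, y); None -> target center
    lambda1: float = 3.5
    beta: float = 1.0

    def __post_init__(self):
        h, w = self.shape
        if h < 16 or w < 16:
            raise PhantomSpecError("scene must be at least 16x16")
        if not 0.0 <= self.background <= 1.0:
            raise PhantomSpecError("background level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise sd must be nonnegative")
        if not self.organoids:
            raise PhantomSpecError("a scene needs at least one organoid")
        if not 0 <= self.target_index < len(self.organoids):
            raise PhantomSpecError("target_index out of range")
        if self.archetype not in ARCHETYPES:
            raise PhantomSpecError(f"unknown archetype {self.archetype!r}")
        for org in self.organoids:
            cx, cy = org.center
            a, b = org.axes
            if a <= 0 or b <= 0:
                raise PhantomSpecError("organoid semi-axes must be positive")
            if not (-max(a, b) < cx < w + max(a, b)) or not (
                -max(a, b) < cy < h + max(a, b)
            ):
                raise PhantomSpecError(
                    "every organoid must lie at least partially inside the frame"
                )

    def resolved_seed_point(self) -> tuple[int, int]:
        if self.seed_point is not None:
            return self.seed_point
        cx, cy = self.organoids[self.target_index].center
        return int(round(cx)), int(round(cy))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomScene:
    """Rendered scene: image grid + per-organoid analytic masks + its spec."""

    grid: ImageGrid
    masks: list[np.ndarray] = field(default_factory=list)
    spec: PhantomSpec | None = None

    @property
    def target_mask(self) -> np.ndarray:
        return self.masks[self.spec.target_index]


def _elliptical_rho(
    shape: tuple[int, int], org: OrganoidSpec
) -> np.ndarray:
    """Normalized elliptical radius: 1 on the organoid boundary."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = org.center
    a, b = org.axes
    ct, st = np.cos(org.orientation), np.sin(org.orientation)
    u = ((xx - cx) * ct + (yy - cy) * st) / a
    v = (-(xx - cx) * st + (yy - cy) * ct) / b
    return np.sqrt(u * u + v * v)


def generate_phantom(spec: PhantomSpec) -> PhantomScene:
    """Render one scene deterministically from its spec and seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), spec.background, dtype=np.float64)

    rhos = [_elliptical_rho(spec.shape, org) for org in spec.organoids]
    masks = [rho <= 1.0 for rho in rhos]
    cores = []
    for org, rho in zip(spec.organoids, rhos):
        w_norm = org.ring_width / (0.5 * (org.axes[0] + org.axes[1]))
        cores.append(rho < 1.0 - w_norm)

    # correlated interior texture shared across the scene (one draw per scene)
    white = rng.standard_normal((h, w))
    for org, mask in zip(spec.organoids, masks):
        texture = ndimage.gaussian_filter(white, sigma=org.texture_corr_length)
        sd = texture.std()
        if sd > 0:
            texture = texture / sd
        img[mask] = org.interior_level + org.texture_amplitude * texture[mask]

    # rings after interiors; both rings stay visible through an overlap, as
    # in a bright-field projection of two translucent bodies
    for org, rho in zip(spec.organoids, rhos):
        w_norm = org.ring_width / (0.5 * (org.axes[0] + org.axes[1]))
        ring = (rho <= 1.0) & (rho >= 1.0 - w_norm)
        img[ring] = org.ring_intensity

    for imp in spec.impurities:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        disk = (xx - imp.center[0]) ** 2 + (yy - imp.center[1]) ** 2 <= imp.radius**2
        img[disk] = imp.level

    for dis in spec.distractors:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        disk = (
            (xx - dis.center[0]) ** 2 + (yy - dis.center[1]) ** 2 <= dis.radius**2
        ).astype(np.float64)
        bump = ndimage.gaussian_filter(disk, sigma=dis.blur_sd)
        img += (dis.level - spec.background) * bump

    if spec.global_blur_sd > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.global_blur_sd)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return PhantomScene(grid=ImageGrid(img), masks=masks, spec=spec)


def _disk(center, radius, **kw) -> OrganoidSpec:
    return OrganoidSpec(center=center, axes=(radius, radius), **kw)


def default_phantom_suite() -> list[PhantomSpec]:
    """Ten fixed-seed scenes, two per difficulty archetype."""
    suite: list[PhantomSpec] = []

    # --- overlap: two partially overlapping organoids, target on top
    suite.append(
        PhantomSpec(
            name="overlap-vertical",
            archetype="overlap",
            seed=101,
            organoids=(
                _disk((128, 106), 45.0),
                _disk((128, 186), 45.0),
            ),
            target_index=0,
            lambda1=2.5,
        )
    )
    suite.append(
        PhantomSpec(
            name="overlap-diagonal",
            archetype="overlap",
            seed=102,
            organoids=(
                OrganoidSpec(center=(116, 112), axes=(46.0, 40.0), orientation=0.3),
                _disk((168, 172), 42.0),
            ),
            target_index=0,
            lambda1=2.5,
        )
    )

    # --- out-of-focus: blurry shadow of an organoid off the focal plane
    suite.append(
        PhantomSpec(
            name="oof-shadow-left",
            archetype="out_of_focus",
            seed=103,
            organoids=(_disk((140, 134), 45.0),),
            distractors=(DistractorSpec(center=(52, 60), radius=30.0, level=0.74),),
            lambda1=2.5,
        )
    )
    suite.append(
        PhantomSpec(
            name="oof-shadow-corner",
            archetype="out_of_focus",
            seed=104,
            organoids=(OrganoidSpec(center=(118, 126), axes=(48.0, 42.0)),),
            distractors=(
                DistractorSpec(center=(204, 196), radius=26.0, level=0.73),
            ),
            lambda1=2.5,
        )
    )

    # --- impurities: small dark specks between the init contour and the boundary
    suite.append(
        PhantomSpec(
            name="impurities-three",
            archetype="impurities",
            seed=105,
            organoids=(_disk((128, 128), 45.0),),
            impurities=(
                ImpuritySpec(center=(164, 164), radius=3.0),
                ImpuritySpec(center=(90, 166), radius=3.5),
                ImpuritySpec(center=(92, 92), radius=3.0),
            ),
            lambda1=3.5,
        )
    )
    suite.append(
        PhantomSpec(
            name="impurities-ellipse",
            archetype="impurities",
            seed=106,
            organoids=(
                OrganoidSpec(center=(130, 124), axes=(50.0, 42.0), orientation=-0.2),
            ),
            impurities=(
                ImpuritySpec(center=(172, 168), radius=3.0),
                ImpuritySpec(center=(86, 86), radius=3.0),
            ),
            lambda1=3.5,
        )
    )

    # --- adjacent: a second organoid close by but not overlapping
    suite.append(
        PhantomSpec(
            name="adjacent-pair",
            archetype="adjacent",
            seed=107,
            organoids=(
                _disk((100, 128), 40.0),
                _disk((188, 128), 40.0),
            ),
            target_index=0,
            lambda1=3.0,
        )
    )
    suite.append(
        PhantomSpec(
            name="adjacent-corner",
            archetype="adjacent",
            seed=108,
            organoids=(
                _disk((140, 140), 44.0),
                _disk((220, 220), 36.0),
            ),
            target_index=0,
            lambda1=3.0,
        )
    )

    # --- weak boundary: low-contrast ring, higher beta guards against leakage
    suite.append(
        PhantomSpec(
            name="weak-boundary-disk",
            archetype="weak_boundary",
            seed=109,
            organoids=(_disk((128, 128), 45.0, ring_intensity=0.45),),
            lambda1=2.0,
            beta=2.0,
        )
    )
    suite.append(
        PhantomSpec(
            name="weak-boundary-ellipse",
            archetype="weak_boundary",
            seed=110,
            organoids=(
                OrganoidSpec(
                    center=(126, 130),
                    axes=(48.0, 41.0),
                    orientation=0.25,
                    ring_intensity=0.45,
                ),
            ),
            lambda1=2.0,
            beta=2.0,
        )
    )
    return suite
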