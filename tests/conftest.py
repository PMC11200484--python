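"""Shared fixtures: analytic test images, signed distances, and the
(session-cached) phantom benchmark used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from organoidseg.core import ImageGrid, LevelSetField
from organoidseg.init import InitRectangle, SeedPoint, rectangle_to_levelset


def disk_sdf(shape: tuple[int, int], center: tuple[float, float], radius: float) -> LevelSetField:
    """Signed distance of a disk, negative inside (exact, analytic)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(xx - center[0], yy - center[1])
    return LevelSetField(r - radius)


def halfplane_sdf(shape: tuple[int, int], x0: float) -> LevelSetField:
    """Signed distance of the half-plane {x < x0}, negative inside."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return LevelSetField(xx - x0)


@pytest.fixture
def two_phase_disk():
    """Noiseless two-phase image: dark disk (0.2) on bright background (0.8)."""
    h = w = 256
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(xx - 128, yy - 128)
    img = np.where(r <= 60, 0.2, 0.8)
    grid = ImageGrid(img)
    truth = r <= 60
    phi0 = rectangle_to_levelset(InitRectangle(SeedPoint(128, 128), 85, 85), grid)
    return grid, truth, phi0


@pytest.fixture(scope="session")
def benchmark_report():
    """Full three-model benchmark over the default suite (runs once)."""
    from organoidseg.evaluation import run_benchmark
    from organoidseg.phantoms import default_phantom_suite

    return run_benchmark(default_phantom_suite())
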