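"""Image/result persistence and run configuration.

Coordinates in files and flags are 0-based with x = column, y = row; masks
are written with 255 = inside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .core import ImageGrid
from .errors import ContractError, ImageIOError, ParameterError

__all__ = [
    "RunConfig",
    "load_image",
    "save_mask",
    "load_mask",
    "save_overlay",
    "save_image_16bit",
    "load_config",
    "save_config",
    "contour_pixels",
]


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of a segmentation run, with the published defaults."""

    model: str = "proposed"
    lambda1: float = 3.0
    lambda2: float = 1.0
    alpha: float = 1.0
    mu: float = 10.0
    beta: float = 1.0
    epsilon: float = 1.5
    sigma: float = 1.5
    dt: float | None = None
    max_iterations: int = 1500
    tolerance: float = 2e-3
    checkpoint_stride: int = 25
    csi_sigma: float = 1.0
    gradient_scale: float = 255.0
    reinit_every: int = 25
    # C-V baseline / pre-segmentation
    mu_cv: float = 0.05
    v: float = 0.0
    preseg_iterations: int = 300
    # CPLSE baseline
    mu_reg: float = 0.2
    lambda_len: float = 5.0
    alpha_area: float = 3.0
    # initialization
    expansion: float = 0.2
    seed_x: int | None = None
    seed_y: int | None = None
    # bookkeeping
    image: str | None = None
    out_dir: str | None = None
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a JSON or YAML config; unknown keys are rejected by name."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ImageIOError(f"cannot read config {path}: {exc}") from exc
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config root must be a mapping, got {type(data)}")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    except OSError as exc:
        raise ImageIOError(f"cannot write config {path}: {exc}") from exc


def load_image(path) -> ImageGrid:
    """Load a grayscale (or RGB, converted by luminance) image as an ImageGrid.

    Intensities are normalized to [0, 1] by dividing by the dtype maximum;
    the original bit depth is recorded.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    dtype = np.asarray(arr).dtype
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ImageIOError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        arr = (
            0.2125 * arr[..., 0] + 0.7154 * arr[..., 1] + 0.0721 * arr[..., 2]
        )
    elif arr.ndim != 2:
        raise ImageIOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if dtype == np.uint8:
        depth, maxval = 8, 255.0
    elif dtype == np.uint16:
        depth, maxval = 16, 65535.0
    elif np.issubdtype(dtype, np.floating):
        depth, maxval = 32, max(float(np.max(arr)), 1.0)
    else:
        raise ImageIOError(f"unsupported image dtype {dtype} in {path}")
    return ImageGrid(np.asarray(arr, dtype=np.float64) / maxval, bit_depth=depth)


def save_image_16bit(intensities: np.ndarray, path) -> None:
    """Write [0, 1] intensities as 16-bit grayscale (PNG or TIFF by suffix)."""
    arr = np.clip(np.asarray(intensities, dtype=np.float64), 0.0, 1.0)
    data = np.round(arr * 65535.0).astype(np.uint16)
    try:
        iio.imwrite(Path(path), data)
    except Exception as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with 255 = inside."""
    mask = np.asarray(mask, dtype=bool)
    try:
        iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))
    except Exception as exc:
        raise ImageIOError(f"cannot write mask {path}: {exc}") from exc


def load_mask(path) -> np.ndarray:
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:
        raise ImageIOError(f"cannot read mask {path}: {exc}") from exc
    return np.asarray(arr) > 0


def contour_pixels(phi_values: np.ndarray) -> np.ndarray:
    """Pixels where phi changes sign along a row or column (zero level set)."""
    phi = np.asarray(phi_values, dtype=np.float64)
    neg = phi < 0
    edge = np.zeros_like(neg)
    edge[:, :-1] |= neg[:, :-1] != neg[:, 1:]
    edge[:-1, :] |= neg[:-1, :] != neg[1:, :]
    return edge


def save_overlay(grid: ImageGrid, phi_values: np.ndarray, path) -> None:
    """RGB PNG of the grayscale image with the zero level set drawn in red."""
    if grid.shape != phi_values.shape:
        raise ContractError("image and level-set shapes differ")
    base = np.round(grid.intensities * 255.0).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    edge = contour_pixels(phi_values)
    rgb[edge] = (255, 0, 0)
    try:
        iio.imwrite(Path(path), rgb)
    except Exception as exc:
        raise ImageIOError(f"cannot write overlay {path}: {exc}") from exc
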