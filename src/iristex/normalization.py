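"""Rubber-sheet unwrapping, heart-sector ROI cropping, and CLAHE enhancement.

The iris annulus is mapped to a fixed 360 x 720 rectangle: pixel (i, j)
samples the image at the point linearly interpolated between the pupil and
limbus boundary points along clock angle theta(j),

    x(r, theta) = (1 - r) x_p(theta) + r x_l(theta)
    y(r, theta) = (1 - r) y_p(theta) + r y_l(theta)

with r = i / (rows - 1), so row 0 is the pupil boundary and the last row
the limbus.  Columns span the full revolution at 0.5 degrees per column,
column 0 at 12 o'clock increasing clockwise; a clock-based iridology chart
sector therefore maps to a contiguous column range — the 60-degree heart
sector (2 to 4 o'clock of a left iris) is exactly 120 columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import exposure

from .segmentation import IrisGeometry

__all__ = [
    "NormalizedIris",
    "RoiSpec",
    "ClaheParams",
    "rubber_sheet",
    "crop_heart_roi",
    "enhance_clahe",
]


@dataclass(frozen=True)
class NormalizedIris:
    """Polar unwrapping of the iris annulus.

    ``pixels``: rows = radial fraction (0 = pupil boundary), columns = clock
    angle.  ``valid``: False where the sample point fell outside the source
    image and was filled with the nearest edge value.
    """

    pixels: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiSpec:
    """Window of the normalized iris holding the heart sector.

    ``clock_start``/``clock_end`` are hour marks (2-4 o'clock by default);
    the radial window starts at ``radial_row_start`` and spans
    ``n_radial_rows`` rows, skipping the pupil-border ring below and the
    limbus above.
    """

    clock_start: float = 2.0
    clock_end: float = 4.0
    radial_row_start: int = 60
    n_radial_rows: int = 190
    n_angular_cols: int = 120


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE tiling and clip limit.

    ``clip_limit`` is expressed as a multiple of the uniform histogram
    height of an 8-bit tile histogram (the common convention of 8-bit
    implementations); 2.0 is a mild default.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 2.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile counts must be >= 1")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")


def rubber_sheet(
    image: np.ndarray,
    geometry: IrisGeometry,
    out_rows: int = 360,
    out_cols: int = 720,
) -> NormalizedIris:
    """Unwrap the iris annulus to a fixed-size rectangle (bilinear sampling)."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    theta = 2.0 * np.pi * np.arange(out_cols) / out_cols
    # clock convention: 0 rad up, clockwise
    dxs, dys = np.sin(theta), -np.cos(theta)
    xp = geometry.pupil.x0 + geometry.pupil.r * dxs
    yp = geometry.pupil.y0 + geometry.pupil.r * dys
    xl = geometry.iris.x0 + geometry.iris.r * dxs
    yl = geometry.iris.y0 + geometry.iris.r * dys
    r = (np.arange(out_rows) / (out_rows - 1))[:, None]
    xs = (1 - r) * xp[None, :] + r * xl[None, :]
    ys = (1 - r) * yp[None, :] + r * yl[None, :]
    valid = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    pixels = map_coordinates(
        img, np.vstack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
    ).reshape(out_rows, out_cols)
    return NormalizedIris(pixels=pixels, valid=valid)


def crop_heart_roi(norm: NormalizedIris, spec: RoiSpec | None = None) -> np.ndarray:
    """Slice the ROI window out of the normalized iris (no resampling).

    The angular window starts at the column of ``clock_start`` (one hour =
    30 degrees = 60 columns at the default width) and spans
    ``n_angular_cols`` columns, wrapping modulo the angular axis; the radial
    window is a plain row slice.
    """
    spec = spec or RoiSpec()
    rows, cols = norm.pixels.shape
    deg_per_col = 360.0 / cols
    col_start = int(round(spec.clock_start * 30.0 / deg_per_col))
    sector_cols = int(round(((spec.clock_end - spec.clock_start) % 12) * 30.0 / deg_per_col))
    if sector_cols != spec.n_angular_cols:
        raise ValueError(
            f"clock sector spans {sector_cols} columns but n_angular_cols={spec.n_angular_cols}"
        )
    r0, r1 = spec.radial_row_start, spec.radial_row_start + spec.n_radial_rows
    if r0 < 0 or r1 > rows:
        raise ValueError(f"radial window [{r0}, {r1}) outside {rows} rows")
    col_idx = (col_start + np.arange(spec.n_angular_cols)) % cols
    return norm.pixels[r0:r1][:, col_idx]


def enhance_clahe(roi: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit ROI.

    A constant input is returned unchanged (no contrast is invented);
    output stays an 8-bit image.
    """
    params = params or ClaheParams()
    img = np.asarray(roi, dtype=np.float64)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if img8.max() == img8.min():
        return img8
    h, w = img8.shape
    kernel = (max(1, int(np.ceil(h / params.tile_rows))),
              max(1, int(np.ceil(w / params.tile_cols))))
    nbins = 256
    out = exposure.equalize_adapthist(
        img8, kernel_size=kernel, clip_limit=params.clip_limit / nbins, nbins=nbins
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
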