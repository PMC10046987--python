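"""Pupil and iris boundary localization with the integro-differential operator.

The detector maximizes, over candidate circles ``(x0, y0, r)``, the magnitude
of the Gaussian-blurred radial derivative of the mean image intensity along
the circle:

    max_{r, x0, y0} | G_sigma(r) * d/dr  (1 / 2 pi r) contour-integral I(x, y) ds |

A dark pupil on a lighter iris, and the iris on a brighter sclera, both
produce strong radial steps in this profile, so the argmax lands on the
boundary circle.  The search is run coarse-to-fine: candidate centers are
found on a block-averaged downscale of the image and refined at full
resolution; an exhaustive full-grid strategy is kept for small images and
for verification.

Angles follow the clock convention used throughout the package: angle 0
points to 12 o'clock (up in the displayed image) and increases clockwise,
so 3 o'clock is +x.  ``arc_mask`` intervals given in this convention let the
contour integral skip occluded arcs (eyelids at 12 and 6 o'clock).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from skimage.transform import downscale_local_mean

from .errors import NoCircleFoundError, OutOfBoundsError

__all__ = [
    "Circle",
    "IrisGeometry",
    "SearchConfig",
    "circular_mean_intensity",
    "ido_response",
    "locate_pupil",
    "locate_iris",
    "default_pupil_config",
    "default_iris_config",
]


@dataclass(frozen=True)
class Circle:
    """A circle in image pixel coordinates (x0 = column, y0 = row)."""

    x0: float
    y0: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")


@dataclass(frozen=True)
class IrisGeometry:
    """Pupil (inner) and limbus (outer) boundary circles of one eye."""

    pupil: Circle
    iris: Circle

    def __post_init__(self) -> None:
        offset = np.hypot(self.pupil.x0 - self.iris.x0, self.pupil.y0 - self.iris.y0)
        if offset + self.pupil.r >= self.iris.r:
            raise ValueError("pupil circle must lie strictly inside the iris circle")


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the circle search.

    radius_min / radius_max bound the candidate radii (pixels);
    ``sigma`` is the std of the Gaussian applied to the radial derivative,
    in units of radius steps.  ``arc_mask`` lists ``(start, end)`` clock-angle
    intervals in radians excluded from the contour integral.
    """

    radius_min: int
    radius_max: int
    center_stride: int = 1
    radius_stride: int = 1
    sigma: float = 1.0
    n_angular_samples: int = 128
    arc_mask: tuple[tuple[float, float], ...] = ()
    response_floor: float = 0.5
    coarse_downscale: int = 4
    # block-averaging skews the coarse score toward small sharp blobs, so a
    # generous candidate list is refined at full resolution before choosing
    n_candidates: int = 12
    # candidates whose disc interior is brighter than the darkest candidate's
    # by more than this (gray levels) are pruned in the pupil search
    interior_tolerance: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.radius_min < self.radius_max):
            raise ValueError("need 0 < radius_min < radius_max")
        if self.center_stride < 1 or self.radius_stride < 1:
            raise ValueError("strides must be >= 1")
        if self.n_angular_samples < 64:
            raise ValueError("n_angular_samples must be >= 64")


def _unit_vectors(n_angular_samples: int, arc_mask) -> tuple[np.ndarray, np.ndarray]:
    """Unit offsets (dx, dy) at the unmasked clock angles."""
    theta = 2.0 * np.pi * np.arange(n_angular_samples) / n_angular_samples
    keep = np.ones(n_angular_samples, dtype=bool)
    for start, end in arc_mask or ():
        lo, hi = start % (2 * np.pi), end % (2 * np.pi)
        if lo <= hi:
            keep &= ~((theta >= lo) & (theta <= hi))
        else:  # interval wraps through 0
            keep &= ~((theta >= lo) | (theta <= hi))
    if not keep.any():
        raise ValueError("arc_mask excludes every sample angle")
    theta = theta[keep]
    # clock convention: 0 rad points up (-y), increasing clockwise toward +x
    return np.sin(theta), -np.cos(theta)


def _check_inside(image: np.ndarray, x0: float, y0: float, r: float) -> None:
    h, w = image.shape
    if x0 - r < 0 or y0 - r < 0 or x0 + r > w - 1 or y0 + r > h - 1:
        raise OutOfBoundsError(
            f"circle (x0={x0}, y0={y0}, r={r}) exits the {w}x{h} image"
        )


def circular_mean_intensity(
    image: np.ndarray,
    circle: Circle,
    n_angular_samples: int = 128,
    arc_mask=(),
) -> float:
    """Mean of bilinearly interpolated intensities along a circle's arc."""
    img = np.asarray(image, dtype=np.float64)
    _check_inside(img, circle.x0, circle.y0, circle.r)
    dx, dy = _unit_vectors(n_angular_samples, arc_mask)
    xs = circle.x0 + circle.r * dx
    ys = circle.y0 + circle.r * dy
    vals = map_coordinates(img, np.vstack([ys, xs]), order=1, mode="nearest")
    return float(vals.mean())


def _mean_profiles(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
) -> np.ndarray:
    """Mean arc intensity for every (center, radius); shape (n_centers, n_radii)."""
    # coords: centers (C,2) [x, y]; build (C, R, S) sample grids
    xs = centers[:, 0, None, None] + radii[None, :, None] * dx[None, None, :]
    ys = centers[:, 1, None, None] + radii[None, :, None] * dy[None, None, :]
    vals = map_coordinates(
        image, np.vstack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
    )
    return vals.reshape(xs.shape).mean(axis=2)


def ido_response(
    image: np.ndarray,
    x0: float,
    y0: float,
    radii,
    sigma: float = 1.0,
    n_angular_samples: int = 128,
    arc_mask=(),
) -> np.ndarray:
    """|Gaussian-smoothed d/dr of the circular mean intensity| per radius.

    Adding a constant to the image leaves the response unchanged (the
    derivative removes offsets); a constant image gives an all-zero response.
    """
    radii = np.asarray(radii, dtype=np.float64)
    if radii.size < 3:
        raise ValueError("need at least 3 radii for a radial derivative")
    img = np.asarray(image, dtype=np.float64)
    for r in (radii[0], radii[-1]):
        _check_inside(img, x0, y0, r)
    dx, dy = _unit_vectors(n_angular_samples, arc_mask)
    means = _mean_profiles(img, np.array([[x0, y0]], float), radii, dx, dy)[0]
    deriv = np.gradient(means, radii)
    return np.abs(gaussian_filter1d(deriv, sigma, mode="nearest"))


def _search_centers(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    config: SearchConfig,
    chunk: int = 512,
):
    """Best (response, x0, y0, r) over a center grid.

    Radii that would push the circle out of the image are dropped per center;
    ties break toward smaller radius, then row-major center order.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    dx, dy = _unit_vectors(config.n_angular_samples, config.arc_mask)
    best = (-np.inf, 0.0, 0.0, 0.0)
    # max radius usable at each center so that samples stay in bounds
    margin = np.minimum(
        np.minimum(centers[:, 0], w - 1 - centers[:, 0]),
        np.minimum(centers[:, 1], h - 1 - centers[:, 1]),
    )
    for lo in range(0, len(centers), chunk):
        sub = centers[lo : lo + chunk]
        sub_margin = margin[lo : lo + chunk]
        ok = radii[None, :] <= sub_margin[:, None]
        usable = ok.sum(axis=1) >= 3
        if not usable.any():
            continue
        sub = sub[usable]
        ok = ok[usable]
        means = _mean_profiles(img, sub.astype(float), radii, dx, dy)
        # invalid radii form a suffix (radii ascending); hold the last valid
        # mean so the derivative there is zero and cannot win
        n_ok = ok.sum(axis=1)
        for ci in range(len(sub)):
            means[ci, n_ok[ci] :] = means[ci, n_ok[ci] - 1]
        deriv = np.gradient(means, radii, axis=1)
        resp = np.abs(gaussian_filter1d(deriv, config.sigma, axis=1, mode="nearest"))
        resp[~ok] = -np.inf
        for ci in range(len(sub)):
            ri = int(np.argmax(resp[ci]))  # first max = smallest radius
            cand = (float(resp[ci, ri]), float(sub[ci, 0]), float(sub[ci, 1]), float(radii[ri]))
            if _better(cand, best):
                best = cand
    return best


def _better(cand, best) -> bool:
    """Order candidates: larger response; then smaller r; then row-major center."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[3] != best[3]:
        return cand[3] < best[3]
    return (cand[2], cand[1]) < (best[2], best[1])


def _center_grid(h: int, w: int, margin: int, stride: int) -> np.ndarray:
    ys = np.arange(margin, h - margin, stride)
    xs = np.arange(margin, w - margin, stride)
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    return np.column_stack([gx.ravel(), gy.ravel()])


def _exhaustive(image: np.ndarray, config: SearchConfig):
    h, w = image.shape
    radii = np.arange(config.radius_min, config.radius_max + 1, config.radius_stride, dtype=float)
    margin = max(2, config.radius_min)
    centers = _center_grid(h, w, margin, config.center_stride)
    return _search_centers(image, centers, radii, config)


def _coarse_to_fine(image: np.ndarray, config: SearchConfig, dark_interior: bool = True):
    f = config.coarse_downscale
    h, w = image.shape
    small = downscale_local_mean(np.asarray(image, float), (f, f))
    sh, sw = small.shape
    c_rmin = max(2, config.radius_min // f)
    c_rmax = max(c_rmin + 2, int(np.ceil(config.radius_max / f)))
    c_radii = np.arange(c_rmin, c_rmax + 1, dtype=float)
    c_centers = _center_grid(sh, sw, max(2, c_rmin), 1)
    dx, dy = _unit_vectors(config.n_angular_samples, config.arc_mask)

    # score every coarse center, keep the strongest few as candidates
    scores = np.full(len(c_centers), -np.inf)
    radii_best = np.zeros(len(c_centers))
    margin = np.minimum(
        np.minimum(c_centers[:, 0], sw - 1 - c_centers[:, 0]),
        np.minimum(c_centers[:, 1], sh - 1 - c_centers[:, 1]),
    )
    for lo in range(0, len(c_centers), 512):
        sub = c_centers[lo : lo + 512]
        ok = c_radii[None, :] <= margin[lo : lo + 512, None]
        usable = ok.sum(axis=1) >= 3
        if not usable.any():
            continue
        means = _mean_profiles(small, sub[usable].astype(float), c_radii, dx, dy)
        oku = ok[usable]
        n_ok = oku.sum(axis=1)
        for ci in range(len(means)):
            means[ci, n_ok[ci] :] = means[ci, n_ok[ci] - 1]
        deriv = np.gradient(means, c_radii, axis=1)
        resp = np.abs(gaussian_filter1d(deriv, config.sigma, axis=1, mode="nearest"))
        resp[~oku] = -np.inf
        idx = np.argmax(resp, axis=1)
        rows = np.flatnonzero(usable) + lo
        scores[rows] = resp[np.arange(len(idx)), idx]
        radii_best[rows] = c_radii[idx]

    # Stage 1: non-maximum suppression on the coarse score map, keeping a
    # generous candidate pool (block averaging skews the coarse score toward
    # small sharp blobs, so the coarse ranking alone is unreliable).
    pool = []
    min_sep = max(3.0, c_rmin)
    for ci in np.argsort(-scores, kind="stable"):
        if not np.isfinite(scores[ci]):
            break
        if all(np.hypot(*(c_centers[ci] - c_centers[cj])) >= min_sep for cj in pool):
            pool.append(ci)
        if len(pool) >= 4 * config.n_candidates:
            break

    # Stage 2: re-rank the pool by the full-resolution response at the
    # candidate center alone (cheap: one profile per candidate), and record
    # the interior brightness of each candidate disc.
    full_radii = np.arange(
        config.radius_min, config.radius_max + 1, config.radius_stride, dtype=float
    )
    rescored = []
    for ci in pool:
        cand = _search_centers(image, (c_centers[[ci]] * f).astype(float), full_radii, config)
        if np.isfinite(cand[0]):
            interior = _interior_mean(image, cand[1], cand[2], cand[3])
            rescored.append((cand[0], ci, cand[3], interior))
    if not rescored:
        return (-np.inf, 0.0, 0.0, 0.0)

    if dark_interior:
        # the pupil is the dark disc: prune candidates whose interior is
        # clearly brighter than the darkest candidate's (fiber troughs and
        # limbus-grazing arcs survive the response ranking otherwise)
        darkest = min(r[3] for r in rescored)
        rescored = [r for r in rescored if r[3] <= darkest + config.interior_tolerance]
    rescored.sort(key=lambda t: -t[0])

    # Stage 3: box refinement around the strongest candidates; the box
    # half-width matches the suppression radius of stage 1 so a true center
    # suppressed by a nearby blob is still reachable.
    half = int(min_sep * f)
    best = (-np.inf, 0.0, 0.0, 0.0)
    for score_c, ci, rc, _ in rescored[: config.n_candidates]:
        cx, cy = c_centers[ci] * f
        r_lo = max(config.radius_min, int(rc - 2 * f))
        r_hi = min(config.radius_max, int(rc + 2 * f))
        radii = np.arange(r_lo, r_hi + 1, config.radius_stride, dtype=float)
        if radii.size < 3:
            continue
        stride = max(config.center_stride, 2)
        xs = np.arange(max(0, cx - half), min(w - 1, cx + half) + 1, stride)
        ys = np.arange(max(0, cy - half), min(h - 1, cy + half) + 1, stride)
        gx, gy = np.meshgrid(xs, ys)
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        cand = _search_centers(image, centers, radii, config)
        if _better(cand, best):
            best = cand
    # polish at unit stride around the winner
    if np.isfinite(best[0]):
        bx, by, br = int(best[1]), int(best[2]), best[3]
        radii = np.arange(
            max(config.radius_min, br - 3),
            min(config.radius_max, br + 3) + 1,
            config.radius_stride,
            dtype=float,
        )
        xs = np.arange(max(0, bx - 2), min(w - 1, bx + 2) + 1, config.center_stride)
        ys = np.arange(max(0, by - 2), min(h - 1, by + 2) + 1, config.center_stride)
        gx, gy = np.meshgrid(xs, ys)
        if radii.size >= 3:
            cand = _search_centers(image, np.column_stack([gx.ravel(), gy.ravel()]), radii, config)
            if _better(cand, best):
                best = cand
    return best


def _interior_mean(image: np.ndarray, x0: float, y0: float, r: float) -> float:
    """Mean intensity of the disc interior (sampled on a few inner circles)."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    vals = [img[int(round(y0)), int(round(x0))]]
    theta = 2.0 * np.pi * np.arange(32) / 32
    for frac in (0.25, 0.5, 0.7):
        xs = np.clip(x0 + frac * r * np.sin(theta), 0, w - 1)
        ys = np.clip(y0 - frac * r * np.cos(theta), 0, h - 1)
        vals.append(map_coordinates(img, np.vstack([ys, xs]), order=1).mean())
    return float(np.mean(vals))


def locate_pupil(
    image: np.ndarray, config: SearchConfig, strategy: str = "coarse_to_fine"
) -> Circle:
    """Find the pupil boundary circle maximizing the IDO response.

    ``strategy`` is ``"coarse_to_fine"`` (default) or ``"exhaustive"``
    (full grid; intended for small images and verification).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if strategy == "exhaustive":
        resp, x0, y0, r = _exhaustive(img, config)
    elif strategy == "coarse_to_fine":
        resp, x0, y0, r = _coarse_to_fine(img, config)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not np.isfinite(resp) or resp < config.response_floor:
        raise NoCircleFoundError(
            f"max response {resp:.4g} below floor {config.response_floor}"
        )
    return Circle(x0, y0, r)


def locate_iris(
    image: np.ndarray,
    pupil: Circle,
    config: SearchConfig,
    center_search: int = 15,
    strategy: str = "two_stage",
) -> Circle:
    """Find the limbus circle, center-constrained near the found pupil.

    The candidate center is restricted to a box of half-width
    ``center_search`` pixels around the pupil center.  ``config.radius_min``
    must exceed the pupil radius.
    """
    img = np.asarray(image, dtype=np.float64)
    if config.radius_min <= pupil.r:
        raise ValueError(
            f"iris radius_min ({config.radius_min}) must exceed pupil radius ({pupil.r})"
        )
    h, w = img.shape
    px, py = int(round(pupil.x0)), int(round(pupil.y0))

    def box(cx, cy, half, stride):
        xs = np.arange(max(0, cx - half), min(w - 1, cx + half) + 1, stride)
        ys = np.arange(max(0, cy - half), min(h - 1, cy + half) + 1, stride)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    if strategy == "exhaustive":
        radii = np.arange(config.radius_min, config.radius_max + 1, config.radius_stride, dtype=float)
        resp, x0, y0, r = _search_centers(img, box(px, py, center_search, config.center_stride), radii, config)
    else:
        stage1 = replace(config, radius_stride=max(config.radius_stride, 2))
        radii1 = np.arange(stage1.radius_min, stage1.radius_max + 1, stage1.radius_stride, dtype=float)
        resp, x0, y0, r = _search_centers(img, box(px, py, center_search, 3), radii1, stage1)
        if np.isfinite(resp):
            r_lo = max(config.radius_min, int(r) - 3)
            r_hi = min(config.radius_max, int(r) + 3)
            radii2 = np.arange(r_lo, r_hi + 1, config.radius_stride, dtype=float)
            if radii2.size >= 3:
                cand = _search_centers(
                    img, box(int(x0), int(y0), 3, config.center_stride), radii2, config
                )
                if _better(cand, (resp, x0, y0, r)):
                    resp, x0, y0, r = cand
    if not np.isfinite(resp) or resp < config.response_floor:
        raise NoCircleFoundError(
            f"max response {resp:.4g} below floor {config.response_floor}"
        )
    return Circle(x0, y0, r)


def default_pupil_config(image_shape: tuple[int, int], **overrides) -> SearchConfig:
    """Anatomically motivated pupil search range: [min_dim/40, min_dim/8]."""
    m = min(image_shape[:2])
    kw = dict(radius_min=max(3, m // 40), radius_max=max(6, m // 8))
    kw.update(overrides)
    return SearchConfig(**kw)


def default_iris_config(
    pupil: Circle, image_shape: tuple[int, int], mask_lids: bool = False, **overrides
) -> SearchConfig:
    """Iris search range [1.5, 5] x pupil radius, capped to stay in-image.

    ``mask_lids`` excludes +-45 degrees around 12 and 6 o'clock from the
    contour integral to dodge eyelid edges (off by default: synthetic eyes
    have no lids).
    """
    h, w = image_shape[:2]
    cap = int(min(pupil.x0, pupil.y0, w - 1 - pupil.x0, h - 1 - pupil.y0)) - 2
    rmin = int(np.ceil(1.5 * pupil.r))
    rmax = min(int(5 * pupil.r), cap)
    mask: tuple[tuple[float, float], ...] = ()
    if mask_lids:
        q = np.pi / 4
        mask = ((2 * np.pi - q, q), (np.pi - q, np.pi + q))
    kw = dict(radius_min=rmin, radius_max=max(rmax, rmin + 3), arc_mask=mask)
    kw.update(overrides)
    return SearchConfig(**kw)
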