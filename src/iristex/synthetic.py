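"""Synthetic eye images with known geometry and class-dependent iris texture.

The clinical iris photographs behind this kind of screening study are not
publicly deposited, so this module renders controllable stand-ins: a bright
sclera, a dark pupil disc, and an iris annulus carrying radial fiber
striation (sinusoidal angular modulation plus smoothed noise).  For the
"diseased" class, dark elliptical lesions are placed *in polar coordinates*
inside the heart sector of the iridology map (2-4 o'clock of a left iris)
and rendered into Cartesian space, so the class signal is guaranteed to land
inside the heart ROI after rubber-sheet unwrapping.  The lesion model is an
artifact of the benchmark, not a claim about iridology.

Also provides tiny integer matrices used as brute-force oracle fixtures for
the texture-feature stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .segmentation import Circle, IrisGeometry

__all__ = [
    "EyeSpec",
    "SyntheticCohort",
    "HEART_SECTOR_DEG",
    "generate_eye",
    "generate_cohort",
    "toy_matrices",
    "write_cohort",
]

# clock-angle extent of the heart sector in a left iris (2 to 4 o'clock),
# measured in degrees clockwise from 12 o'clock
HEART_SECTOR_DEG = (60.0, 120.0)


@dataclass(frozen=True)
class EyeSpec:
    """Ground-truth description of one synthetic eye."""

    image_height: int = 320
    image_width: int = 320
    pupil: Circle = Circle(160.0, 160.0, 38.0)
    iris: Circle = Circle(160.0, 160.0, 112.0)
    pupil_intensity: float = 35.0
    iris_base_intensity: float = 125.0
    sclera_intensity: float = 215.0
    fiber_amplitude: float = 16.0
    fiber_frequency: int = 36
    lesion_count: int = 8
    lesion_contrast: float = 0.0
    label: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        offset = np.hypot(self.pupil.x0 - self.iris.x0, self.pupil.y0 - self.iris.y0)
        if offset + self.pupil.r >= self.iris.r:
            raise GeometryError("pupil circle must lie strictly inside the iris circle")
        h, w = self.image_height, self.image_width
        if (
            self.iris.x0 - self.iris.r < 0
            or self.iris.y0 - self.iris.r < 0
            or self.iris.x0 + self.iris.r > w - 1
            or self.iris.y0 + self.iris.r > h - 1
        ):
            raise GeometryError("iris circle must lie strictly inside the image")
        if not (self.pupil_intensity < self.iris_base_intensity < self.sclera_intensity):
            raise GeometryError(
                "expected pupil_intensity < iris_base_intensity < sclera_intensity"
            )
        if self.lesion_count < 0:
            raise GeometryError("lesion_count must be >= 0")

    @property
    def geometry(self) -> IrisGeometry:
        return IrisGeometry(self.pupil, self.iris)


@dataclass(frozen=True)
class SyntheticCohort:
    images: list
    truths: list
    labels: list


def _soft_disc(dist: np.ndarray, radius: float, width: float = 1.5) -> np.ndarray:
    """1 inside the circle, 0 outside, linear ramp across ``width`` pixels."""
    return np.clip((radius + width / 2 - dist) / width, 0.0, 1.0)


def _boundary_point(circle: Circle, theta: float) -> tuple[float, float]:
    # clock convention: theta=0 points up, increases clockwise
    return (
        circle.x0 + circle.r * np.sin(theta),
        circle.y0 - circle.r * np.cos(theta),
    )


def generate_eye(spec: EyeSpec) -> tuple[np.ndarray, EyeSpec]:
    """Render one eye as an 8-bit grayscale image; pure function of the spec.

    With ``lesion_contrast == 0`` (or label 0) the iris annulus is
    statistically homogeneous in angle; with label 1 the lesions perturb
    run-length and co-occurrence statistics only inside the heart sector.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    d_iris = np.hypot(xx - spec.iris.x0, yy - spec.iris.y0)
    d_pupil = np.hypot(xx - spec.pupil.x0, yy - spec.pupil.y0)
    theta = np.arctan2(xx - spec.iris.x0, -(yy - spec.iris.y0)) % (2 * np.pi)

    # radial fiber striation: angular sinusoid + smoothed broadband noise
    fibers = spec.fiber_amplitude * np.sin(spec.fiber_frequency * theta)
    grain = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
    grain *= 0.6 * spec.fiber_amplitude / max(grain.std(), 1e-12)
    iris_tex = spec.iris_base_intensity + fibers + grain

    img = np.full((h, w), spec.sclera_intensity, dtype=np.float64)
    in_iris = _soft_disc(d_iris, spec.iris.r)
    img = img * (1 - in_iris) + iris_tex * in_iris
    in_pupil = _soft_disc(d_pupil, spec.pupil.r)
    img = img * (1 - in_pupil) + spec.pupil_intensity * in_pupil

    if spec.label == 1 and spec.lesion_contrast != 0 and spec.lesion_count > 0:
        lo, hi = np.deg2rad(HEART_SECTOR_DEG)
        for _ in range(spec.lesion_count):
            th = rng.uniform(lo + 0.08, hi - 0.08)
            rfrac = rng.uniform(0.25, 0.60)
            px, py = _boundary_point(spec.pupil, th)
            lx, ly = _boundary_point(spec.iris, th)
            cx = (1 - rfrac) * px + rfrac * lx
            cy = (1 - rfrac) * py + rfrac * ly
            a, b = rng.uniform(3.0, 6.0), rng.uniform(2.0, 4.0)
            phi = rng.uniform(0, np.pi)
            u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
            v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
            mask = np.clip(1.5 * (1.0 - np.hypot(u / a, v / b)), 0.0, 1.0)
            img -= spec.lesion_contrast * mask * in_iris * (1 - in_pupil)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), spec


def generate_cohort(
    n_per_class: int, effect: float, seed: int = 0
) -> SyntheticCohort:
    """2 * n_per_class eyes with randomized geometry; classes differ only by
    a heart-sector texture perturbation of magnitude ``effect`` (gray levels).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, truths, labels = [], [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            cx = 160.0 + rng.uniform(-8, 8)
            cy = 160.0 + rng.uniform(-8, 8)
            pr = rng.uniform(28, 38)
            ir = rng.uniform(100, 122)
            ix = cx + rng.uniform(-3, 3)
            iy = cy + rng.uniform(-3, 3)
            spec = EyeSpec(
                pupil=Circle(cx, cy, pr),
                iris=Circle(ix, iy, ir),
                pupil_intensity=rng.uniform(25, 45),
                iris_base_intensity=rng.uniform(110, 140),
                sclera_intensity=rng.uniform(200, 230),
                fiber_amplitude=rng.uniform(12, 20),
                fiber_frequency=int(rng.integers(24, 48)),
                lesion_count=8,
                lesion_contrast=float(effect),
                label=label,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, truth = generate_eye(spec)
            images.append(img)
            truths.append(truth)
            labels.append(label)
    return SyntheticCohort(images, truths, labels)


def toy_matrices() -> dict[str, np.ndarray]:
    """Small integer images used as brute-force oracle fixtures."""
    rng = np.random.default_rng(12345)
    return {
        "constant5": np.full((5, 5), 7, dtype=np.int64),
        "checker4": np.indices((4, 4)).sum(axis=0) % 2,
        "runrow": np.array([[0, 0, 0, 1, 1]], dtype=np.int64),
        "random8": rng.integers(0, 8, size=(8, 8)),
    }


def write_cohort(cohort: SyntheticCohort, outdir) -> "Path":
    """Write PNGs plus a CSV manifest; returns the manifest path."""
    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth, label) in enumerate(
        zip(cohort.images, cohort.truths, cohort.labels)
    ):
        name = f"eye_{i:04d}.png"
        Image.fromarray(img).save(outdir / name)
        rows.append(
            dict(
                filename=name,
                label=label,
                pupil_x=truth.pupil.x0,
                pupil_y=truth.pupil.y0,
                pupil_r=truth.pupil.r,
                iris_x=truth.iris.x0,
                iris_y=truth.iris.y0,
                iris_r=truth.iris.r,
                seed=truth.seed,
            )
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
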