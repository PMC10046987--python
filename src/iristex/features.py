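"""Wavelet sub-band texture descriptors: 136-value feature vector per ROI.

One level of a separable 2-D discrete wavelet transform splits the ROI into
four sub-bands (cA approximation, cH horizontal, cV vertical, cD diagonal
detail).  Each sub-band contributes 34 features — 5 first-order statistics,
22 gray-level co-occurrence (GLCM) features averaged over the four standard
directions (0, 45, 90, 135 degrees, distance 1, 8 gray levels), and 7
gray-level run-length (GLRLM) features averaged over the same directions at
16 gray levels — for 4 x 34 = 136 values in a stable, named order
(cA, cH, cV, cD).

Detail-band coefficients are signed, so both co-occurrence and run-length
stages first quantize each band by uniform min-max binning into L levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ConfigError, EmptyGLCMError, EmptyGLRLMError

__all__ = [
    "SubBands",
    "FeatureConfig",
    "FeatureVector",
    "BAND_ORDER",
    "STAT_NAMES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "DIRECTIONS_DEG",
    "feature_names",
    "dwt2_level1",
    "first_order_stats",
    "quantize",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "directional_average",
    "extract_feature_vector",
]

BAND_ORDER = ("cA", "cH", "cV", "cD")
DIRECTIONS_DEG = (0, 45, 90, 135)

STAT_NAMES = ("mean", "std", "entropy", "skewness", "kurtosis")

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "imc1",
    "imc2",
    "inverse_difference_moment",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares",
    "sum_variance",
    "maximal_correlation_coefficient",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rp", "rln", "lgre", "hgre")

# pixel-pair offsets (drow, dcol) per direction, for distance d
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class SubBands:
    """Single-level 2-D DWT coefficient matrices (all four the same shape)."""

    cA: np.ndarray
    cH: np.ndarray
    cV: np.ndarray
    cD: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cA": self.cA, "cH": self.cH, "cV": self.cV, "cD": self.cD}


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the texture descriptor.

    The wavelet defaults to Haar (orthogonal, exact halving of even
    dimensions, perfect reconstruction); ``mcc_sqrt`` selects the
    square-root form of the maximal correlation coefficient.
    """

    wavelet: str = "haar"
    glcm_levels: int = 8
    glcm_distance: int = 1
    glcm_symmetric: bool = True
    glrlm_levels: int = 16
    mcc_sqrt: bool = True


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def feature_names() -> tuple[str, ...]:
    """The 136 feature names: per band, 5 stats + 22 GLCM + 7 GLRLM."""
    names = []
    for band in BAND_ORDER:
        names += [f"{band}_{s}" for s in STAT_NAMES]
        names += [f"{band}_glcm_{s}" for s in GLCM_FEATURE_NAMES]
        names += [f"{band}_glrlm_{s}" for s in GLRLM_FEATURE_NAMES]
    return tuple(names)


def dwt2_level1(roi: np.ndarray, wavelet: str = "haar") -> SubBands:
    """One level of the separable 2-D DWT (periodized boundary).

    Periodization keeps the transform non-redundant, so for an orthogonal
    wavelet on even-sized inputs coefficient energy equals input energy and
    the inverse transform is exact.
    """
    arr = np.asarray(roi, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("ROI must be a 2-D array at least 2x2")
    try:
        cA, (cH, cV, cD) = pywt.dwt2(arr, wavelet, mode="periodization")
    except ValueError as exc:
        raise ConfigError(f"unknown wavelet {wavelet!r}") from exc
    return SubBands(cA=cA, cH=cH, cV=cV, cD=cD)


def _plogp(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 * log 0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def first_order_stats(band: np.ndarray, n_bins: int = 256):
    """(mean, std, entropy, skewness, kurtosis) of a coefficient matrix.

    std uses the 1/(N-1) normalization; entropy is the Shannon entropy
    (bits) of the min-max histogram with ``n_bins`` bins; skewness and
    kurtosis are the biased moment ratios m3 / m2^1.5 and m4 / m2^2.
    A constant input yields (c, 0, 0, 0, 0).
    """
    x = np.asarray(band, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("band is empty")
    mean = float(x.mean())
    if x.size < 2 or np.ptp(x) == 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    std = float(x.std(ddof=1))
    hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = hist / x.size
    entropy = float(-_plogp(p).sum())
    centered = x - mean
    m2 = float((centered**2).mean())
    m3 = float((centered**3).mean())
    m4 = float((centered**4).mean())
    skewness = m3 / m2**1.5
    kurtosis = m4 / m2**2
    return mean, std, entropy, skewness, kurtosis


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Uniform min-max binning into integer levels [0, levels-1].

    Signed coefficients are handled by the min-max range; a constant band
    maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    x = np.asarray(band, dtype=np.float64)
    span = np.ptp(x)
    if span == 0:
        return np.zeros(x.shape, dtype=np.int64)
    q = np.floor((x - x.min()) / span * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm(
    q: np.ndarray,
    levels: int,
    theta_deg: int,
    d: int = 1,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix p(i, j) at offset (d, theta).

    Counts level pairs at the directional offset, optionally adds the
    transpose (symmetric accumulation, which equalizes the marginals), and
    normalizes the counts to sum to 1.
    """
    q = np.asarray(q)
    if theta_deg not in _OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_OFFSETS)} degrees")
    dr, dc = (x * d for x in _OFFSETS[theta_deg])
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise EmptyGLCMError(f"no pixel pair fits offset ({dr}, {dc}) in {q.shape}")
    i = q[r0:r1, c0:c1].ravel()
    j = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(i * levels + j, minlength=levels * levels).reshape(
        levels, levels
    ).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(P: np.ndarray, mcc_sqrt: bool = True) -> np.ndarray:
    """The 22 co-occurrence features, in the order of GLCM_FEATURE_NAMES.

    Gray levels are indexed 1..L in all moment-type features; entropy-like
    features use base-2 logs with 0*log0 := 0.  With a degenerate marginal
    (zero variance) the correlation is defined as 0; the maximal correlation
    coefficient drops zero-marginal levels before forming Haralick's Q
    matrix and reports sqrt(second-largest eigenvalue), clipped to [0, 1].
    """
    P = np.asarray(P, dtype=np.float64)
    L = P.shape[0]
    idx = np.arange(1, L + 1, dtype=np.float64)
    I = idx[:, None] * np.ones((1, L))
    J = np.ones((L, 1)) * idx[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sig_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))
    mu = 0.5 * (mu_x + mu_y)

    # sum distribution p_{x+y}(k), k = 2..2L; difference p_{x-y}(k), k = 0..L-1
    ksum = np.arange(2, 2 * L + 1, dtype=np.float64)
    p_sum = np.zeros(2 * L - 1)
    kdiff = np.arange(0, L, dtype=np.float64)
    p_diff = np.zeros(L)
    sums = (I + J).astype(int) - 2
    diffs = np.abs(I - J).astype(int)
    np.add.at(p_sum, sums.ravel(), P.ravel())
    np.add.at(p_diff, diffs.ravel(), P.ravel())

    HX = float(-_plogp(px).sum())
    HY = float(-_plogp(py).sum())
    HXY = float(-_plogp(P).sum())
    pxy = px[:, None] * py[None, :]
    nz = (P > 0) & (pxy > 0)
    HXY1 = float(-(P[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    HXY2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    autocorrelation = float((I * J * P).sum())
    cluster_prominence = float(((I + J - 2 * mu) ** 3 * P).sum())
    cluster_shade = float(((I + J - 2 * mu) ** 4 * P).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float((((I - mu_x) * (J - mu_y) * P).sum()) / (sig_x * sig_y))
    else:
        correlation = 0.0
    difference_entropy = float(-_plogp(p_diff).sum())
    mu_diff = float((kdiff * p_diff).sum())
    difference_variance = float(((kdiff - mu_diff) ** 2 * p_diff).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    energy = float((P**2).sum())
    entropy = HXY
    homogeneity = float((P / (1.0 + (I - J) ** 2)).sum())
    denom = max(HX, HY)
    imc1 = (HXY - HXY1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))
    inverse_difference_moment = float((P / (1.0 + np.abs(I - J))).sum())
    maximum_probability = float(P.max())
    sum_average = float((ksum * p_sum).sum())
    sum_entropy = float(-_plogp(p_sum).sum())
    sum_of_squares = float(((I - mu) ** 2 * P).sum())
    mu_sum = float((ksum * p_sum).sum())
    sum_variance = float(((ksum - mu_sum) ** 2 * p_sum).sum())
    mcc = _maximal_correlation(P, px, py, sqrt=mcc_sqrt)
    inverse_difference_normalized = float((P / (1.0 + np.abs(I - J) / L)).sum())
    inverse_difference_moment_normalized = float(
        (P / (1.0 + (I - J) ** 2 / L**2)).sum()
    )

    return np.array(
        [
            autocorrelation,
            cluster_prominence,
            cluster_shade,
            contrast,
            correlation,
            difference_entropy,
            difference_variance,
            dissimilarity,
            energy,
            entropy,
            homogeneity,
            imc1,
            imc2,
            inverse_difference_moment,
            maximum_probability,
            sum_average,
            sum_entropy,
            sum_of_squares,
            sum_variance,
            mcc,
            inverse_difference_normalized,
            inverse_difference_moment_normalized,
        ]
    )


def _maximal_correlation(P, px, py, sqrt: bool = True) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k))."""
    keep_r = px > 0
    keep_c = py > 0
    sub = P[np.ix_(keep_r, keep_c)]
    if min(sub.shape) < 2:
        return 0.0
    A = sub / px[keep_r][:, None]
    B = sub / py[keep_c][None, :]
    Q = A @ B.T
    eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
    lam2 = float(np.clip(eig[1], 0.0, 1.0))
    return float(np.sqrt(lam2)) if sqrt else lam2


def glrlm(q: np.ndarray, levels: int, theta_deg: int) -> np.ndarray:
    """Gray-level run-length matrix R[i, j-1]: runs of level i and length j.

    Runs are maximal constant-level segments along every scan line of the
    direction (rows at 0 degrees, columns at 90, anti-diagonals at 45,
    diagonals at 135).  Summing j * R[i, j-1] over all cells returns the
    pixel count: runs tile each direction's scan lines exactly once.
    """
    q = np.asarray(q)
    h, w = q.shape
    if theta_deg == 0:
        lines = [q[r, :] for r in range(h)]
    elif theta_deg == 90:
        lines = [q[:, c] for c in range(w)]
    elif theta_deg == 45:
        flipped = np.fliplr(q)
        lines = [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    elif theta_deg == 135:
        lines = [np.diagonal(q, k) for k in range(-(h - 1), w)]
    else:
        raise ValueError(f"theta must be one of {DIRECTIONS_DEG} degrees")
    max_len = max(h, w)
    R = np.zeros((levels, max_len), dtype=np.float64)
    for line in lines:
        line = np.asarray(line)
        if line.size == 0:
            continue
        # run-length encode: boundaries where the level changes
        starts = np.flatnonzero(np.r_[True, line[1:] != line[:-1]])
        lengths = np.diff(np.r_[starts, line.size])
        for lev, ln in zip(line[starts], lengths):
            R[lev, ln - 1] += 1
    return R


def glrlm_features(R: np.ndarray, n_pixels: int) -> np.ndarray:
    """The 7 run-length features (SRE, LRE, GLN, RP, RLN, LGRE, HGRE).

    Gray-level indices are 1-based in the low/high gray-level emphases;
    run percentage is (number of runs) / (number of pixels).
    """
    R = np.asarray(R, dtype=np.float64)
    n_runs = R.sum()
    if n_runs == 0:
        raise EmptyGLRLMError("run-length matrix contains no run")
    G, Rmax = R.shape
    i = np.arange(1, G + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Rmax + 1, dtype=np.float64)[None, :]
    sre = float((R / j**2).sum() / n_runs)
    lre = float((R * j**2).sum() / n_runs)
    gln = float((R.sum(axis=1) ** 2).sum() / n_runs)
    rp = float(n_runs / n_pixels)
    rln = float((R.sum(axis=0) ** 2).sum() / n_runs)
    lgre = float((R / i**2).sum() / n_runs)
    hgre = float((R * i**2).sum() / n_runs)
    return np.array([sre, lre, gln, rp, rln, lgre, hgre])


def directional_average(per_direction) -> np.ndarray:
    """Arithmetic mean of a per-direction feature set over the 4 directions."""
    if isinstance(per_direction, dict):
        missing = [t for t in DIRECTIONS_DEG if t not in per_direction]
        if missing:
            raise ValueError(f"missing directions: {missing}")
        arrs = [np.asarray(per_direction[t], float) for t in DIRECTIONS_DEG]
    else:
        arrs = [np.asarray(a, float) for a in per_direction]
        if len(arrs) != 4:
            raise ValueError("expected feature sets for exactly 4 directions")
    return np.mean(arrs, axis=0)


def _band_features(band: np.ndarray, config: FeatureConfig) -> np.ndarray:
    stats = np.array(first_order_stats(band))
    q8 = quantize(band, config.glcm_levels)
    glcm_dir = [
        glcm_features(
            glcm(
                q8,
                config.glcm_levels,
                t,
                d=config.glcm_distance,
                symmetric=config.glcm_symmetric,
            ),
            mcc_sqrt=config.mcc_sqrt,
        )
        for t in DIRECTIONS_DEG
    ]
    q16 = quantize(band, config.glrlm_levels)
    glrlm_dir = [
        glrlm_features(glrlm(q16, config.glrlm_levels, t), q16.size)
        for t in DIRECTIONS_DEG
    ]
    return np.concatenate(
        [stats, directional_average(glcm_dir), directional_average(glrlm_dir)]
    )


def extract_feature_vector(
    roi: np.ndarray, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full 136-value descriptor of one ROI: 34 features per wavelet band."""
    config = config or FeatureConfig()
    bands = dwt2_level1(roi, config.wavelet)
    parts = [_band_features(bands.as_dict()[b], config) for b in BAND_ORDER]
    return FeatureVector(values=np.concatenate(parts), names=feature_names())
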