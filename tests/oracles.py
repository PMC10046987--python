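"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over definitions, deliberately
avoiding the vectorized code paths of the package.
"""

from __future__ import annotations

import math

import numpy as np


def bilinear(img: np.ndarray, x: float, y: float) -> float:
    """Plain bilinear interpolation with edge clamping."""
    h, w = img.shape
    x = min(max(x, 0.0), w - 1.0)
    y = min(max(y, 0.0), h - 1.0)
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    return float(
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x1] * fx * (1 - fy)
        + img[y1, x0] * (1 - fx) * fy
        + img[y1, x1] * fx * fy
    )


def quad_circular_mean(img, x0, y0, r, n=8192) -> float:
    """Dense quadrature of the mean intensity along a circle."""
    img = np.asarray(img, dtype=float)
    total = 0.0
    for s in range(n):
        t = 2 * math.pi * s / n
        total += bilinear(img, x0 + r * math.sin(t), y0 - r * math.cos(t))
    return total / n


def brute_ido_search(img, centers, radii, sigma=1.0, n_samples=64):
    """Exhaustive integro-differential search with loop-level code.

    Returns the (x0, y0, r) maximizing the |smoothed radial derivative| of
    the circular mean; ties toward smaller r then row-major center.
    """
    img = np.asarray(img, dtype=float)
    radii = list(radii)
    # discrete Gaussian kernel over radius steps
    half = max(1, int(round(4 * sigma)))
    ker = np.array([math.exp(-0.5 * (k / sigma) ** 2) for k in range(-half, half + 1)])
    ker /= ker.sum()
    best = (-np.inf, None)
    for y0, x0 in centers:
        means = []
        for r in radii:
            total = 0.0
            for s in range(n_samples):
                t = 2 * math.pi * s / n_samples
                total += bilinear(img, x0 + r * math.sin(t), y0 - r * math.cos(t))
            means.append(total / n_samples)
        deriv = np.gradient(np.array(means), np.array(radii, dtype=float))
        padded = np.concatenate([[deriv[0]] * half, deriv, [deriv[-1]] * half])
        smooth = np.convolve(padded, ker, mode="valid")
        resp = np.abs(smooth)
        ri = int(np.argmax(resp))
        if resp[ri] > best[0]:
            best = (resp[ri], (x0, y0, radii[ri]))
    return best[1], best[0]


def brute_glcm(q, levels, theta_deg, d=1, symmetric=True) -> np.ndarray:
    """Pair enumeration by nested loops."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = (v * d for v in offsets[theta_deg])
    q = np.asarray(q)
    h, w = q.shape
    C = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                C[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    C[q[r2, c2], q[r, c]] += 1
    return C / C.sum()


def _entropy2(p) -> float:
    return -sum(v * math.log2(v) for v in np.asarray(p).ravel() if v > 0)


def brute_glcm_features(P) -> np.ndarray:
    """Direct loop evaluation of the 22 co-occurrence features."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    px = [P[i, :].sum() for i in range(L)]
    py = [P[:, j].sum() for j in range(L)]
    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(L)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(L)))
    mu = 0.5 * (mu_x + mu_y)
    p_sum = {k: 0.0 for k in range(2, 2 * L + 1)}
    p_diff = {k: 0.0 for k in range(L)}
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    HX, HY, HXY = _entropy2(px), _entropy2(py), _entropy2(P)
    HXY1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    HXY2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )

    def S(f):
        return sum(f(i + 1, j + 1) * P[i, j] for i in range(L) for j in range(L))

    autocorr = S(lambda a, b: a * b)
    prominence = S(lambda a, b: (a + b - 2 * mu) ** 3)
    shade = S(lambda a, b: (a + b - 2 * mu) ** 4)
    contrast = S(lambda a, b: (a - b) ** 2)
    corr = (
        S(lambda a, b: (a - mu_x) * (b - mu_y)) / (sig_x * sig_y)
        if sig_x > 0 and sig_y > 0
        else 0.0
    )
    diff_ent = _entropy2(list(p_diff.values()))
    mu_d = sum(k * v for k, v in p_diff.items())
    diff_var = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    dissim = S(lambda a, b: abs(a - b))
    energy = float((P**2).sum())
    homog = S(lambda a, b: 1.0 / (1 + (a - b) ** 2))
    imc1 = (HXY - HXY1) / max(HX, HY) if max(HX, HY) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (HXY2 - HXY))))
    idm = S(lambda a, b: 1.0 / (1 + abs(a - b)))
    maxp = float(P.max())
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_ent = _entropy2(list(p_sum.values()))
    sos = S(lambda a, b: (a - mu) ** 2)
    mu_s = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - mu_s) ** 2 * v for k, v in p_sum.items())
    # maximal correlation coefficient via Haralick's Q on non-degenerate levels
    keep = [i for i in range(L) if px[i] > 0 and py[i] > 0]
    if len(keep) < 2:
        mcc = 0.0
    else:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in keep if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(min(max(eig[1], 0.0), 1.0))
    idn = S(lambda a, b: 1.0 / (1 + abs(a - b) / L))
    idmn = S(lambda a, b: 1.0 / (1 + (a - b) ** 2 / L**2))
    return np.array(
        [autocorr, prominence, shade, contrast, corr, diff_ent, diff_var, dissim,
         energy, HXY, homog, imc1, imc2, idm, maxp, sum_avg, sum_ent, sos,
         sum_var, mcc, idn, idmn]
    )


def brute_glrlm(q, levels, theta_deg) -> np.ndarray:
    """Run enumeration by walking every scan line element-wise."""
    q = np.asarray(q)
    h, w = q.shape
    if theta_deg == 0:
        lines = [list(q[r, :]) for r in range(h)]
    elif theta_deg == 90:
        lines = [list(q[:, c]) for c in range(w)]
    elif theta_deg == 45:
        lines = []
        for s in range(h + w - 1):  # r + c = s, ascending c
            lines.append([q[r, c] for c in range(w) for r in range(h) if r + c == s])
    elif theta_deg == 135:
        lines = []
        for dgap in range(-(h - 1), w):  # c - r = dgap
            lines.append([q[r, c] for c in range(w) for r in range(h) if c - r == dgap])
    R = np.zeros((levels, max(h, w)))
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            R[line[i], j - i] += 1
            i = j + 1
    return R


def brute_glrlm_features(R, n_pixels) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    G, M = R.shape
    n_runs = R.sum()
    sre = sum(R[i, j] / (j + 1) ** 2 for i in range(G) for j in range(M)) / n_runs
    lre = sum(R[i, j] * (j + 1) ** 2 for i in range(G) for j in range(M)) / n_runs
    gln = sum(R[i, :].sum() ** 2 for i in range(G)) / n_runs
    rp = n_runs / n_pixels
    rln = sum(R[:, j].sum() ** 2 for j in range(M)) / n_runs
    lgre = sum(R[i, j] / (i + 1) ** 2 for i in range(G) for j in range(M)) / n_runs
    hgre = sum(R[i, j] * (i + 1) ** 2 for i in range(G) for j in range(M)) / n_runs
    return np.array([sre, lre, gln, rp, rln, lgre, hgre])


def pair_count_auc(y_true, scores) -> float:
    """AUC as the fraction of correctly ordered positive-negative pairs."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = len(pos) * len(neg)
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / total


def brute_relieff(X, y, k) -> np.ndarray:
    """Quadratic-time two-class ReliefF on min-max scaled features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    S = (X - lo) / span
    w = np.zeros(p)
    for i in range(n):
        dists = [(sum(abs(S[i] - S[j])), j) for j in range(n) if j != i]
        hits = sorted((d, j) for d, j in dists if y[j] == y[i])[:k]
        misses = sorted((d, j) for d, j in dists if y[j] != y[i])[:k]
        for _, j in misses:
            w += np.abs(S[i] - S[j])
        for _, j in hits:
            w -= np.abs(S[i] - S[j])
    return w / (n * k)
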