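"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain double loops directly from the
defining formulas, deliberately sharing no code with the package, so the
vectorized implementations can be checked against them on small inputs.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(quantized, angle, distance=1, levels=8, symmetric=True, normalized=True):
    """Pair enumeration co-occurrence matrix; values 1..levels, 0 = ignore."""
    q = np.asarray(quantized)
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    M = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] > 0 and q[r2, c2] > 0:
                M[q[r, c] - 1, q[r2, c2] - 1] += 1
    if symmetric:
        M = M + M.T
    if normalized and M.sum() > 0:
        M = M / M.sum()
    return M


def brute_glcm_statistics(P):
    """All 36 co-occurrence statistics by explicit summation loops."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]

    def val(i):  # gray value of index i
        return i + 1

    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum(val(i) * px[i] for i in range(L))
    mu_y = sum(val(j) * py[j] for j in range(L))
    sig_x = math.sqrt(sum((val(i) - mu_x) ** 2 * px[i] for i in range(L)))
    sig_y = math.sqrt(sum((val(j) - mu_y) ** 2 * py[j] for j in range(L)))

    p_sum = {k: 0.0 for k in range(2, 2 * L + 1)}
    p_diff = {k: 0.0 for k in range(0, L)}
    for i in range(L):
        for j in range(L):
            p_sum[val(i) + val(j)] += P[i][j]
            p_diff[abs(val(i) - val(j))] += P[i][j]

    def ent(ps, log):
        return -sum(p * log(p) for p in ps if p > 0)

    entropy = ent(P.ravel(), math.log2)
    hx = ent(px, math.log2)
    hy = ent(py, math.log2)
    hxy1 = -sum(P[i][j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L) if P[i][j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    hxy_ln = ent(P.ravel(), math.log)

    autocorr = sum(val(i) * val(j) * P[i][j] for i in range(L) for j in range(L))
    sum_avg = sum(k * p for k, p in p_sum.items())
    diff_avg = sum(k * p for k, p in p_diff.items())
    denom = max(hx, hy)
    mean_p = float(np.mean(P))
    std_p = float(np.std(P))
    corr = 0.0
    if sig_x > 1e-12 and sig_y > 1e-12:
        corr = (autocorr - mu_x * mu_y) / (sig_x * sig_y)

    return {
        "Autocorrelation": autocorr,
        "Contrast": sum((val(i) - val(j)) ** 2 * P[i][j]
                        for i in range(L) for j in range(L)),
        "Correlation": corr,
        "Cluster prominence": sum((val(i) + val(j) - mu_x - mu_y) ** 4 * P[i][j]
                                  for i in range(L) for j in range(L)),
        "Cluster shade": sum((val(i) + val(j) - mu_x - mu_y) ** 3 * P[i][j]
                             for i in range(L) for j in range(L)),
        "Cluster tendency": sum((val(i) + val(j) - mu_x - mu_y) ** 2 * P[i][j]
                                for i in range(L) for j in range(L)),
        "Dissimilarity": sum(abs(val(i) - val(j)) * P[i][j]
                             for i in range(L) for j in range(L)),
        "Energy": sum(P[i][j] ** 2 for i in range(L) for j in range(L)),
        "Entropy": entropy,
        "Homogeneity": sum(P[i][j] / (1 + (val(i) - val(j)) ** 2)
                           for i in range(L) for j in range(L)),
        "Inverse Difference": sum(P[i][j] / (1 + abs(val(i) - val(j)))
                                  for i in range(L) for j in range(L)),
        "Inverse difference normalized": sum(
            P[i][j] / (1 + abs(val(i) - val(j)) / L)
            for i in range(L) for j in range(L)),
        "Inverse difference moment normalized": sum(
            P[i][j] / (1 + (val(i) - val(j)) ** 2 / L ** 2)
            for i in range(L) for j in range(L)),
        "Maximum probability": max(P[i][j] for i in range(L) for j in range(L)),
        "Sum of squares variance": sum((val(i) - mu_x) ** 2 * P[i][j]
                                       for i in range(L) for j in range(L)),
        "Sum average": sum_avg,
        "Sum variance": sum((k - sum_avg) ** 2 * p for k, p in p_sum.items()),
        "Sum entropy": ent(p_sum.values(), math.log2),
        "Difference average": diff_avg,
        "Difference variance": sum((k - diff_avg) ** 2 * p for k, p in p_diff.items()),
        "Difference entropy": ent(p_diff.values(), math.log),
        "Information measure of correlation":
            (entropy - hxy1) / denom if denom > 1e-12 else 0.0,
        "Information measure of correlation 2":
            math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy_ln)))),
        "Coefficient of variation": std_p / mean_p if mean_p > 1e-12 else 0.0,
        "Marginal mean x": mu_x,
        "Marginal mean y": mu_y,
        "Marginal std x": sig_x,
        "Marginal std y": sig_y,
        "Marginal entropy x": hx,
        "Marginal entropy y": hy,
        "Marginal energy x": sum(p ** 2 for p in px),
        "Diagonal probability": sum(P[i][i] for i in range(L)),
        "Maximum marginal probability": max(px),
        "HXY1": hxy1,
        "HXY2": hxy2,
        "Joint entropy ln": hxy_ln,
    }


def brute_histogram_features(vals):
    vals = np.asarray(vals, dtype=float).ravel()
    counts = [0] * 256
    for v in vals:
        counts[min(255, int(v))] += 1
    n = len(vals)
    entropy = -sum((c / n) * math.log2(c / n) for c in counts if c > 0)
    scaled = vals / 255.0
    mean = sum(scaled) / n
    var = sum((s - mean) ** 2 for s in scaled) / n
    return {"Histogram entropy": entropy, "Smoothness": 1.0 - 1.0 / (1.0 + var)}


def brute_closing(mask, radius):
    """Dilate then erode by direct set shifts with a disk element."""
    mask = np.asarray(mask, dtype=bool)
    offs = [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]
    h, w = mask.shape

    def shifted_any(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                if any(0 <= r + dr < h and 0 <= c + dc < w and m[r + dr, c + dc]
                       for dr, dc in offs):
                    out[r, c] = True
        return out

    def shifted_all(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                # outside the frame counts as foreground for the erosion
                # half of a closing, so borders do not erode artificially
                out[r, c] = all(
                    m[r + dr, c + dc]
                    if (0 <= r + dr < h and 0 <= c + dc < w) else True
                    for dr, dc in offs)
        return out

    return shifted_all(shifted_any(mask))


def brute_knn(X_train, y_train, x, k, classes=(1, 2, 3)):
    """Exhaustive-distance KNN with the package's documented tie policy."""
    dists = sorted((math.dist(row, x), y) for row, y in zip(X_train, y_train))
    nearest = dists[:k]
    votes = {c: sum(1 for _, y in nearest if y == c) for c in classes}
    top = max(votes.values())
    tied = [c for c in classes if votes[c] == top]
    if len(tied) > 1:
        means = {c: np.mean([d for d, y in nearest if y == c]) for c in tied}
        lo = min(means.values())
        tied = [c for c in tied if means[c] == lo]
    return min(tied)


def auc_by_pairs(scores, positives):
    """AUC as the fraction of correctly ordered positive/negative pairs."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0
               for sp in pos for sn in neg)
    return wins / (len(pos) * len(neg))


def brute_hu_moments(mask):
    """Hu's seven invariants from explicit moment summation loops."""
    mask = np.asarray(mask, dtype=float)
    h, w = mask.shape

    def m(p, q):
        return sum(mask[r, c] * (r ** p) * (c ** q)
                   for r in range(h) for c in range(w))

    m00 = m(0, 0)
    cr, cc = m(1, 0) / m00, m(0, 1) / m00

    def mu(p, q):
        return sum(mask[r, c] * ((r - cr) ** p) * ((c - cc) ** q)
                   for r in range(h) for c in range(w))

    def nu(p, q):
        return mu(p, q) / (m00 ** (1 + (p + q) / 2.0))

    n20, n02, n11 = nu(2, 0), nu(0, 2), nu(1, 1)
    n30, n03, n21, n12 = nu(3, 0), nu(0, 3), nu(2, 1), nu(1, 2)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11 ** 2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = ((n30 - 3 * n12) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          + (3 * n21 - n03) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    h6 = ((n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
          + 4 * n11 * (n30 + n12) * (n21 + n03))
    h7 = ((3 * n21 - n03) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          - (n30 - 3 * n12) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    return [h1, h2, h3, h4, h5, h6, h7]
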