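"""Gray-level co-occurrence texture and histogram features.

The co-occurrence matrix N_g(i, j) counts how often gray levels i and j
occur at a fixed displacement (distance d, orientation theta), restricted
to pixels inside the object mask. Matrices are symmetrized and normalized
to sum 1. Gray values are quantized to ``levels`` bins over the object's
own intensity range and indexed 1..levels, so e.g. the autocorrelation of
a single co-occurrence at gray values (2, 3) is 6.

36 statistics are computed per matrix; with the four standard orientations
(0, 45, 90, 135 degrees) this gives the 144-entry GLCM block. Entropy and
the marginal entropies use base-2 logarithms; difference entropy and the
HXY terms of the information measures use natural logarithms (following
the printed conventions of the formulas this block reproduces; the
information measure of correlation therefore mixes bases, which is kept
as-is and mirrored by the test oracles).

Two histogram features (gray-level entropy in bits and the smoothness
measure 1 - 1/(1 + sigma^2) on [0,1]-scaled gray) complete the 146-entry
texture block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ANGLES = (0, 45, 90, 135)
# (row, col) displacement per orientation at unit distance
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_EPS = 1e-12


class DegeneratePatchError(ValueError):
    """Raised when a patch yields no valid co-occurring pixel pairs."""


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 8
    distance: int = 1
    angle: int = 0
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.angle not in ANGLES:
            raise ValueError(f"angle must be one of {ANGLES}")


def quantize(gray: np.ndarray, levels: int = 8, mask: np.ndarray | None = None) -> np.ndarray:
    """Quantize gray values to integer levels 1..levels over the masked range.

    Pixels outside the mask are set to 0 (excluded from pairing).
    """
    gray = np.asarray(gray, dtype=float)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    vals = gray[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < _EPS:
        q = np.ones(gray.shape, dtype=np.int64)
    else:
        q = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int64) + 1
        q = np.clip(q, 1, levels)
    q[~mask] = 0
    return q


def compute_glcm(
    quantized: np.ndarray,
    config: GLCMConfig | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Co-occurrence matrix of a quantized patch (values 1..levels, 0 = ignore).

    Returns a (levels, levels) float matrix; row/column index k corresponds
    to gray value k+1. Symmetrized and normalized per the config.
    """
    config = config or GLCMConfig()
    q = np.asarray(quantized, dtype=np.int64)
    if q.ndim != 2:
        raise ValueError("expected a 2-D quantized patch")
    valid = q > 0
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    dr, dc = _OFFSETS[config.angle]
    dr, dc = dr * config.distance, dc * config.distance
    h, w = q.shape

    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    if r0s >= r0e or c0s >= c0e:
        raise DegeneratePatchError("patch smaller than the requested offset")
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    va = valid[r0s:r0e, c0s:c0e]
    vb = valid[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    pair_ok = va & vb
    if not pair_ok.any():
        raise DegeneratePatchError("no valid co-occurring pairs in patch")

    L = config.levels
    glcm = np.zeros((L, L), dtype=float)
    np.add.at(glcm, (a[pair_ok] - 1, b[pair_ok] - 1), 1.0)
    if config.symmetric:
        glcm = glcm + glcm.T
    if config.normalized:
        glcm /= glcm.sum()
    return glcm


# ordered names of the 36 per-matrix statistics
GLCM_STAT_NAMES = (
    "Autocorrelation",
    "Contrast",
    "Correlation",
    "Cluster prominence",
    "Cluster shade",
    "Cluster tendency",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "Inverse Difference",
    "Inverse difference normalized",
    "Inverse difference moment normalized",
    "Maximum probability",
    "Sum of squares variance",
    "Sum average",
    "Sum variance",
    "Sum entropy",
    "Difference average",
    "Difference variance",
    "Difference entropy",
    "Information measure of correlation",
    "Information measure of correlation 2",
    "Coefficient of variation",
    "Marginal mean x",
    "Marginal mean y",
    "Marginal std x",
    "Marginal std y",
    "Marginal entropy x",
    "Marginal entropy y",
    "Marginal energy x",
    "Diagonal probability",
    "Maximum marginal probability",
    "HXY1",
    "HXY2",
    "Joint entropy ln",
)


def _entropy(p: np.ndarray, log=np.log2) -> float:
    p = p[p > 0]
    return float(-np.sum(p * log(p)))


def glcm_statistics(glcm: np.ndarray) -> dict[str, float]:
    """The 36 texture statistics of one normalized co-occurrence matrix."""
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("expected a square GLCM")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized to sum 1")
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    ks_sum = np.arange(2, 2 * L + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ks_sum])
    ks_diff = np.arange(0, L, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in ks_diff])

    autocorr = float(np.sum(ii * jj * p))
    entropy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    pxy_outer = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-np.sum(p[nz] * np.log(pxy_outer[nz])))
    nz_o = pxy_outer > 0
    hxy2 = float(-np.sum(pxy_outer[nz_o] * np.log(pxy_outer[nz_o])))
    hxy_ln = _entropy(p.ravel(), log=np.log)

    sum_avg = float(np.sum(ks_sum * p_sum))
    diff_avg = float(np.sum(ks_diff * p_diff))
    denom = max(hx, hy)
    imc = (entropy - hxy1) / denom if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy_ln)))))
    mean_p = float(p.mean())
    cov = float(p.std() / mean_p) if mean_p > _EPS else 0.0
    corr = ((autocorr - mu_x * mu_y) / (sig_x * sig_y)
            if sig_x > _EPS and sig_y > _EPS else 0.0)

    return {
        "Autocorrelation": autocorr,
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(corr),
        "Cluster prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "Cluster shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "Cluster tendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "Energy": float(np.sum(p ** 2)),
        "Entropy": entropy,
        "Homogeneity": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Inverse Difference": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Inverse difference normalized": float(np.sum(p / (1.0 + np.abs(ii - jj) / L))),
        "Inverse difference moment normalized": float(np.sum(p / (1.0 + (ii - jj) ** 2 / L ** 2))),
        "Maximum probability": float(p.max()),
        "Sum of squares variance": float(np.sum((ii - mu_x) ** 2 * p)),
        "Sum average": sum_avg,
        "Sum variance": float(np.sum((ks_sum - sum_avg) ** 2 * p_sum)),
        "Sum entropy": _entropy(p_sum),
        "Difference average": diff_avg,
        "Difference variance": float(np.sum((ks_diff - diff_avg) ** 2 * p_diff)),
        "Difference entropy": _entropy(p_diff, log=np.log),
        "Information measure of correlation": float(imc),
        "Information measure of correlation 2": imc2,
        "Coefficient of variation": cov,
        "Marginal mean x": mu_x,
        "Marginal mean y": mu_y,
        "Marginal std x": sig_x,
        "Marginal std y": sig_y,
        "Marginal entropy x": hx,
        "Marginal entropy y": hy,
        "Marginal energy x": float(np.sum(px ** 2)),
        "Diagonal probability": float(np.trace(p)),
        "Maximum marginal probability": float(px.max()),
        "HXY1": hxy1,
        "HXY2": hxy2,
        "Joint entropy ln": hxy_ln,
    }


def histogram_features(gray: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    """Gray histogram entropy (bits) and smoothness 1 - 1/(1 + sigma^2).

    ``gray`` is an 8-bit-scale gray image or pixel vector; smoothness uses
    the variance of gray rescaled to [0, 1].
    """
    gray = np.asarray(gray, dtype=float)
    vals = gray[np.asarray(mask, dtype=bool)] if mask is not None else gray.ravel()
    if vals.size == 0:
        raise ValueError("no pixels")
    counts, _ = np.histogram(vals, bins=256, range=(0.0, 256.0))
    probs = counts / counts.sum()
    var01 = float(np.var(vals / 255.0))
    return {
        "Histogram entropy": _entropy(probs),
        "Smoothness": 1.0 - 1.0 / (1.0 + var01),
    }


def texture_feature_names() -> list[str]:
    """The 144 GLCM feature names (angle-major blocks) in registry order."""
    return [f"{stat}-{ang}" for ang in ANGLES for stat in GLCM_STAT_NAMES]


def texture_features(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 8,
    distance: int = 1,
) -> dict[str, float]:
    """All 144 GLCM statistics of a gray patch over the four orientations."""
    q = quantize(gray, levels=levels, mask=mask)
    feats: dict[str, float] = {}
    for ang in ANGLES:
        cfg = GLCMConfig(levels=levels, distance=distance, angle=ang)
        try:
            glcm = compute_glcm(q, cfg)
            stats = glcm_statistics(glcm)
        except DegeneratePatchError:
            stats = {nm: 0.0 for nm in GLCM_STAT_NAMES}
        for nm, v in stats.items():
            feats[f"{nm}-{ang}"] = v
    return feats
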