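"""Color-space conversions and the 127-entry color feature block.

Six color spaces are used: RGB, HSI, HSV, YIQ, CMY and YCbCr. Per-channel
first-order statistics (mean, standard deviation, skewness and, for RGB,
kurtosis and range) are combined with normalized chromaticities and
vegetation indices. Vegetation indices in RGB follow the standard
chromaticity forms, e.g.

    ExG  = 2 Gn - Rn - Bn
    CIVE = 0.441 Rn - 0.811 Gn + 0.385 Bn + 18.78

with Rn = R/(R+G+B) etc. Channel-excess indices in the other five spaces
(e.g. ExY-YIQ, ExM-CMY) are reconstructions: each space's channels are
first rescaled to [0, 1] by their nominal ranges, then the excess of
channel i is 2*c_i - c_j - c_k. CIVE applied to those rescaled channels
gives the CIVE-<space> variants (CIVE-HSV among them).

Hue is reported in degrees [0, 360). YCbCr uses the digital range
(Y in [16, 235], Cb/Cr in [16, 240]) as produced by scikit-image.
"""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor

COLOR_SPACES = ("RGB", "HSI", "HSV", "YIQ", "CMY", "YCbCr")

# channel display names per space, used by the registry
CHANNEL_NAMES = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H-HSV", "S-HSV", "V-HSV"),
    "HSI": ("H-HSI", "S-HSI", "I-HSI"),
    "YIQ": ("Y-YIQ", "I-YIQ", "Q-YIQ"),
    "CMY": ("C-CMY", "M-CMY", "Y-CMY"),
    "YCbCr": ("Y-YCbCr", "Cb", "Cr"),
}

# nominal (lo, hi) per channel, for rescaling to [0,1] in excess/CIVE indices
_CHANNEL_RANGES = {
    "HSV": ((0, 360), (0, 1), (0, 1)),
    "HSI": ((0, 360), (0, 1), (0, 1)),
    "YIQ": ((0, 1), (-0.5957, 0.5957), (-0.5226, 0.5226)),
    "CMY": ((0, 1), (0, 1), (0, 1)),
    "YCbCr": ((16, 235), (16, 240), (16, 240)),
}

_EPS = 1e-12


def _rgb_to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Classic HSI conversion; hue in degrees, S = 1 - min/intensity."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = (r + g + b) / 3.0
    minimum = np.minimum(np.minimum(r, g), b)
    sat = np.where(intensity > _EPS, 1.0 - minimum / np.maximum(intensity, _EPS), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.degrees(np.arccos(np.clip(num / np.maximum(den, _EPS), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(sat <= _EPS, 0.0, hue) % 360.0
    return np.stack([hue, sat, intensity], axis=-1)


def convert_color(frame01: np.ndarray, space: str) -> np.ndarray:
    """Convert an RGB image scaled to [0, 1] into the requested space.

    Returns a float image with the same spatial shape and 3 channels.
    """
    frame01 = np.asarray(frame01, dtype=float)
    if frame01.ndim != 3 or frame01.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image in [0, 1]")
    if space == "RGB":
        return frame01.copy()
    if space == "HSV":
        hsv = skcolor.rgb2hsv(frame01)
        hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
        return hsv
    if space == "HSI":
        return _rgb_to_hsi(frame01)
    if space == "YIQ":
        return skcolor.rgb2yiq(frame01)
    if space == "CMY":
        return 1.0 - frame01
    if space == "YCbCr":
        return skcolor.rgb2ycbcr(frame01)
    raise ValueError(f"unknown color space: {space!r}")


def _skew(x: np.ndarray) -> float:
    s = np.std(x)
    if s < _EPS:
        return 0.0
    return float(np.mean(((x - np.mean(x)) / s) ** 3))


def _kurt(x: np.ndarray) -> float:
    s = np.std(x)
    if s < _EPS:
        return 0.0
    return float(np.mean(((x - np.mean(x)) / s) ** 4) - 3.0)


# RGB vegetation indices on chromaticities (rn, gn, bn) and raw channels
def _rgb_indices(r, g, b):
    tot = np.maximum(r + g + b, _EPS)
    rn, gn, bn = r / tot, g / tot, b / tot
    exg = 2 * gn - rn - bn
    exr = 1.4 * rn - gn
    exb = 1.4 * bn - gn
    return {
        "ExG-RGB": exg,
        "ExR-RGB": exr,
        "ExB-RGB": exb,
        "ExGR-RGB": exg - exr,
        "CIVE-RGB": 0.441 * rn - 0.811 * gn + 0.385 * bn + 18.78,
        "NDI-RGB": (g - r) / np.maximum(g + r, _EPS),
        "VEG-RGB": g / np.maximum(np.power(np.maximum(r, _EPS), 0.667)
                                  * np.power(np.maximum(b, _EPS), 0.333), _EPS),
        "MExG-RGB": 1.262 * gn - 0.884 * rn - 0.311 * bn,
        "GLI-RGB": (2 * g - r - b) / np.maximum(2 * g + r + b, _EPS),
        "RGRI-RGB": r / np.maximum(g, _EPS),
    }, (rn, gn, bn)


RGB_INDEX_NAMES = ("ExG-RGB", "ExR-RGB", "ExB-RGB", "ExGR-RGB", "CIVE-RGB",
                   "NDI-RGB", "VEG-RGB", "MExG-RGB", "GLI-RGB", "RGRI-RGB")

# excess-channel feature names for the five non-RGB spaces, in channel order
EXCESS_NAMES = {
    "YIQ": ("EXY-YIQ", "ExI-YIQ", "ExQ-YIQ"),
    "HSV": ("ExH-HSV", "ExS-HSV", "ExV-HSV"),
    "HSI": ("ExH-HSI", "ExS-HSI", "ExI-HSI"),
    "CMY": ("ExC-CMY", "ExM-CMY", "ExY-CMY"),
    "YCbCr": ("ExY-YCbCr", "ExCb-YCbCr", "ExCr-YCbCr"),
}
EXCESS_SPACES = ("YIQ", "HSV", "HSI", "CMY", "YCbCr")


def color_feature_names() -> list[str]:
    """The 127 color feature names, in registry order."""
    names: list[str] = []
    channels = [ch for sp in COLOR_SPACES for ch in CHANNEL_NAMES[sp]]
    for ch in channels:
        names += [f"Mean-{ch}", f"Std-{ch}"]
    names += [f"Skew-{ch}" for ch in channels]
    names += ["Rn", "Gn", "Bn", "Std-Rn", "Std-Gn", "Std-Bn"]
    for idx in RGB_INDEX_NAMES:
        names += [idx, f"Std-{idx}"]
    for sp in EXCESS_SPACES:
        for nm in EXCESS_NAMES[sp]:
            names += [nm, f"Std-{nm}"]
    for sp in EXCESS_SPACES:
        names += [f"CIVE-{sp}", f"Std-CIVE-{sp}"]
    names += ["Kurt-R", "Kurt-G", "Kurt-B", "Range-R", "Range-G", "Range-B",
              "Mean-Gray"]
    assert len(names) == 127
    return names


def color_features(pixels: np.ndarray) -> dict[str, float]:
    """127 color features of one object.

    Parameters
    ----------
    pixels
        (n, 3) array of the object's RGB pixel values in 8-bit [0, 255].
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3 or pixels.shape[0] == 0:
        raise ValueError("expected a non-empty (n, 3) RGB pixel array")
    px01 = pixels / 255.0
    img = px01[np.newaxis, :, :]  # (1, n, 3) so image converters apply

    feats: dict[str, float] = {}
    space_px = {}
    for sp in COLOR_SPACES:
        conv = convert_color(img, sp)[0]
        space_px[sp] = conv
        for k, ch in enumerate(CHANNEL_NAMES[sp]):
            vals = conv[:, k]
            feats[f"Mean-{ch}"] = float(np.mean(vals))
            feats[f"Std-{ch}"] = float(np.std(vals))
    for sp in COLOR_SPACES:
        for k, ch in enumerate(CHANNEL_NAMES[sp]):
            feats[f"Skew-{ch}"] = _skew(space_px[sp][:, k])

    r, g, b = px01[:, 0], px01[:, 1], px01[:, 2]
    idx_imgs, (rn, gn, bn) = _rgb_indices(r, g, b)
    for nm, vals in zip(("Rn", "Gn", "Bn"), (rn, gn, bn)):
        feats[nm] = float(np.mean(vals))
        feats[f"Std-{nm}"] = float(np.std(vals))
    for nm in RGB_INDEX_NAMES:
        feats[nm] = float(np.mean(idx_imgs[nm]))
        feats[f"Std-{nm}"] = float(np.std(idx_imgs[nm]))

    for sp in EXCESS_SPACES:
        conv = space_px[sp]
        scaled = np.empty_like(conv)
        for k, (lo, hi) in enumerate(_CHANNEL_RANGES[sp]):
            scaled[:, k] = (conv[:, k] - lo) / (hi - lo)
        for k, nm in enumerate(EXCESS_NAMES[sp]):
            others = [j for j in range(3) if j != k]
            excess = 2 * scaled[:, k] - scaled[:, others[0]] - scaled[:, others[1]]
            feats[nm] = float(np.mean(excess))
            feats[f"Std-{nm}"] = float(np.std(excess))
        cive = (0.441 * scaled[:, 0] - 0.811 * scaled[:, 1]
                + 0.385 * scaled[:, 2] + 18.78)
        feats[f"CIVE-{sp}"] = float(np.mean(cive))
        feats[f"Std-CIVE-{sp}"] = float(np.std(cive))

    for nm, vals in zip(("R", "G", "B"), (r, g, b)):
        feats[f"Kurt-{nm}"] = _kurt(vals)
        feats[f"Range-{nm}"] = float(np.max(vals) - np.min(vals))
    feats["Mean-Gray"] = float(np.mean(0.299 * r + 0.587 * g + 0.114 * b))
    return feats
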