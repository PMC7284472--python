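"""Synthetic paddy-scene and feature-table generators.

Every downstream stage (segmentation, feature extraction, stereo fusion,
selection, classification) is testable without field recordings via two
generators:

``generate_scene``
    Renders a paired left/right RGB frame of three plant classes on a
    soil background. Rice (class 1) and narrow-leaf weeds (class 2) are
    thin elongated super-ellipses that differ in hue and in the spatial
    frequency of a brightness stripe pattern along the leaf — making them
    the confusable pair — while wide-leaf weeds (class 3) are broad
    ellipses. The right frame is the same scene with every object shifted
    horizontally by a fixed disparity and independent photometric noise.
    By construction every rendered plant pixel satisfies the
    green-dominance segmentation rule (G > R, G > B, G >= threshold) and
    every soil pixel violates it, so segmentation ground truth is exact.

``generate_feature_table``
    Draws a labeled Gaussian feature table in which only designated
    informative columns carry class signal (class-conditional means
    separated by ``class_sep`` within-class standard deviations); noise
    columns are label-independent. Used as the oracle harness for the
    wrapper feature selector.

All outputs are fully determined by the integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .tables import FeatureTable

GREEN_THRESHOLD = 140  # the segmentation rule the renderer guarantees


class PlacementError(RuntimeError):
    """Frame too small (or too crowded) to place the requested objects."""


@dataclass(frozen=True)
class ClassAppearance:
    """Appearance distribution of one plant class."""

    base_rgb: tuple[int, int, int]
    length_px: tuple[int, int]        # (lo, hi) of the major axis
    width_px: tuple[int, int]         # (lo, hi) of the minor axis
    stripe_frequency: float           # cycles / px along the leaf
    stripe_amplitude: float = 0.15
    squareness: float = 2.0           # super-ellipse exponent


DEFAULT_APPEARANCE = {
    1: ClassAppearance((70, 195, 60), (60, 90), (8, 12), 0.05),    # rice
    2: ClassAppearance((110, 205, 50), (60, 90), (8, 12), 0.18),   # narrow-leaf
    3: ClassAppearance((45, 170, 75), (42, 56), (26, 38), 0.03,    # wide-leaf
                       squareness=2.0),
}


@dataclass(frozen=True)
class SceneConfig:
    frame_size: tuple[int, int] = (480, 640)          # (H, W)
    n_objects_per_class: tuple[int, int, int] = (4, 4, 4)
    disparity_px: int = 12
    photometric_noise_sd: float = 3.0
    seed: int = 0
    class_appearance: dict = field(default_factory=lambda: dict(DEFAULT_APPEARANCE))
    margin_px: int = 4                                # min gap between objects
    allow_overlap: bool = False

    def __post_init__(self):
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame_size must be positive")
        if self.disparity_px < 0:
            raise ValueError("disparity_px must be >= 0")
        if any(n < 0 for n in self.n_objects_per_class):
            raise ValueError("object counts must be >= 0")


@dataclass
class GroundTruth:
    """Left-frame label mask and per-object records."""

    label_mask: np.ndarray                       # H x W ints in {0,1,2,3}
    objects: list[dict]                          # class_label, bbox, centroid

    def to_json(self, path) -> None:
        payload = [{"class_label": o["class_label"],
                    "bbox": list(o["bbox"]),
                    "centroid": list(o["centroid"])} for o in self.objects]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _leaf_mask(rng: np.random.Generator, app: ClassAppearance) -> np.ndarray:
    """Boolean mask of one rotated super-elliptic leaf, plus stripe phase."""
    length = rng.integers(app.length_px[0], app.length_px[1] + 1)
    width = rng.integers(app.width_px[0], app.width_px[1] + 1)
    theta = rng.uniform(0, np.pi)
    a, b = length / 2.0, width / 2.0
    half = int(np.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    u = xx * np.cos(theta) + yy * np.sin(theta)      # along the leaf
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    n = app.squareness
    mask = (np.abs(u / a) ** n + np.abs(v / b) ** n) <= 1.0
    # crop to tight bbox
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return mask[r0:r1 + 1, c0:c1 + 1], u[r0:r1 + 1, c0:c1 + 1]


def _render(frames_shape, placed, noise, thresh=GREEN_THRESHOLD):
    """Compose objects on soil, add noise, then enforce the rule exactly."""
    h, w = frames_shape
    frame = np.empty((h, w, 3), dtype=float)
    frame[..., 0] = 115.0
    frame[..., 1] = 95.0
    frame[..., 2] = 70.0
    label = np.zeros((h, w), dtype=np.uint8)
    for obj in placed:
        m, stripe, (r0, c0), cls, rgb, amp, freq = obj
        mod = 1.0 + amp * np.sin(2.0 * np.pi * freq * stripe)
        sl = (slice(r0, r0 + m.shape[0]), slice(c0, c0 + m.shape[1]))
        for ch in range(3):
            sub = frame[sl + (ch,)]
            sub[m] = rgb[ch] * mod[m]
        label[sl][m] = cls
    frame += noise
    frame = np.clip(frame, 0, 255)
    plant = label > 0
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    # plant interiors must satisfy the rule; soil must violate it
    r[plant] = np.minimum(r[plant], 253.0)
    b[plant] = np.minimum(b[plant], 253.0)
    g[plant] = np.maximum.reduce(
        [g[plant], np.full(plant.sum(), float(thresh)), r[plant] + 1, b[plant] + 1])
    g = np.minimum(g, 255.0)
    frame[..., 1] = g
    soil = ~plant
    frame[..., 0][soil] = np.maximum(r[soil], frame[..., 1][soil])
    return np.round(frame).astype(np.uint8), label


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a stereo frame pair and its ground truth."""
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_size
    d = config.disparity_px
    occupancy = np.zeros((h, w), dtype=bool)
    placed = []
    records = []
    for cls in (1, 2, 3):
        app = config.class_appearance[cls]
        for _ in range(config.n_objects_per_class[cls - 1]):
            for attempt in range(200):
                m, stripe = _leaf_mask(rng, app)
                mh, mw = m.shape
                gap = config.margin_px
                if h - mh - 2 * gap <= 0 or w - mw - d - 2 * gap <= 0:
                    raise PlacementError(
                        f"frame {h}x{w} too small for a {mh}x{mw} object "
                        f"with disparity {d}")
                r0 = int(rng.integers(gap, h - mh - gap))
                c0 = int(rng.integers(gap, w - mw - d - gap))
                region = occupancy[max(0, r0 - gap):r0 + mh + gap,
                                   max(0, c0 - gap):c0 + mw + d + gap]
                if config.allow_overlap or not region.any():
                    break
            else:
                raise PlacementError("could not place object without overlap")
            occupancy[r0:r0 + mh, c0:c0 + mw + d] = True
            jitter = rng.normal(0, 4, size=3)
            rgb = np.clip(np.array(app.base_rgb, dtype=float) + jitter, 0, 255)
            placed.append((m, stripe, (r0, c0), cls, rgb,
                           app.stripe_amplitude, app.stripe_frequency))
            ys, xs = np.nonzero(m)
            records.append({
                "class_label": cls,
                "bbox": (r0, c0, r0 + mh, c0 + mw),
                "centroid": (r0 + float(ys.mean()), c0 + float(xs.mean())),
            })
    noise_l = rng.normal(0, config.photometric_noise_sd, size=(h, w, 3))
    noise_r = rng.normal(0, config.photometric_noise_sd, size=(h, w, 3))
    left, label_mask = _render((h, w), placed, noise_l)
    placed_r = [(m, s, (r0, c0 + d), cls, rgb, amp, fr)
                for (m, s, (r0, c0), cls, rgb, amp, fr) in placed]
    right, _ = _render((h, w), placed_r, noise_r)
    return left, right, GroundTruth(label_mask, records)


def save_scene(out_dir, left, right, truth: GroundTruth, frame_id: str = "scene") -> None:
    """Write the pair as PNG, the label mask as 16-bit PNG, truth as JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{frame_id}_L.png", left)
    iio.imwrite(out / f"{frame_id}_R.png", right)
    iio.imwrite(out / f"{frame_id}_labels.png", truth.label_mask.astype(np.uint16))
    truth.to_json(out / f"{frame_id}_truth.json")


def generate_feature_table(
    n_samples: int,
    n_informative: int,
    n_noise: int,
    class_sep: float,
    seed: int,
) -> FeatureTable:
    """Labeled Gaussian table with known informative columns.

    Informative column j gives class c a mean of ``class_sep`` times a
    column-specific random permutation of (-1, 0, 1); within-class standard
    deviation is 1. Noise columns are N(0, 1) regardless of label.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    rng = np.random.default_rng(seed)
    n_feat = n_informative + n_noise
    labels = np.array([(k % 3) + 1 for k in range(n_samples)])
    rng.shuffle(labels)
    X = rng.normal(0.0, 1.0, size=(n_samples, n_feat))
    positions = rng.permutation(n_feat)[:n_informative]
    offsets = np.array([-1.0, 0.0, 1.0])
    for j in positions:
        perm = rng.permutation(offsets)
        X[:, j] += class_sep * perm[labels - 1]
    df = pd.DataFrame(X, columns=[f"F{k:03d}" for k in range(n_feat)])
    return FeatureTable(df, labels, informative=tuple(int(p) for p in sorted(positions)))
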