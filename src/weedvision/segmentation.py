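"""Green-dominance vegetation segmentation and plant-object extraction.

A pixel is vegetation when its green component strictly dominates red and
blue and reaches an absolute 8-bit threshold (default 140):

    plant(x, y)  <=>  R < G  and  B < G  and  G >= threshold

The binary mask is cleaned with a morphological closing (disk structuring
element) and decomposed into connected components; components below a
minimum area are discarded as speckle.

Coordinates are 0-based row-major; bounding boxes are half-open
``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology


@dataclass(frozen=True)
class SegmentationConfig:
    green_threshold: int = 140
    closing_radius: int = 1
    min_object_area: int = 50
    connectivity: int = 8  # 4 or 8 neighbourhood

    def __post_init__(self):
        if not (20 <= self.green_threshold <= 250):
            raise ValueError("green_threshold must lie in [20, 250]")
        if self.closing_radius < 1:
            raise ValueError("closing_radius must be >= 1")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class PlantObject:
    """One connected green region; the unit of classification."""

    mask: np.ndarray                    # local boolean patch (tight)
    bbox: tuple[int, int, int, int]     # (row0, col0, row1, col1) half-open
    centroid: tuple[float, float]       # (row, col) in frame coordinates
    area: int
    source_frame_id: str = ""
    channel: str = ""
    label: int = 0                      # 0 = unknown
    meta: dict = field(default_factory=dict)

    def pixels(self, frame: np.ndarray) -> np.ndarray:
        """Pixel values of this object from its source frame, shape (n, C)."""
        r0, c0, r1, c1 = self.bbox
        patch = frame[r0:r1, c0:c1]
        return patch[self.mask]


def _check_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB frame")
    return frame


def green_mask(frame: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Pixelwise green-dominance rule: R < G and B < G and G >= threshold."""
    config = config or SegmentationConfig()
    frame = _check_rgb(frame).astype(np.int32)
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    return (r < g) & (b < g) & (g >= config.green_threshold)


def close_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing (dilate then erode) with a disk element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    selem = morphology.disk(radius)
    return morphology.closing(mask, footprint=selem).astype(bool)


def extract_objects(
    mask: np.ndarray,
    config: SegmentationConfig | None = None,
    *,
    frame_id: str = "",
    channel: str = "",
) -> list[PlantObject]:
    """Connected components of a cleaned mask, small speckle removed.

    Objects are returned ordered by the (row0, col0) of their bounding box.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if config.connectivity == 4 else 2
    labeled = measure.label(mask, connectivity=conn)
    objects: list[PlantObject] = []
    for region in measure.regionprops(labeled):
        if region.area < config.min_object_area:
            continue
        r0, c0, r1, c1 = region.bbox
        objects.append(
            PlantObject(
                mask=region.image.copy(),
                bbox=(r0, c0, r1, c1),
                centroid=tuple(region.centroid),
                area=int(region.area),
                source_frame_id=frame_id,
                channel=channel,
            )
        )
    objects.sort(key=lambda o: (o.bbox[0], o.bbox[1]))
    return objects


def segment_frame(
    frame: np.ndarray,
    config: SegmentationConfig | None = None,
    *,
    frame_id: str = "",
    channel: str = "",
) -> tuple[np.ndarray, list[PlantObject]]:
    """Full segmentation pipeline: rule mask -> closing -> objects."""
    config = config or SegmentationConfig()
    raw = green_mask(frame, config)
    closed = close_mask(raw, config.closing_radius)
    objects = extract_objects(closed, config, frame_id=frame_id, channel=channel)
    return closed, objects
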