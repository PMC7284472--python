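"""Per-object feature vector assembly and whole-frame feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import FeatureRegistry, default_registry
from .segmentation import PlantObject
from .tables import FeatureTable
from .color import color_features
from .shape import shape_features
from .texture import histogram_features, texture_features

# luminance weights for the texture gray conversion
_GRAY_W = np.array([0.299, 0.587, 0.114])


def object_gray_patch(obj: PlantObject, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-bit luminance patch of the object's bounding box plus its mask."""
    r0, c0, r1, c1 = obj.bbox
    patch = np.asarray(frame[r0:r1, c0:c1], dtype=float)
    gray = patch @ _GRAY_W
    return gray, obj.mask


def extract_feature_vector(
    obj: PlantObject,
    frame: np.ndarray,
    registry: FeatureRegistry | None = None,
    glcm_levels: int = 8,
) -> np.ndarray:
    """The 302-entry descriptor of one object, in registry order."""
    registry = registry or default_registry()
    pixels = obj.pixels(frame)
    feats: dict[str, float] = {}
    feats.update(color_features(pixels))
    gray, mask = object_gray_patch(obj, frame)
    feats.update(texture_features(gray, mask=mask, levels=glcm_levels))
    feats.update(histogram_features(gray, mask=mask))
    feats.update(shape_features(obj.mask))
    vec = np.array([feats[nm] for nm in registry.names], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [registry.names[k] for k in np.nonzero(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite features: {bad}")
    return vec


def extract_table(
    objects: list[PlantObject],
    frame: np.ndarray,
    registry: FeatureRegistry | None = None,
) -> FeatureTable:
    """Feature table of all objects of one frame (labels from obj.label)."""
    registry = registry or default_registry()
    rows = [extract_feature_vector(o, frame, registry) for o in objects]
    df = pd.DataFrame(np.array(rows).reshape(len(rows), len(registry)),
                      columns=list(registry.names))
    labels = np.array([o.label for o in objects], dtype=int)
    return FeatureTable(df, labels)
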