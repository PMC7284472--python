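"""The fixed 302-entry feature registry.

Every plant object is described by exactly 302 features, partitioned as
127 color, 144 GLCM texture (36 statistics x 4 orientations), 2 histogram
and 29 shape descriptors. The registry fixes the names, groups and order
once; feature vectors and CSV columns follow it everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .color import color_feature_names
from .shape import SHAPE_FEATURE_NAMES
from .texture import texture_feature_names

GROUP_SIZES = {"color": 127, "texture": 144, "histogram": 2, "shape": 29}
N_FEATURES = 302

HISTOGRAM_FEATURE_NAMES = ("Histogram entropy", "Smoothness")


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, named catalogue of the 302 features."""

    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def indices_of_group(self, group: str) -> list[int]:
        return [k for k, g in enumerate(self.groups) if g == group]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_json(self, path) -> None:
        payload = [{"index": k, "name": n, "group": g}
                   for k, (n, g) in enumerate(zip(self.names, self.groups))]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_registry() -> FeatureRegistry:
    names: list[str] = []
    groups: list[str] = []
    for nm in color_feature_names():
        names.append(nm)
        groups.append("color")
    for nm in texture_feature_names():
        names.append(nm)
        groups.append("texture")
    for nm in HISTOGRAM_FEATURE_NAMES:
        names.append(nm)
        groups.append("histogram")
    for nm in SHAPE_FEATURE_NAMES:
        names.append(nm)
        groups.append("shape")
    if len(names) != N_FEATURES or len(set(names)) != N_FEATURES:
        raise AssertionError("registry must contain 302 unique names")
    return FeatureRegistry(tuple(names), tuple(groups))
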