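"""Extract the 302-entry descriptor of one plant object.

The descriptor is 127 color features (per-channel statistics over six
color spaces plus vegetation indices), 144 GLCM texture statistics
(36 per orientation at 0/45/90/135 degrees), 2 histogram features and
29 shape descriptors.
"""

import weedvision as wv

cfg = wv.SceneConfig(frame_size=(300, 400), n_objects_per_class=(1, 1, 1), seed=3)
left, _, _ = wv.generate_scene(cfg)
_, objects = wv.segment_frame(left)
registry = wv.default_registry()

vec = wv.extract_feature_vector(objects[0], left, registry)
print(f"features per object: {len(vec)}")
for group in ("color", "texture", "histogram", "shape"):
    print(f"  {group:9s}: {len(registry.indices_of_group(group))}")

named = dict(zip(registry.names, vec))
for name in ("Rn", "ExG-RGB", "CIVE-RGB", "Entropy-45", "Elongation feature", "WL"):
    print(f"  {name:20s} = {named[name]: .4f}")

# Rn near 1/3 with ExG > 0 says the object is green-dominant; a high
# elongation / low WL marks a thin leaf (rice or narrow-leaf weed).
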