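"""The full four-category pipeline on synthetic stereo scenes.

Segmentation, feature extraction, stereo fusion, PSO feature selection,
bee-algorithm MLP optimization and the KNN reference, evaluated with
confusion matrices and one-vs-rest AUC on a 70/30 split.
"""

import weedvision as wv
from weedvision.classify import BAConfig
from weedvision.selection import PSOConfig

cfg = wv.PipelineConfig(
    seed=1, n_frames=6,
    scene=wv.SceneConfig(frame_size=(360, 480), n_objects_per_class=(3, 3, 3),
                         disparity_px=10),
    ba=BAConfig(n_scouts=6, n_sites=2, n_elite=1, recruits_elite=3,
                recruits_other=2, iterations=2),
    selection=PSOConfig(swarm_size=8, max_iterations=5, subset_size=24),
)
result = wv.run_pipeline(cfg)

print(f"{'category':>11} | {'ANN-BA acc':>10} | {'KNN acc':>8} | ANN-BA spec")
for cat in wv.CATEGORIES:
    rep = result["categories"][cat]
    spec = rep["ann_ba"]["spec"]
    print(f"{cat:>11} | {rep['ann_ba']['overall_accuracy']:>9.2f}% "
          f"| {rep['knn']['overall_accuracy']:>7.2f}% "
          f"| {spec['hidden_sizes']} {spec['transfers']} {spec['training']}")

# On these separable scenes every category classifies at or near 100%;
# with noisier appearance the fused categories are the robust ones.
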