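"""Anatomical feature points by quadric-error-metric simplification.

Extracts a feature-point set from a synthetic 5-cusp tooth and checks that
every cusp apex — known analytically for the generator — has a feature
point nearby, which is what makes the downstream RBF correspondence work.
"""

import numpy as np

from toothwear import SyntheticToothSpec, extract_feature_points, generate_tooth

spec = SyntheticToothSpec(n_cusps=5, resolution=800, seed=1)
tooth = generate_tooth(spec)
features = extract_feature_points(tooth, 80)
print(f"{tooth.n_vertices} vertices -> {features.count} feature points")

apex_xy = spec.cusp_centers()
apex = np.column_stack([apex_xy, spec.height(apex_xy)])
for k, a in enumerate(apex):
    d = np.linalg.norm(features.positions - a, axis=1).min()
    print(f"cusp {k + 1}: nearest feature point {d:.3f} mm from the apex")
# Distances well under one edge length (~0.4 mm here) mean the simplified
# model kept a vertex on every cusp, i.e. the features track the anatomy.
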