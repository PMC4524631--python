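"""Full wear-process simulation on a synthetic molar, end to end.

Generates an intact tooth and an independently retessellated worn
counterpart, then runs the whole pipeline — QEM feature extraction,
axial-only ICP, RBF + contraction-and-bounding homogenization, and
Laplacian-coordinate morphing on a 6-frame linear schedule — and reports
how well the known wear depths are recovered.
"""

import numpy as np

from toothwear import (
    PipelineConfig,
    SyntheticToothSpec,
    WearFieldSpec,
    apply_wear,
    generate_tooth,
)
from toothwear.pipeline import simulate_meshes

s0 = generate_tooth(SyntheticToothSpec(n_cusps=5, resolution=800, seed=1))
s1, truth = apply_wear(
    s0, WearFieldSpec(max_depth=0.5, pattern="per-cusp", seed=1), retessellate=True
)
print(f"intact tooth: {s0.n_vertices} vertices; worn scan: {s1.n_vertices} vertices")

config = PipelineConfig(n_features=100, n_frames=6)
frames, report = simulate_meshes(s0, s1, config)

h = report["stages"]["homogenize"]
print(f"homogenization: {h['iterations']} iterations, final E = {h['final_E']:.2e} "
      f"(converged: {h['converged']})")

final = frames[-1]
err = np.abs(final.wear_depth - truth)
print(f"frames at u = {[f.u for f in frames]}")
print(f"wear-depth recovery vs ground truth: mean |error| = {err.mean():.4f} mm, "
      f"90th pct = {np.quantile(err, 0.9):.4f} mm (max true depth 0.5 mm)")
# The mean error is the vertex-wise accuracy of the whole chain: feature
# projection, RBF interpolation, contraction and morph reconstruction.
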