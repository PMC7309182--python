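# phytoskel

Skeleton extraction and refinement for 3D point clouds of leafless plants.

Plant phenotyping pipelines (branch counting, internode distances, growth
tracking, pruning robotics) need a thin, centered, biologically faithful
skeleton of the scanned plant. Centroid-based skeletonizers produce usable
but flawed trees: zigzag structure near branch junctions, nodes off the
branch centerline or outside the cloud entirely, and non-uniform point
density. `phytoskel` builds such a coarse skeleton, re-expresses it as a
**curve tree** — one β-spline-resampled curve per botanical axis, child
curves attached on their parent with C_child(0) = C_parent(u₀) — and then
refines every skeleton point against the original cloud with an
EM-optimized Gaussian mixture:

- cloud points p_j are observations of a mixture
  `p(p_j) = ε/n + (1−ε) Σ_i α_ij N(p_j; s_i, σ² I)` whose centroids are
  the m skeleton points (m ≪ n), with a uniform outlier component ε;
- membership priors `α_ij = exp(−α |μ_i − μ_j|)` compare local-PCA shape
  descriptors μ = λ₀/(λ₀+λ₁+λ₂) of the two point sets;
- the M-step displaces centroids through a coherent field `s′ = s + G·W`,
  `G[i,i′] = exp(−‖s_i−s_i′‖²/2β²)`, penalized by `(λ/2)·tr(WᵀGW)`, which
  has a closed-form solution each iteration.

For tube-like organs the stationary centroids sit on the centerline, which
is exactly what a skeleton should be. See `docs/methods.md` for the full
model, parameter table and limitations.

## Worked example

Generate a synthetic two-junction plant with exact ground truth, degrade
its centerline the way a coarse skeletonizer would, refine it, and score
both skeletons:

```python
import numpy as np
from phytoskel import (PlantSpec, generate_ground_truth, sample_tube_cloud,
                       perturb_skeleton, decompose_axes, build_curve_tree,
                       refine, GMMParams, evaluate_skeleton)

spec = PlantSpec(n_axes=3, depth=2, radius=1.0, points_per_mm2=8.0,
                 noise_sd=0.02, curvature=0.01, seed=1)
gt, centerline = generate_ground_truth(spec)
cloud = sample_tube_cloud(centerline, spec, seed=1)         # (4533, 3), mm
initial = perturb_skeleton(centerline, zigzag_amp=0.5, seed=2)

curve_tree = build_curve_tree(decompose_axes(initial))      # uniform 1 mm spacing
refined, trace = refine(cloud, curve_tree, GMMParams())     # lambda=5, beta=5

for name, skel in [("initial", initial), ("refined", refined)]:
    e = evaluate_skeleton(gt, skel)
    print(name, round(np.mean(e.junction_errors), 4),
          round(np.mean(e.segment_errors), 4))
```

Output:

```
initial 0.0275 0.3928
refined 0.0253 0.0698
```

Both numbers are errors relative to the mean ground-truth branch-segment
length (18.2 mm here): the degraded skeleton mis-measures branch segments
by ~39% on average — its zigzag inflates every polyline arc length — while
the refined skeleton is within ~7%; the junction-location error also
drops. On a straight tube of radius 1 mm the same refinement moves a
zigzag skeleton (RMSE 0.49 mm off-axis) to within 0.21 mm of the true
centerline in 17 EM iterations.

The same pipeline is scriptable from the shell:

```sh
phytoskel synth --seed 1 --out-cloud cloud.xyz --out-gt gt.json --out-init init.json
phytoskel refine --cloud cloud.xyz --skeleton init.json --output refined.json --trace trace.csv
phytoskel evaluate --gt gt.json --pred refined.json --report report.json
phytoskel run --config run.yaml        # all stages, intermediates persisted
```

`phytoskel coarse` extracts the initial skeleton from a raw cloud when you
do not already have one. Clouds are read/written as ASCII XYZ or PLY;
skeletons as JSON (with axes) or SWC.

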