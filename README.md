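# stemleaf

Stem–leaf segmentation and phenotyping of individual 3D plant point clouds.

Point clouds of young plants (e.g. cucumber seedlings reconstructed from
multi-view imagery) must be split into stem and leaf points before any organ
-level trait can be measured. `stemleaf` implements a complete pipeline for
this task on a single CPU:

- **Semantic segmentation** with a dual-channel *geometric graph encoder*:
  for every point's K-nearest-neighbor graph, an adaptive-kernel graph
  convolution extracts local geometric relationships in Euclidean space
  (per-edge kernels g_m(Δf_ij) scored against Δx_ij = [x_i; x_j − x_i] and
  attention-pooled), while a star-transformer over the same neighborhood —
  embedded in the Poincaré ball of curvature −c via the exponential map
  exp₀(f) = tanh(√c‖f‖)·f/(√c‖f‖) — captures hierarchical shape structure.
  A sigmoid gate fuses the two channels per feature. Two full-resolution
  encoder blocks and three pooling blocks (farthest point sampling at rate 4
  + neighborhood max pooling) form an N → N/4 → N/16 → N/64 hierarchy whose
  stage outputs are interpolated back to N rows and scored by a shared MLP
  (512, 256, p). Training minimizes α·L_CE + β·L_triplet with SGD
  (momentum 0.9, cosine-annealed learning rate 0.1 → 0.001, batch size 4,
  early stopping).
- **Instance segmentation** of individual leaves by K-means (k-means++) with
  the cluster count chosen by a geometric elbow criterion on the inertia
  curve.
- **Phenotyping**: plant height C_h = z_max − z_min; leaf length/width as
  PCA-extremal chord distances; leaf area as the Heron-formula sum over a
  pivot-ball surface triangulation; agreement with reference values scored
  by R² and RMSE (reference leaf area convention 0.743·L·W).
- **Synthetic plants** with exact analytic ground truth (per-leaf length,
  width, surface area; semantic and instance labels), plus the
  point-removal and uniform-noise corruption protocols used for robustness
  tests.

The network runs on a self-contained numpy reverse-mode autodiff engine —
no deep-learning framework required.

## Worked example

```python
import numpy as np
from stemleaf import (
    SyntheticPlantSpec, generate_plant, normalize, denormalize,
    GGEConfig, LossConfig, OptConfig, train_model, predict,
    segment_leaf_instances, extract_phenotypes, confusion_counts,
)
from stemleaf.autodiff import default_dtype
from stemleaf.hyperbolic import HGSConfig

# 32 training plants and 4 held-out plants, 512 points each
def plants(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = SyntheticPlantSpec(points_total=512, n_leaves=int(rng.integers(6, 9)),
                                  junction_gap=1.0,  # petiole stand-off
                                  seed=int(rng.integers(2**31 - 1)))
        cloud, _ = generate_plant(spec)
        out.append(normalize(cloud)[0])
    return out

train, held = plants(32, 0), plants(4, 99)
cfg = GGEConfig(stage_dims=(32, 32, 64, 128, 256), K=10, head_dims=(256, 128),
                hgs=HGSConfig(layers=2, heads=4), seed=0)
with default_dtype(np.float32):          # float32 training on one CPU
    model, history = train_model(train, cfg, LossConfig(),
                                 OptConfig(epochs=10, patience=10, seed=0))
    pred = predict(held[0], model)
m = confusion_counts(pred.semantic_labels, held[0].semantic_labels, 2)
print(f"held-out OA {m.oa:.3f}  mIoU {m.miou:.3f}")
```

```
held-out OA 0.973  mIoU 0.823
```

97 % of the held-out points carry the correct stem/leaf label after ten
epochs (about five minutes on one CPU at these scaled widths). Phenotyping
then runs on a segmented, metric-restored cloud:

```python
spec = SyntheticPlantSpec(points_total=2000, n_leaves=6, junction_gap=1.0,
                          surface_noise_sd=0.0, seed=7)
cloud, truth = generate_plant(spec)
norm, t = normalize(cloud)
with default_dtype(np.float32):
    seg = predict(norm, model)
labeled, _ = segment_leaf_instances(denormalize(seg, t))   # elbow + k-means++
record = extract_phenotypes(labeled)
print(record.as_frame(plant_id=0).head())
print("true height %.2f cm; true lengths %s"
      % (truth.plant_height, np.round(sorted(truth.leaf_length), 2)))
```

```
   plant_id  leaf_id        C_h       C_l       C_w        C_a
0         0        0  16.965141  5.509739  4.165865  17.804859
1         0        1  16.965141  6.991001  4.688993  25.440230
2         0        2  16.965141  5.600280  4.805803  20.757411
3         0        3  16.965141  6.594139  4.201902  21.102962
4         0        4  16.965141  5.429958  3.740482  15.614023
true height 16.97 cm; true lengths [5.43 5.51 5.6  6.25 6.59 6.99]
```

Heights are in cm, areas in cm²; each row is one leaf instance of the
plant: the plant height matches the ground truth to a hundredth of a cm and
the per-leaf length/width chords track the generator values. A command-line
interface wraps the same pipeline
(`stemleaf synth / train / segment / phenotype / evaluate`); see
`stemleaf --help`.

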