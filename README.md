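# elasticshapes

Elastic and geometric-morphometric analysis of planar outline shapes, for
anyone who classifies objects — shells, leaves, vessels, any segmentable
silhouette — by the shape of their boundary curve.

Two shape spaces are implemented side by side:

- **Eigenshapes** (linear): outlines resampled to equally spaced
  semi-landmarks, Procrustes-aligned to remove translation/scale/rotation,
  reduced by PCA; distances are Euclidean in the first *d* components
  (chosen by explained variance).
- **Elastic / SRVF** (curved): each curve `c` is mapped to its square-root
  velocity function `q = c′/√‖c′‖` and scale-normalized, which places every
  shape on a sphere in function space. The distance

  `d = arccos ⟨q₁, (O q₂)∘γ · √γ̇⟩`

  is minimized over rotation `O`, monotone reparametrization `γ` (dynamic
  programming) and, for closed curves, the cyclic start point — so it is
  invariant to translation, scale, rotation, start vertex and
  parametrization. Open-curve mode pins homologous start/end landmarks
  instead, removing the rotation search.

On top of the metrics: a distance-matrix k-NN with stratified replicates
and weighted-F1 reporting, linear and Karcher (Fréchet) mean shapes,
geodesic shape-transformation series with path energies, mirror-symmetric
transforms, class-average distance matrices, metric correlations, and
neighbour-joining trees with monophyly checks. A seeded synthetic outline
generator (star-shaped Fourier templates plus nuisance transforms) makes
the whole pipeline testable without any image downloads.

## Worked example

```python
import numpy as np
from elasticshapes import (
    NuisanceSpec, PipelineConfig, make_dataset, make_families, run_pipeline,
)

families = make_families(n_classes=5, separation=0.25, seed=7)
nuisance = NuisanceSpec(
    rotation_range=2 * np.pi, scale_range=(0.8, 1.25), translation_range=0.5,
    start_shift=True, reparam_strength=0.3, vertex_noise_sd=0.01,
)
dataset = make_dataset(families, nuisance, n_per_class=8, n_points=100, seed=11)

for method in ("srvf-closed", "eigenshapes"):
    cfg = PipelineConfig(method=method, n_points=100, grid_size=60,
                         n_replicates=10, train_fraction=2/3, seed=1)
    res = run_pipeline(cfg, dataset=dataset)
    print(method, "f1 = %.3f (best k = %d)" % (res["report"].f1_mean, res["best_k"]))
```

prints

```
srvf-closed f1 = 1.000 (best k = 3)
eigenshapes f1 = 0.458 (best k = 3)
```

The gap is the point: the generator rotates every outline and randomizes
its start vertex, so vertex correspondence is destroyed. Procrustes + PCA
depends on that correspondence, while the elastic distance optimizes it
away, and the k-NN ranking reflects exactly that.

The same library drives a CLI for file-based work:

```bash
elasticshapes synth --n-classes 5 --n-per-class 30 --seed 1 --out data/
elasticshapes run --manifest data/manifest.csv --method srvf-closed --out run/
elasticshapes tree --distances run/distances.csv --manifest data/manifest.csv \
    --root class_0 --out tree.nwk
elasticshapes geodesic --from a.csv --to b.csv --kappa 5 --out path/
```

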