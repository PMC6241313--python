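# diffcentroid

Fast template estimation and tangent-space statistics for populations of
triangulated surfaces (brain structures such as hippocampi) under the
LDDMM diffeomorphic framework with a currents data term.

## The problem

Population shape analysis needs a *template*: a centre of the population
from which every subject's anatomy can be encoded as a deformation.  The
classical variational template (alternating subject-to-template matchings
with a closed-form template update) is accurate but needs N × iter
expensive matchings.  This package implements *iterative centroids*:
estimators that reach a well-centred template in exactly N − 1 pairwise
matchings by unrolling the running-mean recursion

    b_{k+1} = geod(b_k, x_{k+1}, 1/(k+1))

on the shape manifold — the Riemannian analogue of the Euclidean identity
b_N = (1/N) Σ x_i.  Three variants are provided:

* **IC1** — carries a single mesh; cheapest.
* **IC2** — carries a weighted union of surfaces in the space of currents,
  averaging forward-deformed members with the backward-flowed new subject.
* **PW** — pairwise recursion over a dyadic tree with size-proportional
  weights.

Shapes are matched by minimizing J(v) = γE(v) + ‖[φ_v(S)] − [T]‖²_W*,
where E is the deformation energy of a velocity field in an RKHS with
Cauchy kernel K_V (scale σ_V) and the data term is the currents metric
(kernel K_W, scale σ_W) — no point correspondences required.  Matching is
parametrized by initial momentum vectors α(0) under geodesic shooting;
those momenta are also the tangent-space coordinates used downstream:
kernel PCA (covariance (αⁱ−ᾱ)ᵀK_V(αʲ−ᾱ)/(N−1)), the centring diagnostic
R = ‖Σvⁱ‖_V / Σ‖vⁱ‖_V (zero at a critical point of the Fréchet
functional), first-order approximated distance matrices
ρ̃(i,j) = ‖αʲ−αⁱ‖_K, and linear score prediction from principal-mode
coordinates.  A synthetic-population generator with a *known exact
centre* (antipodal momentum pairs ⇒ Σα = 0) makes the whole pipeline
verifiable end to end.  See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

Estimate an IC1 centroid of a small synthetic population and analyse its
tangent space:

```python
import numpy as np
from diffcentroid import (
    KernelConfig, MatchConfig, SyntheticConfig,
    generate_population, make_base_shape, ic1_centroid,
    extract_momenta, centring_ratio, kernel_pca, approx_distance_matrix,
)

base = make_base_shape(42, "bent_ellipsoid")          # 42-vertex bent ellipsoid
cfg = MatchConfig(kernel_V=KernelConfig("cauchy", 15.0),
                  kernel_W=KernelConfig("cauchy", 7.5))
pop = generate_population(SyntheticConfig(n_subjects=6, base_shape=base,
                                          kernel_V=cfg.kernel_V, seed=7))

centroid = ic1_centroid(pop.shapes, cfg)              # 5 pairwise matchings
momenta = extract_momenta(centroid, pop.shapes, cfg)  # 6 more matchings
R = centring_ratio(momenta)
pca = kernel_pca(momenta)
dm = approx_distance_matrix(momenta)

print(f"matchings performed: {centroid.n_matchings}")
print(f"centring ratio R = {R:.3f}")
print(f"CEV (modes 1-3): {np.round(pca.cev[:3], 3)}")
print(f"mean pairwise distance (approx): {dm.values[np.triu_indices(6, 1)].mean():.2f} mm")
```

Output:

```
matchings performed: 5
centring ratio R = 0.038
CEV (modes 1-3): [0.927 1.    1.   ]
mean pairwise distance (approx): 6.33 mm
```

Reading it: the centroid of 6 subjects cost 5 matchings; its centring
ratio 0.038 means the mean initial velocity from the centroid to the
subjects is ~4% of the mean velocity magnitude, i.e. the centroid is very
close to a critical point of the Fréchet functional (0 would be exact).
Two PCA modes explain all variance because the population was generated
from two dominant momentum directions, and the 6.3 mm mean pairwise
distance is the first-order tangent-space estimate of the diffeomorphic
distances between subjects.

A command-line interface mirrors the library
(`diffcentroid simulate | match | centroid | template | stats | predict |
run | convert`); meshes are read and written as PLY or legacy ASCII VTK
polydata.

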