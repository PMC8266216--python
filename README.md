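# placemap

Non-negative sparse coding model of how the hippocampus could learn a
place map from entorhinal cortex inputs.

Grid cells in the medial entorhinal cortex fire on hexagonal lattices
characterized by spacing λ, orientation θ and phase (x₀, y₀); other
entorhinal cells carry only weak, unstructured spatial tuning.  Hippocampal
place cells, one synapse downstream, fire at a single location.  This
package implements a two-layer learning model of that transformation: the
entorhinal population response **s**ₑ = **E**ᵀ**r** at a one-hot location
**r** drives a hippocampal population whose rates solve the non-negative,
ℓ1-penalized sparse coding problem

    min_{s ≥ 0}  ½‖s_e − A s‖² + β Σᵢ sᵢ

via locally competitive dynamics (threshold β, lateral competition
**W** = **A**ᵀ**A** − **I**, first-order Euler integration), while the
non-negative dictionary **A** is learned online with
Δ**A** = η(**s**ₑ − **A s**ₕ)**s**ₕᵀ, clipping to zero and unit-norm
columns.  The package also implements the full analysis pipeline:
reverse-correlation recovery of hippocampal firing fields, isotropic
Gaussian place-field fitting, place-cell classification (fit error < 15%,
breadth σ > 5 cm) and tiling statistics (distance-to-place-field d_PF and
second-nearest-neighbour distance d_ND), plus preset experiments for
diverse/ablated grid inputs, realistic module-sampled grids, weakly
spatial inputs, response noise, a stretched arena and trajectory-based
training.

Intended users: computational neuroscientists studying the
entorhinal-hippocampal circuit, spatial codes, or sparse coding models.

## Worked example

Train on 600 diverse idealized grid cells (4 spacings from 28 cm with
geometric ratio 1.42, 6 orientations, 5×5 phases) with 100 hippocampal
cells at the default hyperparameters, then recover, fit and classify
(about half a minute on one CPU):

```python
import placemap as pm

results = pm.run_experiment(pm.get_preset("fig3"), seed=1)
for key in ("n_place_cells", "mean_radius_cm", "mean_nearest_distance_cm",
            "max_distance_to_field_cm", "active_fraction"):
    print(key, round(results[key], 3))
```

prints

```
n_place_cells 100
mean_radius_cm 8.95
mean_nearest_distance_cm 10.55
max_distance_to_field_cm 8.513
active_fraction 0.091
```

All 100 hippocampal cells become place cells with mean fitted radius
≈ 8.9 cm; their centers tile the 1 × 1 m arena in a near-hexagonal lattice
(second-nearest-neighbour distance ≈ 10.5 cm, every location within
≈ 8.5 cm of a field center), and about 9% of cells are co-active at any
location.

The same model is exposed as a scikit-learn style estimator:

```python
from placemap import SparseCodingPlaceMap, make_environment, make_math_grid_population

pop = make_math_grid_population(make_environment(), 4, 6, 5, 5)
est = SparseCodingPlaceMap(n_hippocampal=100, random_state=1).fit(pop.E)
rates = est.transform(pop.E)      # (1024 locations, 100 cells)
```

There is also a CLI:

```bash
placemap list-presets
placemap run fig3 --seed 1 --out runs/fig3
```

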