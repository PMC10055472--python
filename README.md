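# jetmap

Derivative-preserving mapping of neuron traces under diffeomorphisms.

## The problem

Single-neuron reconstructions are stored as trees of sampled 3D points
("knots"), typically in the SWC format, and are compared across brains by
transforming them into a common coordinate system. Standard practice maps
only the knot positions and re-connects them with straight segments — what
we call **zeroth order** mapping. Under a nonlinear transformation this
ignores how the map bends the segments between knots, so differently sampled
versions of the same neuron can land on different mapped shapes.

`jetmap` treats a sampled curve as a sequence of time-stamped *jets*
`(t_i, x_i⁽ᵏ⁾)` — position plus the first *k* derivatives — on which a
diffeomorphism φ acts by the chain rule (prolongation). For *k* = 2:

    φ·(t, x₀, x₁, x₂) = (t, φ(x₀), Dφ(x₀)x₁, Dφ(x₀)x₂ + D²φ(x₀)[x₁, x₁])

**First order** mapping transports the one-sided tangent vectors of the
polyline by the Jacobian Dφ and rebuilds each segment as a cubic Hermite
polynomial matching the mapped positions and one-sided derivatives at both
endpoints. Worst-case bounds make the comparison precise: for an arc-length
polyline with knot spacing δ and transformed curve f = φ∘c,

    zeroth order:  max|f − g₀| ≤ ¾ M₄ (δ/2)⁴ + 3/2 (δ/2)³ M₃ + 3/2 (δ/2)² M₂
    first  order:  max|f − g₁| ≤ (3/4!) M₄ (δ/2)⁴

where Mⱼ bounds the j-th derivatives of f's coordinates. A separate bound
ties the zeroth-order error to the spectral norm of Dφ − I and the knot
displacements, and is verified numerically here.

The package is aimed at neuroinformatics users who register traces to
atlases (and at anyone mapping sampled curves through smooth deformations):
it provides SWC I/O, decomposition of trees into non-branching branches,
both mapping orders, dense ground-truth mapping, an LDDMM-style random
diffeomorphism simulator for stress-testing, discrete Fréchet and
morphometric (path angle, branch angle, tortuosity, segment length)
comparison, and the node-removal (downsampling) analysis.

## Worked example

```python
import numpy as np
from jetmap import (make_tree, decompose_tree, dense_ground_truth,
                    zeroth_order_map, first_order_map, discrete_frechet,
                    random_lddmm_diffeo, LddmmConfig)
from jetmap.experiments import center_tree, forest_bounds

tree = center_tree(make_tree(n_leaves=3, seed=42))
phi = random_lddmm_diffeo(
    LddmmConfig(sigma=320.0, bounds=forest_bounds([tree]), seed=7))
print(f"min Jacobian determinant on the grid: {phi.min_jacobian_det():.3f}")
for i, branch in enumerate(decompose_tree(tree)):
    gt = dense_ground_truth(branch, phi)   # 2 um upsampling, then map
    e0 = discrete_frechet(zeroth_order_map(branch, phi)(gt.knot_params),
                          gt.knot_positions)
    e1 = discrete_frechet(first_order_map(branch, phi)(gt.knot_params),
                          gt.knot_positions)
    print(f"branch {i}: {len(branch):3d} knots, {branch.length:6.1f} um arc, "
          f"Frechet error zeroth {e0:.3f} um / first {e1:.3f} um")
```

prints

```
min Jacobian determinant on the grid: 0.806
branch 0:  26 knots,  646.5 um arc, Frechet error zeroth 1.880 um / first 1.573 um
branch 1:   2 knots,   19.5 um arc, Frechet error zeroth 0.064 um / first 0.096 um
branch 2:   3 knots,   62.4 um arc, Frechet error zeroth 0.616 um / first 0.395 um
```

The random field (`sigma = 320` μm/time Gaussian initial momentum, smoothed
and flowed to a diffeomorphism) displaces this neuron's neighborhood by tens
of microns while staying invertible (positive Jacobian determinant). Each
branch is mapped three ways; errors are discrete Fréchet distances from the
dense ground truth, sampled at the same arc-length parameters. The long,
coarsely sampled branch is where mapping order matters most; either method
can win on a short nearly straight branch (here branch 1, where both errors
are far below a micron).

## Command line

```sh
jetmap simulate-diffeo --sigma 320 --seed 7 --bounds 400 --out field.txt
jetmap map neuron.swc mapped.swc --order 1 --field field.txt --sidecar side.tsv
jetmap evaluate neuron.swc mapped.swc
jetmap sweep config.yaml --out sweep.tsv       # sigma-sweep study
jetmap removal config.yaml --out removal.tsv   # node-removal study
```

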