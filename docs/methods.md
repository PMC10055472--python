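# Methods

## Model

A neuron trace is a rooted tree of 3D points in microns (SWC). Radius and
structure-type columns are carried through I/O but ignored by all
computations: the trace is a tree of piecewise-linear curves. Trees are
reduced to non-branching **branches** by recursively removing the
root-to-leaf path of longest arc length; each remaining subtree is reduced
the same way starting from its attachment node, whose position is duplicated
into the child branch so every branch is geometrically self-contained. Ties
in arc length are broken toward the leaf with the smaller SWC id, making the
decomposition a pure function of the tree. Every parent–child edge lands in
exactly one branch and the branch count equals the leaf count.

Each branch is parameterized by cumulative chord length (t₁ = 0, tᵢ − tᵢ₋₁ =
distance between consecutive knots), i.e. by the arc length of the polyline
itself. The data being mapped are time-stamped jets (tᵢ, x₀, …, x_k): the
knot position plus its first k derivatives with respect to t. A
diffeomorphism φ acts on a jet by the chain rule; up to k = 2:

- x₀ ↦ φ(x₀)
- x₁ ↦ Dφ(x₀)·x₁
- x₂ ↦ Dφ(x₀)·x₂ + D²φ(x₀)[x₁, x₁]

Time-stamps are never modified by the action, so mapped curves of any order
can be sampled at the same parameter values and compared point-by-point.

**Zeroth order mapping** transforms knot positions only and re-linearizes
(an order-1 spline). **First order mapping** also transforms the one-sided
derivatives of the polyline — the secant slopes (xᵢ₊₁ − xᵢ)/(tᵢ₊₁ − tᵢ),
which are exact one-sided derivatives of the piecewise-linear curve and unit
vectors under arc-length parameterization — and rebuilds each segment as the
cubic Hermite polynomial matching position and one-sided derivative at both
endpoints. The resulting order-3 spline is continuous but deliberately not
forced to be differentiable at knots (left and right mapped derivatives
differ wherever the polyline has a corner). An experimental order-2 mapping
(quintic segments, with the polyline's vanishing interior second derivative
mapped through the Hessian term) is provided but is not part of the core
pipeline.

**Ground truth** takes the stored polyline at face value: each segment is
subdivided into ceil(L/2 μm) equal pieces (original knots always retained)
and the dense polyline is mapped zeroth order. Comparison curves are
evaluated at exactly these parameter values; per-branch error is the
discrete Fréchet distance between the two point sequences, and per-neuron
error aggregates branches by the maximum (a conservative choice; `mean` is
available as a switch).

## Error bounds

Two worst-case results are implemented and verified numerically rather than
re-proved:

- `zeroth_order_error_bound`: for an arc-length polyline,
  max|f − g| ≤ maxᵢ,ₜ ½‖Dφ(c(t)) − I‖₂ (tᵢ − tᵢ₋₁) + |εᵢ − εᵢ₋₁| with
  εᵢ = c(tᵢ) − φ(c(tᵢ)) and ‖·‖₂ the spectral norm (largest singular
  value, computed exactly). The supremum over t is approximated by `n_probe`
  uniform probes per segment, so the returned number refines toward the
  analytic bound from below; with 50 probes it dominated the observed error
  in every random trial we run.
- `spline_error_bounds`: given maxima M₂, M₃ (at the knots) and M₄
  (anywhere) of the transformed curve's coordinate derivatives and the
  maximum spacing δ, returns the comparable pair
  (¾M₄(δ/2)⁴ + 3/2(δ/2)³M₃ + 3/2(δ/2)²M₂, (3/4!)M₄(δ/2)⁴). The first-order
  bound is structurally never larger.

The bound structure predicts convergence orders under spacing refinement:
empirically the max error of zeroth-order mapping of a fixed smooth curve
under a fixed smooth non-affine map decays at order ≈ 2 and first-order at
≈ 4 (fitted log–log slopes 1.95 and 3.91 over spacings 20 → 10 → 5 μm).
Under affine maps both methods are exact (error < 1e−9 μm): an affine map
carries line segments to line segments and chord slopes to the Hermite
endpoint derivatives, so the cubic degenerates to the line.

## Random diffeomorphisms (LDDMM shooting)

Test deformations are generated in the LDDMM framework. On a regular grid
covering the working bounding box (20% margin, default spacing 100 μm) an
initial momentum field p₀ is drawn i.i.d. N(0, σ²) per node component, with
σ in μm/time the single strength knob (study levels: 80, 160, 320, 640).
The velocity is the Gaussian-kernel smoothing v = K∗p; the flow runs over
unit time in `n_timesteps` = 10 explicit Euler steps while the momentum is
transported by the EPDiff conservation law in its integrated (coadjoint)
form

    p_t = |det Dψ_t| (Dψ_t)ᵀ p₀∘ψ_t,

with the inverse flow ψ advanced semi-Lagrangially
(ψ_{t+dt}(x) = ψ_t(x − dt·v_t(x))). We use this form deliberately: a direct
forward-Euler/central-difference discretization of the EPDiff transport PDE
is unconditionally unstable for white-noise momentum, whereas the
conservation-law form only ever interpolates bounded fields and is stable at
every σ level. All semi-Lagrangian lookups clamp to the grid and the
smoothing uses a zero boundary condition, so the flow leaves the padded
margin essentially fixed.

The kernel width defaults to a quarter of the box extent (minimum: one grid
spacing). The width is the one genuinely free parameter of the simulator; a
quarter-extent correlation length produces fields that remain invertible
(positive Jacobian determinant on the grid) at all four study σ levels on a
millimeter-scale box — matching the protocol, in which all four random
fields are diffeomorphisms — while displacing geometry by median ≈ 4 μm
(σ = 80) to ≈ 35 μm (σ = 640) with same-seed momenta scaling linearly in σ,
so displacement profiles grow nested with σ. The final map is backed by the
forward displacement field, evaluated by trilinear interpolation; its
Jacobian uses central differences with a step of half the grid spacing
(consistent with the interpolation order). Fields with nonpositive
determinant anywhere on the grid are flagged and excluded from experiment
tables with a log entry.

Analytic families (affine, quadratic polynomial, sinusoidal) provide exact
Jacobians and Hessians for oracle tests; a composition wrapper supplies the
closed-form chain-rule Jacobian and Hessian used to verify the group-action
axioms to 1e−8 relative tolerance.

## Morphometrics and statistics

Four per-neuron distributions are compared: **path angle** (angle subtended
at a non-branching node by its parent and child; 180° = straight — computed
with the atan2 form, which stays well-conditioned near 0° and 180° where
arccos of a normalized dot product loses half its digits), **branch angle**
(between outgoing child segments at a bifurcation; all unordered pairs at
multifurcations), **segment length** (per edge), and **tortuosity** (per
decomposed branch: arc length over endpoint distance). Distributions are
pooled per neuron with no binning and compared with the two-sample
Kolmogorov–Smirnov statistic; values are quantized at 1e−9 before the KS
comparison because the statistic is tie-sensitive and float jitter between
evaluation paths would otherwise register as signal. For the KS comparison
all three mapped trees (ground truth, zeroth, first) are resampled at the
ground-truth parameter values and reassembled into trees (branches welded
back at their attachment nodes), so the statistics reflect mapped geometry
rather than sampling density. Paired zeroth-vs-first differences across
neurons use the two-sided Wilcoxon signed-rank test with Bonferroni
correction (default ×4, one per σ level); all-zero differences are flagged
degenerate instead of producing a p-value.

The discrete Fréchet distance is the standard O(nm) dynamic program (numba-
compiled); it is validated against an exhaustive enumeration of monotone
couplings for short sequences.

## Synthetic data

Fixtures are generated, never stored. Each branch family (line, helix,
sinusoid, polynomial, random-smooth) keeps its underlying smooth curve with
an analytic parametric derivative and a dense numeric arc-length
reparameterization, so the true transformed curve and true tangents can be
sampled at 0.1 μm resolution for oracle comparisons independent of the 2 μm
ground-truth convention. The helix is parameterized by arc length in closed
form (uniform sampling gives exactly equal chords). Random trees weld
random-smooth branches (low-order Fourier perturbations of a line, wiggle
amplitude 5% of length) at random interior attachment points; decomposition
recovers exactly `n_leaves` branches.

Study conditions: the σ-sweep forest holds 20 trees with per-branch knot
spacing drawn U(5, 40) μm, spanning the sampling periods of manual
reconstructions (mapping order matters most above ~10 μm). The node-removal
forest uses 20 trees at a uniform 10 μm spacing: the removal question
presumes sampling fine enough that a nearly collinear node's chord deviation
sits well below the 1 μm threshold — with 40 μm spacing the baseline
(identity-map) removal error itself straddles 1 μm and the fraction is
dominated by sampling artifacts rather than by the mapping. Both studies use
σ ∈ {80, 160, 320, 640} with five replicate momentum draws; these sizes keep
the full suite and the acceptance script in the minutes range on one CPU and
are stated here as the package's reference configuration.

What the synthetic forests do not emulate: real axon/dendrite branching
statistics (Sholl profiles, branch-order distributions), radius taper,
tracing noise, or the spatial extent of whole-brain reconstructions
(millimeter box versus centimeter brain). Passing the scaled-down studies
therefore demonstrates the ordering and trend claims (first-order mapping is
at least as accurate under strong deformation; fewer nodes are redundant
under stronger deformation), not the absolute micron values reported for
real data.

## Numerical choices and limitations

- Hermite evaluation uses the original (pre-map) arc-length parameters; the
  mapped curve is not re-parameterized by post-map arc length.
- Mapped derivatives Dφ·ẋ are used as-is; re-normalizing them would break
  the interpolation contract.
- One-sided derivatives at attachment knots are computed per branch; no
  sharing across branches.
- Zero-length SWC edges are rejected under strict validation and collapsed
  (duplicate dropped, grandchildren re-attached) in lenient mode.
- `decompose_tree` breaks arc-length ties by smaller leaf id; branch
  extraction order is breadth-first along removed paths.
- Removal study: each qualifying node (non-branching in the full tree, path
  angle > 170°) is examined individually on its local two-segment span —
  the reduced single segment is mapped first order and compared with the
  ground-truth mapping of the original two segments; joint removal of
  neighboring nodes is out of scope.
- The LDDMM generator's kernel, grid spacing, and step count are free
  parameters of the simulator, not estimates of any particular brain
  deformation; absolute displacement histograms are therefore
  configuration-dependent even though the monotone σ trend is not.
- Known limitation: branches with n = 2 knots make first-order mapping
  coincide with a single Hermite segment whose endpoint derivatives are the
  chord direction; for strongly curved underlying anatomy this is exactly
  the regime the sampling-period analysis flags as unreliable for either
  method.
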