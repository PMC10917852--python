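# Methods

## Model

A neuron trace is a rooted tree of knots with straight segments in between —
a tree of piecewise-linear curves, each parameterized by arc length
(timestamps are cumulative Euclidean segment lengths). Radius and SWC type
codes are carried through untouched; mapping is radius-free. Traces with
*repeat nodes* (connected knots closer than 1e-6 µm) are rejected at read
time: a zero-length segment has no arc-length parameterization, so mapping
and tangent estimation are undefined on it. Non-consecutive revisits of a
position are accepted — per-segment parameterization remains valid.

### Branch decomposition

Mapping operates on non-bifurcating branches. The decomposition recursively
removes the root-to-leaf path with the longest arc length; each remaining
subtree is processed the same way from the junction node where it hangs off
an already-extracted branch, with that junction copied as the new branch's
first knot. Ties between equal-length paths are broken toward the smaller
leaf id (then smaller child id), making extraction deterministic. Edges are
partitioned exactly — only points are copied, never edges — so total branch
arc length equals total tree edge length.

On reassembly the junction copies are fused; they were produced by evaluating
the same function at the same point, so they must agree to 1e-9 µm — a larger
spread signals a non-function transformation (or a bug) and raises an error
rather than averaging. Knot-level reassembly preserves the original node ids
and order; dense (upsampled) outputs renumber nodes sequentially in branch
order, chain the samples within each branch, attach each branch's first
sample to the fused junction node, and let interpolated samples inherit type
and radius from the downstream original knot of their segment.

## Jets and the action of diffeomorphisms

A k-jet at parameter t bundles a curve's position and first k derivatives.
Diffeomorphisms act on jets so that acting on a curve's jet equals the jet of
the composed curve: position through φ, first derivative through the Jacobian
Dφ, second derivative through Dφ plus the Hessian correction D²φ(x₁, x₁).
The implementation caps k at 2 — mapping uses k = 1, and the k = 2 action
exists for verification of the action axioms; no quintic-spline
reconstruction is built on top of it.

Tangents of a polyline branch are **one-sided**: both endpoints of a segment
carry the segment's unit chord, so an interior knot has a (generally
different) derivative on each side. This is the piecewise-linear reading of
an SWC file and deliberately permits tangent discontinuity at knots; a C¹
alternative (averaged tangents at interior knots) would smooth the *source*
representation and is not what this package computes. Mapped tangents
Dφ(x)u are used as-is — they are derivatives with respect to the source
arc-length parameter, and are generally not unit norm after mapping.

## The three mapping methods

Per segment [x₀, x₁] with L = |x₁ − x₀| and unit chord u:

* **ground truth** — sample the source segment at the parameter set
  S = {0, 2, 4, …} ∪ {L} (µm) and map each sample through φ;
* **order 0** — map the endpoints; reconstruct with the straight line
  through φ(x₀), φ(x₁); sample at S;
* **order 1** — additionally map the tangents dy₀ = Dφ(x₀)u,
  dy₁ = Dφ(x₁)u; reconstruct with the unique cubic Hermite interpolant
  (SciPy's `CubicHermiteSpline`) matching both positions and tangents;
  sample at S.

All three use the identical parameter set, so their outputs are directly
comparable, and at the knots all three equal φ(knot) exactly — mapping error
is purely a between-knot phenomenon. Interior multiples of the sampling
spacing are kept strictly below L (the naive loop would overshoot the
segment), and multiples within 1e-3 µm of L are dropped so dense traces
never carry near-degenerate final segments. Whole-trace ground truth is
equivalent to upsampling the source to ≤ 2 µm node spacing and applying
zeroth-order mapping.

When no analytic Jacobian is available it is approximated by forward finite
differences, (φ(x + h eⱼ) − φ(x))/h per column — four map calls. Default
steps: 1e-5 µm for analytic maps, 1e-3 µm for interpolated displacement
fields (whose trilinear cells are 100 µm, so the step stays well inside one
cell); the step is exposed on the CLI (`--fd-step`). Forward differences are
exact for affine maps and O(h) otherwise; the error decreases linearly in h,
which the tests audit on quadratic maps.

## Error bounds

Two computable worst-case bounds on the sup deviation between the transformed
curve f = φ∘c and its reconstruction:

* **Jacobian bound** (zeroth order, C¹ maps, piecewise-linear c): per knot
  interval, ½(|Dφ(c(t)) − I| · |tᵢ − tᵢ₋₁| + |εᵢ − εᵢ₋₁|), with
  εᵢ = c(tᵢ) − φ(c(tᵢ)) and the spectral norm for matrices; the bound is the
  max over intervals of the sup over t. The sup over continuous t is
  approximated by dense probing (default 100 probes per interval), so the
  computed number is a lower estimate of the true sup — the soundness tests
  use ≥ 50 probes and a 1% slack. Intervals are indexed [tᵢ₋₁, tᵢ] for
  i = 2…n (the source statement's index range starts at 0 while knots are
  numbered from 1; we read it as the n − 1 genuine intervals).

* **Derivative bounds** (C⁴ maps): with δ the maximum knot spacing and
  Mₖ = max |∂ₜ⁽ᵏ⁾fⱼ| over coordinates,

      bound0 = (3/4) M₄ (δ/2)⁴ + (3/2)(δ/2)² M₃ (δ/2) + (3/2)(δ/2)² M₂
      bound1 = (3/4!) M₄ (δ/2)⁴

  bound1 ≤ bound0 always, with ratio → 1/6 as M₂, M₃ → 0. The arithmetic is
  exposed directly on user-supplied maxima (keeping the statement testable in
  isolation) and end-to-end through an estimator that evaluates f on a dense
  probe grid per segment (each segment of a piecewise-linear source is a
  piecewise-C⁴ piece of f) and takes central finite differences of orders
  2–4. M₂ and M₃ enter bound0 evaluated at the knots; the estimator reports
  grid-wide maxima instead, an upper estimate that keeps the computed bound
  conservative. Default probe spacing 0.5 µm balances truncation against
  round-off amplification in the fourth-difference stencil.

The convergence content of the bounds — O(δ²) for zeroth order, O(δ⁴) for
first order — is verified empirically: log–log slopes of sup error versus δ
over δ ∈ {2, 4, 8, 16} µm under a smooth sinusoidal test map come out at
1.95 and 3.90.

## Random large deformations

The generator follows the LDDMM recipe at flow fidelity: iid Gaussian
momenta (std σ, µm/time) on a regular grid are smoothed with a Gaussian
kernel into a velocity field, which is integrated over unit time by an
N-step Euler flow of the grid points; the resulting displacement field is
interpolated trilinearly. This is a deliberate simplification — exact
geodesic (EPDiff) shooting with momentum conservation is out of scope; the
mapping algorithms and bounds are agnostic to how φ was produced, and what
the experiments need is a family of large smooth deformations whose
magnitude is controlled by a single scale σ.

Defaults: grid spacing 100 µm, kernel width 500 µm, 10 Euler steps, grid
centered at the origin and required to cover the traces plus one kernel
width of margin. Out-of-grid queries raise rather than extrapolate — silent
extrapolation would corrupt mapping experiments.

Two numerical safeguards:

* the velocity is tapered smoothly (half-cosine ramp) to zero over one
  kernel width at each grid face, so the flow never crosses the boundary,
  where the velocity interpolant would otherwise kink; traces live in the
  untapered core;
* every generated map passes a local invertibility audit — positive Jacobian
  determinant at all grid nodes (central differences). On failure the
  velocity amplitude is halved with a warning, and repeated failure raises.

The momentum-to-velocity kernel normalization is a convention, so the
absolute displacement scale is a gauge choice: the smoothed field is rescaled
so its component standard deviation equals `amplitude_gauge · σ`, with
amplitude_gauge = 0.25 by default — chosen so the strongest study level
(σ = 640 µm/time) sits comfortably inside the diffeomorphic regime (observed
minimum grid determinants ≈ 0.5) while deformation magnitude stays linear in
σ. With these defaults the median grid displacement runs from ≈ 12 µm at
σ = 80 to ≈ 100 µm at σ = 640. Deformations from differently normalized
kernels can be stronger per unit σ; only the σ-relative behavior (linearity,
monotonicity) is meaningful across conventions. The generator is a pure
function of its config — identical configs give bit-identical fields.

## Evaluation

* **Discrete Frechet distance**: the standard O(nm) dynamic program over
  monotone couplings (rolling rows); validated against exhaustive coupling
  enumeration on short polylines. Trace-level distance is the max over
  matched branches; mappings of a common source are matched by the shared
  source decomposition (the library API carries the correspondence
  explicitly, so no re-decomposition of mapped outputs is needed).
* **Morphometrics**: path angle at single-child, non-root nodes (angle
  between the directions toward parent and toward child; straight = 180°),
  branch angle at bifurcations (pairwise child directions), tortuosity per
  branch (arc length over endpoint distance, ≥ 1), per-edge segment length.
  These definitions are fixed here and used consistently; the scientific
  endpoint is *distribution comparison* via the two-sample
  Kolmogorov–Smirnov statistic (sup ECDF distance, cross-checked against
  scipy), for which any internally consistent definition serves. Wilcoxon
  signed-rank and Bonferroni correction are exposed as thin scipy wrappers.

A caveat discovered in testing and worth keeping in mind: the KS statistic is
rounding-brittle on distributions with point masses. An identity-level
mapping reproduces ground truth to ~1e-9 µm, yet KS on *segment lengths* can
be large because the dense 2-µm lengths form a point mass that arithmetic
noise shifts sideways across the ECDF step. Position-level comparisons and
the continuous quantities (path angles) are the meaningful checks in that
regime.

## Synthetic traces

Branches are integrated random walks of the unit tangent: per step of
(jittered) length equal to the sampling period, the tangent turns by
curvature_scale × step in a random perpendicular direction. Later branches
sprout from random interior nodes with a fresh random direction. Defaults —
5 branches of 20–40 nodes, 10 µm mean sampling period (±20% jitter),
curvature 0.005 /µm (200 µm radius of curvature), 1 mm spatial extent with
soft inward steering at the boundary — emulate desk-scale reconstructions of
fairly straight axonal arbors at the sampling regime where the choice of
mapping order starts to matter. What the generator does **not** emulate:
real somas and type annotations, realistic branch-order statistics, tissue
anisotropy, tracing noise, and multi-millimeter axon collaterals of real
whole-brain reconstructions. Passing tests therefore demonstrate the
numerical properties of the mapping machinery, not fidelity to any specific
dataset; the real-data workflow (user-supplied SWC files through the same
CLI) exists but is not exercised by the test suite.

## Experiment protocols

* **σ sweep**: traces are centered at the origin (mean of node positions —
  a convention; bounding-box centering would differ immaterially for these
  near-isotropic trees). One deformation per (σ, replicate seed) is applied
  to all traces, with momentum noise shared across σ within a replicate so
  the deformation family scales with σ. Recorded per (trace, σ, method):
  trace Frechet error versus ground truth, KS statistics of the four
  morphometric quantities, mean sampling period, and provenance (seeds,
  configs). Desk scale is 20 traces × 4 σ levels × 1 replicate (~40 s).
* **Node removal**: candidates are non-branching, non-terminal nodes with
  path angle above 170°. For each, the single segment parent→child is mapped
  with both methods and compared (discrete Frechet on the dense 2-µm
  samplings) against the ground-truth mapping of the original two-segment
  span; reported is the fraction of candidates with error ≤ 1 µm per method.
  The ground truth is span-level (the two segments adjacent to the removed
  node), and candidates are assessed one at a time — removing all of them
  jointly is a different, harsher experiment. No candidates yields an
  empty-result flag, not an error.

## Known limitations

* The first-order path needs only the Jacobian; order-2 jet actions require
  an analytic Hessian (no finite-difference fallback) and have no
  reconstruction path.
* Trilinear displacement interpolation makes generated fields only piecewise
  smooth; across-cell kinks limit how much of the O(δ⁴) advantage
  first-order mapping can realize under *generated* (as opposed to analytic)
  deformations. The observed advantage under generated fields is a factor of
  ~2 in median Frechet error rather than orders of magnitude.
* The computed Jacobian-bound and derivative-maxima estimates are
  probe-grid approximations: dense enough to be reliable for smooth maps,
  but formally a lower estimate of a sup (bound probing) or an upper
  estimate of knot maxima (derivative estimator, conservative direction).
* Loop-containing graphs and multi-point soma contours are out of scope;
  somas are ordinary nodes.
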