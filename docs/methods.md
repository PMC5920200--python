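# Methods

## The model and what the package computes

Cardiac tissue is described by the bidomain picture: co-located
intracellular and extracellular conductors with tensors `G_i` and `G_e`
(mS/cm), coupled through the membrane with capacitance `C_m` (µF/cm²) and
surface-to-volume ratio `β` (cm⁻¹).  Propagation itself is integrated with
the monodomain reduction

    C_m ∂t Vm = β⁻¹ ∇·(G_m ∇Vm) − I_ion(Vm, y),   G_m = G_i G_e / (G_i + G_e),

with no-flux boundaries on the heart surface.  The surface ECG is a
zero-sum combination `V(t) = Σ c_i φ_e(x_i)` of the extracellular potential
at electrode positions, where `φ_e` obeys the elliptic problem

    ∇·((G_i+G_e) ∇φ_e) = −∇·(G_i ∇Vm)

over the whole torso with a no-flux outer boundary.  The package computes
`V(t)` four ways:

* **FSF** — solve the elliptic problem on the simulation grid at every
  output step and sample the electrodes.
* **FSC** — project the nodal source currents onto a nested coarser grid
  (trilinear partition-of-unity weights, exactly conservative) and solve
  there.
* **LF / LFS** — solve once per lead for the lead field `Z`
  (`∇·((G_i+G_e)∇Z) = Σ c_i δ(x−x_i)`, unit total current `Σ|c_i| = 2`),
  then evaluate `V(t) = ∫ ∇Z · G_i ∇Vm dx` over the myocardium at every
  step.  `∇Z` may be block-averaged by a factor `n` either plainly (LF) or
  tissue-selectively (LFS: blocks containing myocardium average only their
  myocardial elements, because `∇Z` jumps at conductivity interfaces such
  as myocardium–lung).

Because the discrete elliptic operator is exactly symmetric, the discrete
Green identity `Σ c_i φ_e(x_i) = ⟨Z, b⟩` (with `b` the assembled right-hand
side) holds to solver tolerance — this reciprocity is the package's
central invariant and is tested directly.

## Discretization

Structured hexahedral grids; element-constant tensors built in the local
fiber frame, `G = σ_L ff' + σ_T ss' + σ_C nn'`; potentials on nodes.  The
operator `∇·(G∇·)` is a 19-point stencil:

* Face-neighbor couplings: conservative flux form, with the diagonal
  tensor entry averaged over the up-to-4 elements incident to each edge
  (quarter-section conductances).  No-flux boundaries arise naturally from
  the zero conductivity of exterior elements.
* Edge-diagonal couplings (cross-derivative terms `∂_a(G_ab ∂_b·)`):
  face-diagonal differences weighted by `G_ab` averaged over the **two
  elements sharing each face diagonal**, with a diagonal correction that
  zeroes every row sum exactly.  This 2-element support means a coupling
  exists only between corners of an element carrying that tensor entry, so
  the intracellular operator never references nodes outside the
  myocardium — which keeps the discrete Eq-8 sources consistent with the
  element quadrature used for the lead-field ECG (on smooth fields the two
  ECG routes agree to solver tolerance).

The scheme is second-order consistent on smooth fields (verified by a
manufactured-solution order measurement, both isotropic and with rotated
anisotropic tensors), exactly symmetric by construction (the `(A+Aᵀ)/2`
symmetrization step is retained as an enforced contract but is a no-op),
and annihilates constants row-wise exactly.  Matrices are stored in
conductance form (entries in mS; `A·u` is a nodal current in µA); the
density form divides by per-node control volumes `(incident elements)/8 ·
h³`, which reproduces `σ(u_{i−1}−2u_i+u_{i+1})/h²` on a 1-D chain.

Node typing follows the element mesh: every corner of a myocardial element
is a myocardial node, and the nodal `β` is the 8-incident-element average
(zero for non-myocardium), so boundary nodes carry proportionally less
membrane.  The monodomain operator restricted to myocardial nodes lumps
any would-be outside couplings onto the diagonal (none arise with the
shipped stencil), keeping the resting state an exact discrete equilibrium.

Per-element gradients (`∇Z` and `∇Vm` in the ECG quadrature) use the same
4-edge-average rule per component, so the native-resolution evaluation is
internally consistent.

## Elliptic solves

The pure-Neumann system is singular with a constant null space.  The
solver restricts to the matrix-graph active set, projects the constant out
of the right-hand side, and returns zero-mean solutions over conducting
nodes.  Systems up to ~35k unknowns are factorized once (sparse LU on the
one-node-pinned system) and reused; larger systems use Jacobi-
preconditioned CG with warm starts (linear extrapolation from the two
previous frames), falling back to MINRES.  Every solve is verified against
the relative-residual contract (default 1e-8) and raises on failure.
Sources below the assembly rounding floor (e.g. a frame entirely at rest)
are treated as exactly zero rather than solved.

The sign convention follows the operator equation as written: `A Z = +c`
with `A ≈ ∇·(G∇·)`, whose free-space Green's function is `−1/(4πσr)`; the
analytic-limit check uses that sign.

## Membrane model and integration

The membrane interface requires `I_ion(Vm, state)`, per-gate `(y_∞, τ)(Vm)`
(advanced with the Rush–Larsen exponential update, exact for frozen rates
and unconditionally bounded in [0,1]), and rates for non-gating variables
(forward Euler).  The shipped default is a two-variable Mitchell–Schaeffer
model on the normalized potential `u = (Vm + 80 mV)/100 mV`:

    du/dt = h u²(1−u)/τ_in − u/τ_out,
    h → 1 with τ_open below u = 0.13, h → 0 with τ_close above it,

with `τ_in = 0.3`, `τ_out = 6`, `τ_open = 120`, `τ_close = 150` ms,
`C_m = 1 µF/cm²`.  It yields a ~250 ms action potential, an exact resting
fixed point, and a conduction velocity of ≈0.46 m/s at `σ` from the default
tissue table — adequate surrogate physiology for ECG-methodology work; it
is *not* a human ventricular cell model.  Any ionic model implementing the
interface can be substituted.

The explicit step follows the canonical order: diffusion current, membrane
state update, ionic current, forward-Euler `Vm` update (with the stimulus
current added inside the window).  Defaults: `dt = 10 µs`, output every
100 steps (1 ms cadence), 500 ms duration.  Stability of the explicit
diffusion step is the user's responsibility; at the shipped resolutions
the diffusion limit is far above 10 µs.

The stimulus is a transmembrane current injection (default 30 µA/cm² for
2 ms in a sphere of radius two elements); the seven default stimulus sites
sit mid-wall around the shell plus one at the apex, emulating distinct
activation origins.

## Conductivities

Defaults (mS/cm; β in cm⁻¹):

| tissue     | σ_iL | σ_iT | σ_iC | σ_eL | σ_eT | σ_eC | β   |
|------------|------|------|------|------|------|------|-----|
| myocardium | 3.0  | 0.3  | 0.3  | 3.00 | 1.20 | 1.20 | 800 |
| body       | 0    | 0    | 0    | 2.00 | 2.00 | 2.00 | 0   |
| blood      | 0    | 0    | 0    | 6.00 | 6.00 | 6.00 | 0   |
| lung       | 0    | 0    | 0    | 0.50 | 0.50 | 0.50 | 0   |
| muscle     | 0    | 0    | 0    | 3.55 | 3.55 | 0.44 | 0   |

Skeletal muscle is realized with its across-sheet axis along the local
torso surface normal (low radial, high in-plane conductivity).

## The synthetic phantom

The default phantom is an 8 cm box torso at 2 mm spacing (40³ elements,
one exterior element of margin): a truncated-ellipsoid myocardial shell
(outer semi-axes 16×16×20 mm, 8 mm wall, closed by a basal cap) around a
blood cavity, two ellipsoidal lungs that abut the shell (providing the
myocardium–lung interfaces the LFS rule targets), a 10 mm subcutaneous
muscle layer under the lateral faces, and isotropic bulk body.  Myocardial
fibers rotate linearly from −60° (endo) to +60° (epi) within planes
tangent to the shell — a standard rule-based surrogate, not a reproduction
of any measured architecture.  Electrodes: the 9 standard positions (RA,
LA, RL, LL high/low on the lateral faces; V1–V6 across the anterior face
at heart level), snapped to the nearest surface node; the 12 standard
leads (with Wilson's central terminal for the precordials) carry exact
rational coefficients so `Σc = 0` and `Σ|c| = 2` hold exactly.

Smaller companions ("small", 20³ at 4 mm; "tiny", 10³ at 8 mm) share the
physical geometry for fast tests; the propagation strand is a 2×2-element
myocardial bar at 0.2 mm spacing (the reaction-diffusion resolution at
which a Mitchell–Schaeffer wavefront, ~0.25 mm wide, is resolved).

What the phantom does **not** emulate: patient anatomy (no atria, no
bones, box torso), measured fiber fields, heterogeneous action-potential
durations, and realistic lead fields of a human thorax.  Passing tests
demonstrate correctness and internal consistency of the numerics and the
methodology trends (downsampling error growth, LFS superiority near
tissue interfaces), not clinical fidelity of the traces.

## Numerical choices and tie-breaks

* Coarse companion mesh (FSC): majority-vote tissue per `r³` block (ties →
  smallest label), fiber frames from the block orientation tensor's
  principal eigenvector with re-orthogonalized sheet/normal axes.
* Coarse electrodes snap to the nearest conducting surface node of the
  coarse mesh (plain index division can land in the exterior).
* Downsampling with non-divisible dimensions: trailing partial blocks
  average the elements available.  Blocks without conducting elements
  store zero vectors and are never referenced by the quadrature.
* `fiber_variability` blocks without myocardium are flagged invalid and
  carry NaN, never zero; the coarse direction is the orientation-tensor
  eigenvector (sign-invariant).
* Dirac electrode sources are unit nodal loads, with no spreading;
  analytic comparisons exclude probes within 5 spacings of an electrode.
* Muscle-layer face assignment at box edges breaks ties in axis order
  (x before y); deterministic.
* NaN anywhere in a trace or state is a hard error with location, never
  silently dropped.

## Problem sizes used in the checks

Reciprocity runs on the 20³ phantom (21³ nodes, direct solver, error
~1e-13 against the 1e-5 requirement).  The quadrature-fidelity and
downsampling checks run the full seven-site, 500 ms, 12-lead protocol on
the default 40³ phantom; LF-vs-FSF RelDif is reported as the average over
the seven activation sequences.  At 2 mm the residual (≈0.015–0.02) is
dominated by the covariance between the 4-edge-average element quadrature
and the stencil's bilinear form across sub-element-wide wavefronts; it
shrinks roughly linearly with spacing, consistent with the sub-percent
agreement reported for such comparisons on meshes an order of magnitude
finer.  The analytic point-source check uses an 80³ homogeneous box with a
centered pair 8 spacings apart and near-field probes (≥5 spacings from
each electrode, ≥10 from the boundary, within 10 of the pair midpoint);
the error is reported as a pooled relative L2 over the probe set because
the pointwise relative error is ill-conditioned on the dipole's null
plane.  Conduction-velocity scaling uses the 0.2 mm strand at `dt = 10 µs`
with all myocardial conductivities quadrupled.

## Known limitations

* The lead-field and full-solution routes share the same discrete
  operator family; agreement does not validate the discretization against
  a continuum reference beyond the convergence and analytic-limit checks.
* The monodomain model receives no bath loading (φ_e never feeds back
  into the Vm update), matching the one-way usage of the coarse solution.
* At 2 mm the depolarization front is not resolved; propagation is
  grid-slowed and the ECG morphology is phantom-specific.  The strand at
  0.2 mm is the resolution at which propagation quantities (CV scaling)
  are meaningful.
* Elements with off-diagonal conductivity touching the outermost grid
  layer would lose cross-couplings pairwise (row sums stay exact); all
  shipped generators keep anisotropic tissue at least two elements from
  the boundary.
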