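# Methods

`lvmetad` implements localized-volume well-tempered metadynamics
(LV-MetaD) at desk scale: the enhanced-sampling protocol used to map
ligand-binding free-energy landscapes on shallow protein surface
pockets, rebuilt on toy host–guest potentials where every quantity has
an independent brute-force truth. This note records the model, the
parameters that matter, the numerical choices, and what the toy
systems do and do not demonstrate about real all-atom runs.

## The model

### Dynamics

The guest is a point particle of mass m (amu) moving under a potential
U(r) (kcal/mol) plus external forces (bias and restraint walls),
integrated with underdamped Langevin dynamics in the BAOAB splitting:

    B: v ← v + (Δt/2)·F/m
    A: x ← x + (Δt/2)·v
    O: v ← c₁·v + c₂·ξ,   c₁ = e^(−γ_f Δt),  c₂ = √(k_BT/m·(1−c₁²)),  ξ ~ N(0,1)
    A: x ← x + (Δt/2)·v
    B: v ← v + (Δt/2)·F(x_new)/m

The O part is the exact Ornstein–Uhlenbeck update, so the integrator
is stable at the hill-deposition strides used and exactly reproducible
from these formulas. One force evaluation per step (the final B reuses
the cached force at the new position). Units are Å, ps, amu, K,
kcal/mol with k_B = 0.0019872041 kcal/mol/K and 1 kcal/mol = 418.4
amu·Å²/ps². Randomness comes from a single `numpy` PCG64 generator
seeded in the run configuration; identical seeds give bit-identical
trajectories and output files.

### Collective variables

The guest position is expressed in the host frame through three CVs
tied to a parabolic-solid restraint volume about a unit axis (aligned
with +x in the toy fixtures):

* **ρ** — distance between the guest and a reference point of the host
  (host centre by default; configurable, since the distance axis of
  the final projection may use a different reference subgroup, e.g. a
  metal-cluster site).
* **τ = r_⊥ / √(k·(a − a₀))** — dimensionless transverse coordinate,
  where a is the axial coordinate from the volume origin, a₀ the
  paraboloid apex offset, r_⊥ the distance from the axis, and k (Å)
  the paraboloid steepness. τ = 1 is the paraboloid surface
  r_⊥² = k·(a − a₀); τ < 1 is inside. This functional form is this
  package's interpretation of the parabolic-solid shape parameter:
  it makes τ dimensionless with O(0.1) fluctuations, consistent with
  a Gaussian hill width of 0.04 in τ.
* **θ** — azimuth of the transverse projection about the volume axis,
  measured in the plane perpendicular to the axis from a deterministic
  reference direction (+y for an x-axis), wrapped to (−π, π] and
  treated as periodic everywhere. Measuring θ in the plane
  perpendicular to the axis (rather than literally in the x-y plane)
  is the physically meaningful choice for a paraboloid about x.

On the axis θ is defined as 0 (measure-zero tie-break) and the ∂θ/∂r
gradient is regularized by replacing r_⊥² with max(r_⊥², ℓ²),
ℓ = 0.1 Å, capping its magnitude at 1/ℓ and avoiding NaN forces.

`invert_cvs` maps (ρ, τ, θ) back to Cartesian coordinates by
intersecting the (τ, θ) ray with the host-centred sphere of radius ρ,
taking the root with the largest axial coordinate when several exist;
it exists purely as a round-trip oracle for the forward map (round
trips agree to < 1e−10 Å).

### Restraint walls

The localized volume is enforced by half-harmonic walls in CV space:
k_w·(ρ−ρ_max)² beyond ρ_max and k_w·(τ−τ_max)² beyond τ_max, zero
inside, with θ free. A third half-harmonic wall below an axial
coordinate a_min (default a₀ + 0.5 Å) keeps the guest away from the
paraboloid apex, where τ and its gradient are singular; without it a
fluctuation behind the apex would produce unbounded forces. All three
walls enter the quadrature oracle as part of the total potential, so
they cancel exactly in every simulation-vs-oracle comparison. Under a
wall of stiffness k_w the Boltzmann tail beyond the wall is Gaussian
with width √(k_BT/k_w); excursions past 3 of those widths are rare
(≲1e−2 of frames in practice, with the residual coming from bias
pushing against the wall).

### Well-tempered bias

Gaussians of height h and widths (σ_ρ, σ_τ, σ_θ) are deposited every
τ_dep picoseconds at the current CV point, with the well-tempered
schedule h = h₀·exp(−V(s,t)/k_BΔT), ΔT = (γ−1)T. The bias converges
to −(1−1/γ)·F(s) up to a constant, so γ/(γ−1)·V + F is asymptotically
flat. The bias and its CV-gradient are evaluated by direct summation
over all deposited hills (vectorized); the bias force on the guest is
−Σ_cv (∂V/∂cv + ∂W/∂cv)·∇cv via the analytic CV gradients. Δθ is
wrapped before entering the Gaussian. In 1D mode the dynamics force
may instead come from a grid cache of the bias (node values V and
dV/dx updated incrementally per hill; cubic Hermite in between, error
O(h⁴·V⁗) ≈ 1e−6 kcal/mol at the default spacing σ/10 — tested against
direct summation), which makes the evaluation O(1) per step; recorded
COLVAR bias values and hill heights always use exact direct summation.

Library defaults mirror a published all-atom protein–ligand protocol:
h₀ = 0.287 kcal/mol, stride 1 ps, widths (1 Å, 0.04, π/8) for
(ρ, τ, θ), γ = 20 at 298 K. The toy fixtures override them (below)
because the toy CV ranges and barriers are an order of magnitude
smaller than an all-atom complex's.

### Observables

* **d** — guest-to-reference distance, reported in nm (ρ/10 for the
  default reference).
* **N** — H-bond/salt-bridge count: N = Σ_pairs s(r_ij) over a
  configured donor–acceptor pair list, with the rational switching
  function s(r) = (1−x^n)/(1−x^m), x = (r−d₀)/r₀, defaults n = 8,
  m = 12, d₀ = 0, r₀ = 2.5 Å. s is evaluated as the analytic limit
  n/m when |1−x^m| < 1e−10 (the printed formula is 0/0 at x = 1) and
  clamped to 1 for r < d₀ (a distance below d₀ is a fully formed
  contact). The per-pair occupancies double as pose fingerprints for
  a deterministic leader clustering (threshold on Euclidean
  fingerprint distance, frames visited in order, medoid = member
  minimizing summed within-cluster distance).

### Reweighting and analysis

Frames are unbiased with the time-dependent estimator

    w_i ∝ exp(β·(V(s_i, t_i) − c(t_i))),
    c(t) = (1/β)·ln[ Σ_s e^(βγV(s,t)/(γ−1)) / Σ_s e^(βV(s,t)/(γ−1)) ],

with the grid sums accumulated incrementally hill by hill (the
Gaussians are separable across CV dims) and stabilized by
max-subtraction. The grid must resolve the hills (≥4 cells per
smallest σ, enforced); halving the spacing changes c(t) by < 0.01
kcal/mol on the fixtures. V(s, t) contains hills deposited strictly
before t, matching the run loop's convention of recording the COLVAR
bias before any hill deposited at the same timestamp; c at a frame
time is the nearest preceding evaluation (0 before the first hill).
Only the final window of the trajectory is weighted (the filling
phase carries no useful equilibrium information): the library default
window is the final 2/13 of the run, mirroring common practice of
discarding the first ~85% of a long production run; the toy fixtures
use the final half, since their runs are short and their c(t) has
plateaued by then.

The weighted ensemble is projected onto (d, N): F(cell) =
−k_BT·ln(Σ w), min-shifted to 0, with unsampled cells flagged (NaN),
and a Kish effective sample size per cell. Errors come from block
averaging: the window is split into n contiguous time blocks (default
5), each block yields its own normalized FES, and the per-cell error
is the weighted standard error of F across blocks, weighted by block
weight mass (unbiased weighted variance scaled by Σŵ²; equal masses
reduce to std/√n). Cells sampled by fewer than two blocks are
flagged, not zeroed.

Basins are found by watershed: steepest-descent assignment on the
8-connected grid (plateau ties resolved toward the lower flat index),
minima above global-min + depth_cutoff merged into the neighbour
across the lowest shared saddle; an optional minimum-prominence
threshold additionally merges sampling-noise ripples. Labels are
ordered by basin minimum.

The binding free energy between two disjoint regions (windows on
COLVAR columns) is ΔG = −k_BT·ln(W_bound/W_unbound), negative when
binding is favourable; its error is the block standard error of the
per-block ΔG. An optional standard-state term k_BT·ln(V_unbound/V°),
V° = 1660 ų, references the result to 1 M; it is off by default
(whether a published unbinding number includes it is often
unstated), and the geometric unbound volume inside the restraint is
computed by grid counting.

## Toy study conditions (fixture registry)

All magnitudes live in `lvmetad.fixtures`; they were chosen once as a
realistic desk-scale analog and the run lengths by convergence
diagnostics (flat c(t) plateau, stable ΔF under window changes).

**Confined 1D double well** — quartic with 5 k_BT barrier, 1 k_BT
asymmetry (right minimum raised), minima 4 Å apart, plus symmetric
half-harmonic confinement walls at |x| = 3 Å (k = 20 kcal/mol/Ų).
The walls are the 1D analog of the localized volume: without them the
well-tempered bias pushes the walker far up the quartic wings (the
explored range self-consistently extends to U ≈ γ·k_BT·O(few)),
inflating the free-energy range the bias must fill and slowing
convergence several-fold. The oracle integrates the same confined
potential, so the walls cancel identically. Langevin: Δt = 4 fs,
friction 1/ps, 40 amu, 298 K. Metadynamics: h₀ = 0.025 kcal/mol,
σ_ρ = 0.15 Å, stride 0.5 ps, γ = 6, 16000 hills (8 ns), reweighting
the final half. The hill width obeys σ² ≪ k_BT/U″ over the checked
range — a wider hill cannot represent the quartic flank curvature and
leaves a systematic (1−1/γ)·σ²U″/2 bump in the converged bias; γ = 6
keeps late hills adaptive (larger γ re-explores the steep wings,
smaller γ freezes residual corrugation), and the small h₀ keeps the
stationary corrugation of the converged bias well inside the
half-k_BT band the convergence tests demand. These runs use the 1D
grid-cache bias evaluation (below).

**3D host–guest** — a rigid host of three 12-6 sites (an apolar core
at the origin, depth 0.8 kcal/mol, range 2 Å; two polar flanks at
(0.9, ±0.7, 0), depths 1.6 and 1.0, range 2.3 Å) forming a single
~2.7 kcal/mol pocket on the +x side; the guest binds near (3.1, 0, 0).
Parabolic solid: origin at the host core, axis +x, k = 1.5 Å,
a₀ = −0.5 Å, a_min = 0, ρ_max = 6 Å, τ_max = 1, walls 10
kcal/mol/unit². The polar sites define the default contact pairs for
N. Metadynamics: h₀ = 0.1 kcal/mol, widths (0.4 Å, 0.12, π/4),
stride 1 ps, γ = 6, 4000 hills (4 ns), reweighting the final half;
same Langevin parameters. The 1 ps stride gives the guest a couple of
velocity-relaxation times between depositions, keeping the
quasi-static assumption of the reweighting estimator honest; the run
length is chosen so the block standard error of ΔG still reflects the
dominant (statistical) error — at much longer lengths the blocks,
which share one bias potential, become near-identical and the block
error stops seeing the residual bias-shape error. The bound region is
ρ < 3.5 Å, the "solvated" reference the 4.5–5.5 Å shell, where the
12-6 tails are < 0.05 kcal/mol. Runs start from the relaxed pocket
minimum (Nelder–Mead on the host potential from a point down the
axis), the toy analog of starting from a deposited pose.

## The oracle

`reference_free_energy` computes −k_BT·ln(∫_A e^(−βU)/∫_B e^(−βU)) by
deterministic midpoint-rule quadrature (4000 points in 1D, 140³ in
3D) over the same total potential the sampler feels (host + walls),
with a Richardson-style discretization estimate from halving the
resolution (< 0.01 kcal/mol on the fixtures, provided region edges
are not pathologically incommensurate with the grid). It shares no
code with the sampling or reweighting paths.

## What the toys show — and what they do not

Passing tests demonstrate that the bias deposition, CV geometry,
restraints, reweighting, error analysis and ΔG bookkeeping are
mutually consistent and converge to independently computed truths on
systems with one slow degree of freedom and, in 3D, a single smooth
pocket. They do not demonstrate: force-field realism, explicit
solvent and its relaxation times, multiple competing poses with
orthogonal slow modes, protein flexibility under the volume bias, or
the hundreds-of-nanoseconds convergence behaviour of an all-atom
complex. The analysis half (c(t), weights, FES, blocks, basins, ΔG)
reads PLUMED-dialect HILLS/COLVAR text files, so it applies unchanged
to externally produced all-atom runs.

## Numerical choices and degenerate inputs

* Hills with h₀ = 0 are never stored: the run degenerates exactly
  (bit-identically for a fixed seed) to the unbiased trajectory.
* Hill times must strictly increase; equal or decreasing times are a
  sequencing error.
* Non-finite forces or CVs abort the run naming the step and the last
  good COLVAR frame.
* The τ wall below the axial clamp a₀ + 0.25 Å is evaluated at the
  clamped axial coordinate (the axial wall dominates there); the
  12-6 site terms clamp d ≥ 1e−3 Å so grid quadrature never overflows.
* Zero-weight regions make ΔG undefined (an error, not a NaN); blocks
  missing a region are dropped from the ΔG error estimate; a
  single-block error is reported as NaN.
* Floats are written as %.6f (CVs, times) and %.10g (energies,
  heights, weights, errors) so re-running a config reproduces files
  byte for byte; every artifact opens with a provenance block (tool
  version, config hash, seed).

## Known limitations

* The 3D bias is summed directly over hills; the grid cache exists
  only for 1D, so 3D runs much longer than ~10⁴ hills get slow.
* Block errors assume blocks longer than the correlation time; the
  fixture runs satisfy this (error plateaus between 5 and 10 blocks),
  short custom runs may not.
* The watershed merge rule is greedy (one merge per pass, lowest
  saddle first); pathological flat landscapes with many exactly equal
  saddles could depend on the documented tie-breaks.
* `cluster_poses` is O(n²) in cluster size through the medoid step.
* Externally produced HILLS files are assumed to share one bias
  factor; multiple-walker or varying-γ files are out of scope.
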