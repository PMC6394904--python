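# Methods

## Model

Two morphogens live on the surface of a developing microspore: a
short-range activator A and a long-range inhibitor H (concentrations in
μM).  Their dynamics follow the Gierer–Meinhardt activator–inhibitor
system

    ∂A/∂t = D_A ∇²A − μ_A A + ρ₁ (A + ρ_A)² / H
    ∂H/∂t = D_H ∇²H − μ_H H + ρ₂ A² + ρ_H

with wild-type constants D_A = 1.1, D_H = 54 μm²/s, μ_A = 0.21,
μ_H = 0.6 s⁻¹, ρ₁ = 0.2 s⁻¹, ρ₂ = 0.2 μM⁻¹s⁻¹, ρ_A = 0.003 μM,
ρ_H = 0.0001 μM/s (`GMParameters` defaults).  ρ₁ and ρ₂ share one
magnitude and are swept jointly as a single knob `rho`.  Spikes — localized
activator maxima — stand in for aperture centers; equally spaced
equatorial spikes correspond to the wild-type three-aperture pattern of
*Arabidopsis* pollen.

Assumptions inherited from the model design: a single microspore; a
perfect sphere (or its equatorial circle) of constant size; constant
kinetics over a run; simulations run to steady state.

## Domains and discretization

The sole size descriptor is the front-view area a (μm²), the projected
disc area of the grain as imaged: a = πR².  The 1D domain is the full
equatorial circumference L = 2πR with periodic topology (default 256
nodes, spectral Laplacian via FFT).  The 3D domain is the whole sphere
surface (area 4a), discretized as a subdivided icosahedral mesh with the
cotangent-weight Laplace–Beltrami operator and lumped barycentric mass.
This mapping makes the linearly admissible modes match the observed spike
counts: at 550 μm² the fastest-growing ring mode is m = 3 and the
fastest-growing spherical-harmonic degree is l = 3.

Mesh adequacy was checked against spherical-harmonic eigenfunctions:
eigenvalue errors at subdivision 4 (2562 vertices) are ≤1% for l ≤ 5 and
2.4% at l = 8; subdivision 3 (642 vertices) gives 1.4% at l = 3–4 and 9%
at l = 8.  Single-run and stimulus work defaults to subdivision 4;
campaign sweeps default to subdivision 3 as the scaled-down lever, backed
by the refinement-stability checks below.

## Linear stability

The diffusion-free steady state (A*, H*) is found by bracketing bisection
on the activator balance with the inhibitor eliminated, using the
basal-term-free closed form A* = ρ₁μ_H/(ρ₂μ_A) to set the bracket; the
basal terms are retained because the governing equations include them.
The Turing conditions for a two-species system are trace < 0, det > 0,
D_H f_A + D_A g_H > 0, and (D_H f_A + D_A g_H)² > 4 D_A D_H det at the
steady state; when they hold, the unstable squared-wavenumber band is
bounded by the roots of D_A D_H k⁴ − (D_H f_A + D_A g_H) k² + det = 0.
For the wild-type constants the band is k² ∈ (0.01275, 0.16664) μm⁻².
The per-parameter robustness interval (the contiguous factor range around
1.0 keeping the criteria satisfied) is located by a log-spaced grid scan
refined by bisection to 10⁻³ relative precision; intersected over all
parameters it is [34.8%, 287.3%] of the wild-type values.

## Time integration

Initial conditions are (A*, H*) plus independent uniform noise of
±5×10⁻⁴ μM at every node (clipped at zero with a warning if an amplitude
would produce negative concentrations).

* Ring: ETD2RK (Cox–Matthews) in Fourier space.  The linear factor
  exp(−(D k² + μ)dt) is exact, so the growth-rate competition between
  modes is unbiased by the step size; the reaction terms are second-order.
* Sphere: backward-Euler IMEX on diffusion + decay with two-step
  Adams–Bashforth reaction terms.  The scheme is L-stable and its fixed
  points are exactly the discrete steady states, independent of dt.

Both steppers adapt dt from a local truncation-error estimate (target
10⁻⁴ relative to A*; predictor–corrector difference on the ring, AB2–AB1
difference on the sphere).  On the ring the error target tightens tenfold
while the pattern is saturating (amplitude above 0.5 A* and rate still
far from steady): that window is where near-degenerate modes compete and
spike merges are decided, and label distributions there are converged in
the tightened target (verified against 10⁻⁵ and 3×10⁻⁶) but not at the
base one.  On the sphere dt is additionally capped at
0.5 s while the perturbation amplitude is below 0.5 A*, because the
backward-Euler linear factor distorts growth rates at large dt and the
linear phase is where mode competition is decided; once the pattern has
formed the cap is released (to 4×dt_max = 8 s) and the error target is
relaxed tenfold, since only the fixed point matters from there.  Label
distributions were verified to be unchanged when the error target is
tightened to 10⁻⁵–3×10⁻⁶.

A run is steady when max-node |∂A/∂t|/A* (and likewise for H) stays below
steady_tol = 10⁻⁶ s⁻¹ over two consecutive 10 s windows without
increasing by more than 20% across them; the two-window, non-increasing
form matters because a near-homogeneous state with very small initial
noise passes through a rate trough (stiff modes decay before the
instability amplifies) that a single sub-threshold window would mistake
for steady state.  The time budget is t_max = 10⁵ s.
Formed sphere patterns drift extremely slowly toward mesh-pinned
orientations (the continuous rotational symmetry is weakly broken by the
mesh), so some large-domain 3D runs reach t_max with the pattern long
since formed but the drift rate still above threshold; these are recorded
as unconverged and classified anyway.  Divergence (any non-finite value
or max A > 10⁶ A*) is recorded as a failed run, never raised.

## Stimuli

Pre-patterning cues act on the activator only.  A spike stimulus is a
Gaussian bump amplitude·exp(−r²) in chord distance with a fixed unit
(1 μm) length scale; patterns are k = 1..4 equally spaced equatorial
bumps, four tetrahedral bumps, an equatorial band amplitude·exp(−z²)
(polar coordinate z), or a spatially uniform control.  Transient stimuli
(μM) add to the activator initial condition; continuous stimuli (μM/s)
add a time-invariant forcing to ∂A/∂t for the whole run.

## Classification

Steady activator fields map to a taxonomy of spike counts plus geometry
(none, equatorial, polar, tetrahedral, other_spikes, ring,
spike_plus_ring, elongated_tetra_edges, failed).  The cascade: a field is
unpatterned unless max(A) ≥ 2A* and min(A) ≤ 0.5A*; super-threshold
components (50% of max) are extracted on the mesh adjacency (periodic
runs on the ring), discarding fragments below 3 nodes or 3% of the
largest component; a component covering ≥300° around its best-fit great
circle is a ring; a component with principal-extent ratio ≥3 is
elongated (six of them pairing antipodally = tetrahedron edges); four
compact spikes with pairwise separations within ±15° of 109.47° are
tetrahedral; spikes coplanar with the center within 15° are equatorial;
two spikes ≥150° apart are polar.  All constants are named fields of
`ClassifierConfig`.

These thresholds operationalize a by-eye taxonomy.  The valley gate is
0.5 A* rather than a tighter value because densely packed spike patterns
(three spikes at 400 μm², four at 750 μm²) leave valley minima of
0.12–0.14 A*; a gate below that would misread genuine patterns as
unpatterned.

## Synthetic labeled fields

`synthetic_fields` builds static template fields for every taxonomy class
(Gaussian caps, equatorial bands, tetra-edge ridges) on a valley baseline
of 0.05 A* with peak 4 A*, randomly rotated per instance, plus uniform
noise expressed as a fraction of the peak.  The low baseline emulates the
valley depletion of converged patterns (the activator falls nearly to
zero between spikes); the ridge cross-section (σ = 1.6 μm) is kept wider
than the campaign-mesh vertex spacing so ridges stay resolved.  The
classifier recovers 100% of these labels with noise up to 10% of the
peak.  These fields validate the classifier and pipeline only: they have
no dynamics, perfectly symmetric geometry, and spatially white noise, so
passing them says nothing about solver accuracy — that is covered by the
dispersion-rate and refinement checks.

## Campaigns and reproducibility

Every campaign runs replicates with one pseudo-random stream per
replicate, seeded by the integer triple (base seed, condition index,
replicate index) via NumPy's SeedSequence, so any row of a campaign table
can be recomputed in isolation.  Campaign tables are long-form CSV (one
row per replicate) with a JSON manifest of every setting.

Problem sizes used by the test suite and the acceptance script (chosen as
desk-scale defaults; the full protocol is 25 replicates everywhere):
ring campaigns 25 replicates at 256 nodes; the full-range ring sweep 6
replicates per area; sphere wild-type runs 25 replicates (subdivision 4
in the acceptance script, 3 in the scaled test); the large-area sphere
sweep a reduced area grid with few replicates; stimulus checks a reduced
amplitude grid at subdivision 4.

## Known limitations

* The 4-spike/3-spike competition on the 750 μm² ring is close (the m = 4
  growth rate exceeds m = 3 by only ~3%), and transient four-spike states
  frequently coarsen to three; the modal 1D count at 750 μm² is therefore
  sensitive to the noise realization in a way the wild-type domain is not.
* Transient stimuli as specified (unit-width bumps, ~1 μm against a
  ~27 μm pattern wavelength) nucleate activity near their sites but do
  not enforce spike counts at any tested amplitude (10⁻⁵–10 μM): the bump
  covers only a few mesh vertices and projects less power onto the
  unstable subspace than the initial noise.  Continuous stimuli do
  enforce their patterns, with spikes at the forced sites, on the domain
  whose spontaneous count they match; a 3-spike forcing of 10⁻³ μM/s does
  not override the larger domain's preference for four tetrahedral
  spikes.
* Elongated (furrow-like) patterns occur only near the edge of the
  pattern-forming regime and are not robust, matching their rarity in the
  kinetics sweeps.
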