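# Methods

## Model

The package simulates `S` competing species with abundances
`u_i(x, t) >= 0` on a bounded habitat patch, obeying the
competition–diffusion system

    du_i/dt = D_i Δu_i + u_i (r_i − Σ_j a_ij u_j),    i = 1..S,

with absorbing (Dirichlet) boundary conditions `u_i = 0` on the patch
edge: the surrounding matrix is lethal, so individuals that disperse
across the boundary are lost. `r_i` is the intrinsic growth rate
(1/time), `D_i` the diffusion coefficient (length²/time), and `a_ij >= 0`
the per-capita effect of species `j` on species `i`; intraspecific
density dependence is fixed at `a_ii = 1`, so a single species
equilibrates at `u = r` in the absence of boundaries. Two-species
analyses use the inversely symmetric construction `a_12 = 1/a_21` with a
shared growth rate, so a single number `a_21 > 1` expresses species 1's
competitive dominance.

The mechanism under study is a *reverse* competition–colonization
trade-off. Boundary loss is a mortality flux proportional to `D_i`, so
near an absorbing edge a low dispersal ability becomes an advantage:
a species that is inferior in both competition and dispersal can hold a
peripheral band where the dominant species' dispersal mortality depresses
it, while the superior competitor-and-disperser holds the interior. All
abundances start equal, uniform and low (`u_0 = 0.1` by default), and the
system is integrated to numerical equilibrium.

## Numerics

Explicit forward-time centred-space (FTCS) integration on either a 1-D
interval with `n` interior cells or a rasterized 2-D patch (cell centre
strictly inside the polygon ⇒ habitat; 5-point Laplacian; exterior cells
are Dirichlet zeros, and a one-cell exterior frame is always present).
The time step is `0.9 · h²/(2 d max_i D_i)` (`d` the dimension), further
capped at `0.1/max_i r_i` so the logistic reaction is well resolved.
Equilibrium is declared when the total absolute change per step, summed
over every cell and species, drops below `tol = 1e-6` (a per-cell
normalized variant is available but off by default; note the literal
criterion is extensive in grid size). Non-convergence within `max_steps`
is flagged, not raised. FTCS undershoots in `(−1e-12, 0)` are clamped to
zero and counted; anything more negative (or non-finite) raises a
numerical-instability error rather than being silently repaired.

The production path packs interior cells into flat arrays and runs the
update in a compiled (numba) loop over a CSR Laplacian; `step_ftcs` is
the plain-numpy reference implementation, and a test pins the two paths
against each other. Known limitation: at the experiment resolutions the
boundary layers of the least-dispersive species (width `√(D/r)`) span
only one or two cells, so the discrete persistence threshold sits about
1% from the continuum `L_c = π √(D/r)` in 1-D, and edge-band abundances
are coarsely resolved in 2-D; the qualitative dominance structure is
unaffected over the grid-refinement range we checked.

A kernel-dispersal variant replaces the diffusion operator by a
growth-then-redistribution step: a reaction-only update followed by
convolution with a per-species isotropic Gaussian, mass landing outside
the patch being discarded. With `σ_i² = 2 D_i dt` it reproduces the
diffusive profiles (checked to a few percent over hundreds of steps), and
it lets dispersal be varied without changing the stability bound.

## Persistence bisection

Locating the critical patch size by simulation needs care: near the
threshold the decay rate goes to zero, and the equilibrium-change
criterion can halt a slowly dying population while its abundance is still
sizeable. The critical-length check therefore integrates each candidate
length for a fixed horizon (`t = 400/r`, tolerance effectively disabled)
and classifies persistence by growth from the low initial abundance
(final maximum above `u_0` ⇒ persistent). Bisection to a 2% bracket
reproduces `L_c = π √(D/r)` to about 1%.

## Synthetic islands

Island outlines are star-shaped radial-Fourier polygons,
`R(θ) = R₀ (1 + Σ_m a_m cos(mθ + φ_m))`, sampled at `n_vertices ≥ 64`
equally spaced angles. Modes 2–6 carry the macro-scale structure (lobes,
peninsulas, inlets) with per-mode amplitudes summing to `macro_amp`;
modes 20–60 carry micro-scale jaggedness summing to `micro_amp`. The two
bands draw from independent sub-streams of the island seed, so raising
`micro_amp` at a fixed seed perturbs the *same* macro shape — the matched
pairs used to test the metrics' scale separation. Amplitude sums below 1
keep the radius positive, hence the polygon simple; a damped retry (×0.7,
up to 10 attempts) guards the corner cases. Outlines are rescaled to a
target area (0.25 model units unless stated).

What the generator does *not* emulate: real coastlines are not
star-shaped, have fractal structure across scales, multi-part islands,
and lagoons. Conclusions from passing tests are therefore about the
mechanism on single connected lobed patches, not about any specific real
archipelago.

The study archipelago (`generate_archipelago`) places `n` islands along a
joint gradient: macro amplitude linearly spaced over (0.05, 0.6) and area
geometrically spaced over (0.08, 0.5), with micro amplitude drawn
independently from U(0, 0.05). Coupling size to macro complexity mirrors
natural drowned-coastline archipelagos, whose larger islands carry
proportionally more large-scale boundary structure; it is what makes the
raw perimeter-deficit metric vary systematically across the set (see
below). A degenerate area range recovers a fixed-size archipelago.

## Complexity metrics

* `m1` — isoperimetric (perimeter) deficit: `m1_raw = P − 2√(πA)` in
  length units (the literal "perimeter minus equal-area circle's
  perimeter"), and the dimensionless `m1_norm = P/(2√(πA)) − 1`. Raw and
  normalized are proportional at fixed area and diverge across an
  archipelago with a size spread.
* `m2` — compressibility of the boundary's turning-angle sequence: the
  outline is resampled at 512 equal-arclength stations (making the value
  independent of digitization density), the signed exterior angles are
  quantized into 64 uniform bins over (−π, π], and the byte sequence is
  DEFLATE-compressed; `m2` is compressed over raw length. This
  operationalizes a Kolmogorov-style descriptive complexity, which is
  itself uncomputable. Smooth outlines give `m2 ≈ 0.03–0.1`; strong
  micro-jaggedness approaches 1. Resampling starts from a canonical
  vertex (lowest y, then lowest x), which makes the value exactly
  invariant under vertex-cycle rotation of the input; rigid motions
  change it only through re-binning (well under 0.02 on our fixtures).

## Random communities and the ease-of-coexistence protocol

Random `S = 4` communities draw off-diagonal `a_ij` i.i.d. lognormal
(median 1, log-sd 0.35), one shared growth rate `r` lognormal (median 1,
log-sd 0.2), and dispersal `D_i` i.i.d. lognormal (median 2e-3, log-sd
0.75). Each (generator seed, replicate) pair is an independent stream, so
any replicate subset reproduces in isolation.

On the D scale: the model has three lengths — patch size, `√(D/r)`, and
nothing else — so only `D/(r L²)` is meaningful, and the D units are
fixed by where the patch sizes sit. The defaults put the critical-patch
threshold `D ≈ r (R/2.405)²` of the archipelago's islands (areas
0.08–0.5 ⇒ thresholds 2.5e-3–3e-2) inside the dispersal distribution's
bulk, so superior dispersers pay a real boundary-mortality cost on the
smaller patches. At substantially smaller D (relative to patch size)
boundary mortality is negligible against competitive differences and
patch geometry has no measurable effect on coexistence counts — we
verified this directly (equal-area disc vs strongly lobed islands,
60–180 replicates: indistinguishable means), and it is the reason the
defaults sit where they do.

Ease of coexistence on a patch: release all four species at `u_0`,
integrate to equilibrium, and count species whose total (spatially
integrated) abundance exceeds 0.05 of the largest species' total; average
the count over replicate communities. Desk-scale runs use 50 replicates
per island (the full-fidelity protocol is 850; means differ only in
precision). Replicates hitting numerical instability are excluded and
counted, and the summary is flagged if they reach 5%. Outcome labels in
the two-species parameter scan additionally require a maximum cell
abundance above 1e-4, an absolute floor that separates genuine
persistence from slowly decaying transients.

A deliberate reading: "0.05 of maximum abundance" is interpreted as the
max over species of *spatially summed* abundance; a per-cell reading is
possible but makes the count depend on single-cell peaks.

## What the headline correlation does and does not show

Across the 12-island archipelago (50 communities each), the mean
coexisting count correlates positively with `m1_raw` (r ≈ +0.6 to +0.7)
and weakly negatively with `m2` (r ≈ −0.2 to −0.3). The mechanism is
edge-driven: smaller patches (equivalently, patches with more boundary
per unit area) lose their superior dispersers first, and `m1_raw`, being
a length, grows with both island size and macro-scale boundary
structure. At strictly equal areas, pure shape complexity does not
measurably move the mean count in this model — which is why the
archipelago, like real island sets, enters the analysis with its size
spread. `m2` is scale-free and independent of the gradient by
construction, so its correlation hovers near zero. The sign pattern, not
the numerical values, is the reproducible claim.

## Habitat-loss experiment

Peripheral loss is modelled by erosion of the rasterized domain: cells
within a given distance of the exterior become exterior (Euclidean
distance between cell centres). For a coexisting two-species pair
(canonically `a_21 = 1.4, D_1 = 3e-3, D_2 = 5e-4` on a mildly lobed
island of area 0.25 — in two dimensions the extra boundary demands a
larger competitive edge than the 1-D profile's `a_21 = 1.2`), each eroded
domain is recolonized and re-run. The interior dominant goes extinct at a
strictly smaller erosion depth than the boundary specialist: erosion
removes exactly the deep-interior habitat the high-D species requires,
while the low-D species tolerates proximity to the edge. Total erosion is
recorded as all-extinct, not an error.

## Problem sizes

Default desk-scale settings: 1-D profiles at 199–399 cells; 2-D rasters
at 32–64 cells across the longest side; 12 islands × 50 communities for
the correlation experiment; step caps of 6e4 (community replicates,
non-convergence flagged and under a few percent of replicates) to 2e6
(two-species reference runs). These sizes keep the full pipeline in the
minutes range on one core while leaving the assertions' margins wide;
every size is a config field, and the full-fidelity protocol (100 islands,
850 communities) is the same code run longer.
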