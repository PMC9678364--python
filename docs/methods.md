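# Methods

## The model

`actoring` simulates a confined actomyosin network as two coupled phases.
The *solution phase* holds diffusing G-actin, formin nucleators, NMII
(non-muscle myosin II) mini-filaments and alpha-actinin crosslinkers as
integer copy numbers on a compartment grid; transport between neighboring
compartments is a stochastic single-molecule hop reaction with rate
D/ℓ² per molecule per neighbor (D = 20 µm²/s). The *polymeric phase*
holds semiflexible actin filaments discretized as chains of cylinders
whose equilibrium length is 2.7 nm × n_monomers (1–40 monomers, i.e. up
to 108 nm); bound motors and crosslinkers are two-point harmonic springs
attached to discrete binding sites (four per cylinder, at fractions
{1/8, 3/8, 5/8, 7/8} of the axis).

### Chemistry

All reactions are simulated exactly with the Next Reaction Method (NRM),
a variant of the Gillespie algorithm using one exponential clock per
channel and time rescaling on propensity changes. Channels:

- polymerization/depolymerization at barbed (BE) and pointed (PE) ends:
  k_on_BE ∈ [11.6, 34.8] (µM·s)⁻¹, k_on_PE = 1.3 (µM·s)⁻¹,
  k_off_BE = 1.4 s⁻¹, k_off_PE ∈ [0.8, 2.4] s⁻¹. The two treadmilling
  arms used throughout are (k_on_BE, k_off_PE) = (11.6, 0.8) ("slow",
  in-vitro baseline, ⟨r_TM⟩ ≈ 0.55 s⁻¹) and (34.8, 2.4) ("fast",
  three-fold formin/cofilin-boosted, ⟨r_TM⟩ ≈ 2.2 s⁻¹).
- two-step formin nucleation: formin + G → intermediate (rate-limiting,
  k_nu = 0.005 s⁻¹ per free formin with local G-actin available),
  then the fast step consumes two further G-actin and emits a 3-monomer
  formin-capped filament at a random position/orientation inside the
  compartment ∩ effective boundary. The two-G stoichiometry of the fast
  step is what makes the 3-monomer product conserve the total monomer
  count exactly (an invariant the test suite asserts over every event
  sequence).
- formin dissociation (FBE → BE, 0.01 s⁻¹) and destruction of 2-monomer
  filaments into 2 G-actin (k_destruction = 1.0 s⁻¹).
- motor/linker binding over geometric candidate pairs: all unoccupied
  site pairs on distinct filaments with separation in [175, 225] nm
  (NMII) or [30, 40] nm (alpha-actinin), found with a k-d-tree radius
  query (an O(n²) scan is kept as the test oracle). Motor binding
  propensity is n_heads · k_on_head · (free NMII copies) with
  n_heads ~ U{15..30} pre-sampled per event; linker binding is
  mass-action per candidate pair, k_on · [linker] · n_pairs.
- motor walking: one end advances one binding site (27 nm) toward the
  barbed end at the force-throttled rate below. Stepping keeps the
  spring's binding-time rest length, so walking *stretches* the ensemble
  spring — that is the origin of contractile force. (The alternative
  reading, resetting the rest length to the new separation after every
  step, makes motors force-free passive crosslinks; implemented that way
  the networks never collapse into clusters, contradicting the modeled
  biology, so the force-generating reading is used.)

Filament channels of the same kind are aggregated per compartment (one
channel carries the summed propensity; the firing filament is drawn by
weight). By superposition of exponential clocks this is statistically
exact and reduces the per-event update cost from O(filaments) to O(1).
The queue is rebuilt from state at each chemistry-window boundary —
exact by memorylessness — and updated incrementally within a window.

### Mechanics

After each chemistry window the network relaxes to a local energy
minimum (quasi-static mechanics; elastic relaxation is much faster than
chemistry). Terms: cylinder axial stretching ½K(l−l₀)² (K = 100 pN/nm);
bending K(1−cos θ) between consecutive cylinders (K = 672 pN·nm);
motor/linker springs ½K_eff(l−l₀)² with K_linker = 8 pN/nm and
K_motor = 2.5 pN/nm *per head* (heads in parallel ⇒ additive stiffness);
exponential boundary repulsion ε·exp(−(d−a₀)/λ) with ε = 100 pN·nm,
λ = 2.7 nm, a₀ = 100 nm (the barrier sits 100 nm inside the mechanical
wall, so a 400-nm-tall, 4-µm-wide mechanical oblate confines an
effective 200 nm × 3.8 µm volume), sampled at both endpoints and the
midpoint of every cylinder; and an optional 1/r⁴ pair-potential
excluded-volume term (K = 10⁵ pN/nm⁴, 16×16 Gauss–Legendre quadrature,
100 nm cutoff, capped for intersecting segments). Production-style runs
keep the steric term off (its cost is prohibitive and the phase behavior
does not require it); it is fully implemented, differentiated and
tested.

Minimization uses FIRE with an adaptive timestep, a 1 nm per-step
displacement cap, and a force tolerance of 1 pN (default; the desk-scale
preset uses 5 pN and a 400-iteration cap and accepts best-so-far —
forces relevant to the rate laws are tens of pN, so a few-pN residual is
immaterial). The energy/gradient kernel is a fused numba-jitted loop; a
pure-numpy implementation of the same math is kept and the suite asserts
both paths agree to round-off and match central finite differences to
1e-5. The boundary exponent is clamped at 50 to keep deep-penetration
configurations finite; within one chemistry window the stale ratchet
factor cannot stop growth at the hard wall, so polymerization attempts
that would land within 5 nm of the mechanical wall are discarded
(thinning).

### Mechanochemistry

After minimization the rates are refreshed (never mid-window):

- Brownian ratchet: k_poly = k⁰·exp(−F_ext/1.5 pN), F_ext = compressive
  boundary force along the filament axis at the growing end.
- slip bond (linker): k_unbind = k⁰·exp(max(F,0)/17.2 pN).
- catch bond (NMII, parallel-cluster form):
  k_unbind = β·k⁰/N·exp(−F/(N·F_c)) with β = 0.2, k⁰ = 1.7 s⁻¹ per
  head, F_c = 1/γ = 20 pN (γ = 0.05 pN⁻¹ is the only tabulated
  parameter with the right units; its purpose is not otherwise stated,
  so F_c = 1/γ is an inference).
- Hill force–velocity: k_walk = k⁰·(F_s − F/N)/(F_s + F/(N·ξ)) with
  F_s = 12.62 pN per head, ξ = 0.1, zero exactly at ensemble stall; the
  two force symbols in the printed relation are read as the same motor
  tension resolved against the step direction. k⁰_walk is not
  tabulated anywhere; the default 7.4 s⁻¹ gives an unloaded ensemble
  velocity of ≈0.2 µm/s at the 27 nm site spacing.

## Protocol and scenarios

One cycle = chemistry window Δt → FIRE minimization → rate update.
Δt = 10 ms by default (the published protocol value); the desk-scale
preset uses 100 ms, one order coarser, which still respects the
chemistry/mechanics time-scale separation while keeping a 600-s run to a
few minutes of wall time. De-novo runs start from seed filaments plus
40 µM G-actin and nucleator; 0.06 µM NMII and 4 µM alpha-actinin are
added at 300 s. Latrunculin-A-like inhibition (at 800 s): weak =
(k_on_BE 11.6, k_off_BE 2.1, k_off_PE 2.4), strong = (3.48, 11.2, 4.8),
k_on_PE fixed at 1.3. NMII perturbations (Calyculin-A / Y-27632
analogues) add or remove NMII on a preformed ring state (80 µM actin,
0.18 µM NMII), removal draining the diffusing pool first and then
force-unbinding random motors.

### The desk-scale preset

`scaled_down_config()` shrinks the mechanical disk to 2 µm, uses a
well-mixed (single-compartment) solution phase, and Δt = 0.1 s. Actin,
NMII and linker concentrations and all rate constants keep their
full-scale values. Two quantities are deliberately rescaled because they
control dimensionless geometry rather than chemistry: the nucleator
concentration (1.0 µM instead of 0.1 µM) and the seed count (60), chosen
so the emergent mean filament length over disk radius (L/R ≈ 0.26 at
300 s) matches the full-scale regime (≈0.3). At raw concentrations a
2-µm disk holds a handful of radius-length filaments and every
morphology degenerates into rim-hugging chords, erasing the
ring/cluster dichotomy. A well-mixed solution phase is forced by event
count: explicit 500-nm-compartment diffusion generates ~10⁶ hop events
per simulated second at these copy numbers.

## Analysis definitions

- R_median: median in-plane radius of all polymerized monomers divided
  by the effective radius (uniform disk → 1/√2; peripheral ring → ring
  radius fraction; central cluster → near 0). Monomers are weighted
  equally (monomer weighting rather than cylinder-midpoint weighting:
  the radial density is a distribution of polymerized actin mass).
- ⟨r_TM⟩: *net* barbed-end monomer gain per filament per second over the
  post-onset window, from cumulative end-event counters; equal to the
  net pointed-end loss at kinetic steady state (the equality is what
  makes the treadmilling rate well defined; gross addition rates do not
  balance). Steady-state onset = first time the 100-s rolling mean
  filament length changes < 2% per 100 s.
- turnover t½: monomers are labeled via each filament's lab-frame
  monomer interval [L, R) (pointed-end loss advances L, barbed-end gain
  advances R), giving exact subunit identity with O(1) bookkeeping; t½
  is the interpolated time for the surviving labeled fraction to reach
  0.5.
- clusters: 100 nm × 100 nm in-plane bins, per-bin concentration in µM
  using the effective height, threshold 160 µM, 4-connected components,
  components < 4 bins discarded; local concentration = mean over member
  bins.
- remodeling rate: slope of the longest linear segment of R_median(t)
  (R² ≥ 0.9 and RMS residual below max(1% of range, 1.5× the robust
  point-noise estimate), minimum 50 s; global fit as fallback).
- U_Mech = filament bending + stretching of filaments, motors and
  linkers; the boundary and steric terms are excluded.
- image pipeline: Otsu threshold on the smoothed image (hole-filled
  largest component) → mask centroid → 50 rays at 7.2° spacing with
  bilinear sampling, per-ray distance normalized at the mask edge; the
  radial median weights pooled samples by intensity × radius (the
  annulus-area Jacobian), so a uniform disk gives 1/√2; the
  center-to-plateau slope fits the 10%→90%-of-plateau transition of the
  bleach-normalized mean profile (plateau = mean of the outer 20% of
  radii).

## Synthetic data

The generator produces uniform / ring / cluster snapshots from straight
108-nm filaments (rings tangential, otherwise isotropic in-plane;
orientation — not position — is resampled when an endpoint would leave
the boundary, so the monomer density is not depleted near the rim),
TIRF-like renders (pixel binning → Gaussian PSF → photon scaling →
optional per-frame bleaching → Poisson shot noise; no read noise), and
kinetics fixtures (Poisson end-event counter streams; exponential
turnover logs with optional exact quantile spacing for noise-free
analytic checks). Fixtures are bitwise deterministic under a fixed seed
and make no attempt at mechanical plausibility. Passing fixture tests
demonstrates the correctness of the quantification algorithms, not the
realism of the simulator; the simulator is validated separately by its
conservation laws, kinetic oracles and phase behavior.

## Problem sizes used by the shipped runs

The acceptance computation uses: morphology fixtures of 30–60k monomers;
chemistry-only treadmilling/turnover runs at the full-scale effective
geometry (3.8 µm × 200 nm, ~54,700 monomers, 1400 s simulated, labels at
1000 s); and one paired desk-scale mechanochemical experiment (2 µm
disk, 600 s, motors at 300 s, steady window 500–600 s). The directional
phase test in the suite runs the same pair with one seed.

## Known limitations

- The desk-scale pre-motor state is still somewhat rim-biased in the
  fast-treadmilling arm (the assembly burst briefly produces
  radius-scale filaments); the post-motor contrast between arms is
  robust to this.
- The turnover halftime is much more sensitive to modeling choices than
  ⟨r_TM⟩: it is controlled by the length-biased filament-size
  distribution, which is broader under a well-mixed solution phase than
  under explicit compartment-scale diffusion, so t½ values should be
  read as order-of-magnitude at desk scale.
- No membrane, no filament–boundary tethering, no branching, no
  nucleotide states on subunits, no thermal fluctuations in mechanics,
  and no hydrodynamics — all outside the modeled mechanism.
- Bit-reproducibility holds for a fixed seed on a fixed floating-point
  environment; the jitted and numpy gradient paths agree to round-off
  but a different BLAS/fastmath environment may change trajectories at
  machine precision.
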