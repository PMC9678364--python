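# actoring

Mechanochemical simulation of confined actomyosin networks, built to
probe how filament **treadmilling** and **myosin contractility** compete
to set network architecture: rapid treadmilling drives polymerized actin
to the periphery of a thin disk (an actin *ring*, the geometry of the
immunological synapse), while slow treadmilling lets NMII-driven
contraction win and collapse the network centripetally into dense
*clusters*.

The package is for cytoskeletal modelers who want a desk-scale,
fully-tested implementation of this class of model: exact stochastic
reaction kinetics coupled to quasi-static filament mechanics, plus the
quantification pipeline that classifies the resulting morphologies (and
the matching pipeline for TIRF-like intensity images).

## The model in brief

Two phases. Diffusing G-actin, formin, NMII mini-filaments and
alpha-actinin live as copy numbers in a compartment grid; filaments are
chains of cylinders (2.7 nm per monomer, ≤ 40 monomers per cylinder)
with motors/linkers as harmonic springs between binding sites. The
chemistry — polymerization/depolymerization at both ends, two-step
formin nucleation, dimer destruction, motor/linker (un)binding and
motor walking — is propagated exactly with the Next Reaction Method.
After every chemistry window (10 ms at full scale) the mechanical energy

U = Σ ½K_str(l−l₀)² + Σ K_bend(1−cos θ) + Σ ½K_spring(l−l₀)²
  + Σ ε·e^{−(d−a₀)/λ} (+ optional steric ∬dl dl′/r⁴)

is minimized (FIRE), and the relaxed forces feed four mechanosensitive
rate laws: a Brownian ratchet on polymerization,
k = k⁰e^{−F/F₀}; a slip bond on crosslinker unbinding,
k = k⁰e^{+F/F_c}; a catch bond on motor unbinding,
k = βk⁰/N·e^{−F/(N F_c)}; and a Hill force–velocity relation on motor
stepping that vanishes at the ensemble stall force N·F_stall.
The readouts are the normalized radial median of polymerized actin
(R_median: 1/√2 for a uniform disk, →1 for rings, →0 for clusters), the
treadmilling rate ⟨r_TM⟩ (net barbed-end elongation per filament per
second), FRAP-like turnover halftimes, grid-based cluster detection
(100 nm bins, 160 µM threshold), and the mechanical energy
U_Mech (filament bending + all stretching terms).

See `docs/methods.md` for every parameter, unit and convention, and
`docs/trajectory_schema.md` for the trajectory file format.

## Worked example

```python
from actoring import protocol, analysis

# slow-treadmilling arm: in-vitro baseline rates, NMII + alpha-actinin
# added at 300 s, desk-scale 2 µm disk
cfg = protocol.baseline_config("slow", total_time=600.0)
traj = protocol.run(cfg, seed=1)

t, rm = analysis.r_median_series(traj)
rep = analysis.treadmilling_rate(traj, t_start=350.0)
_, _, umech = analysis.mechanical_energy_series(traj, steady_window=100.0)
cs = analysis.detect_clusters(traj.snapshots[-1])
print(rep.rtm, rm[t >= 500].mean(), umech, len(cs),
      analysis.local_concentration(cs))
```

printed (seed 1):

```
<r_TM> = 0.555  monomers/s/filament   # slow arm treadmilling rate
steady R_median = 0.47                # network collapsed toward center
U_Mech ≈ 14,750 pN·nm                 # bent, frustrated cluster state
1 cluster, local [F-actin] ≈ 289 µM   # ~7x condensed over the 40 µM pool
```

Re-running with `baseline_config("fast")` (three-fold boosted
barbed-end assembly and pointed-end disassembly) gives
⟨r_TM⟩ = 2.23 s⁻¹, steady R_median = 0.79 and U_Mech ≈ 7,580 pN·nm: the
same ingredients, but treadmilling now outruns contraction and the
network accumulates at the boundary as a mechanically relaxed ring —
higher R_median, roughly two-fold lower mechanical energy, no clusters.

The `examples/` directory holds one short narrative script per
capability: the four rate laws, treadmilling kinetics and turnover,
morphology quantification on synthetic ground truth, the image pipeline
cross-check, and the full ring-versus-cluster experiment. A thin CLI
(`actoring simulate|analyze|quantify-image|make-fixtures|phase-scan`)
wraps the same functions for shell use.

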