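# Methods

## Model summary and assumptions

`npcbd` models the nuclear pore complex (NPC) as a two-spoke elastic
scaffold in a 2D cross-sectional plane: the plane contains the pore
axis (y, import direction negative) and a transverse coordinate (x).
Two opposing spokes stand in for the eightfold-symmetric pore; the
720 FG motifs of the two-spoke build scale to ~2880 per whole pore,
inside the physiological 2700–3000 window, which is the consistency
argument behind the default motif count.  Drag and diffusion
nonetheless use 3D Stokes spheres (`ζ = 6πηR`, `D = kT/ζ`), which is
what reproduces the tabulated diffusion coefficients.

Assumptions inherited from the modeling framework:

* the nuclear envelope is a rigid slab; pom anchors are immobile;
* solvent enters only through drag and thermal noise (free-draining;
  no hydrodynamic inter-bead coupling);
* the cargo–kap complex is one rigid sphere; it does not rotate, and
  its binding-spot arc is body-fixed;
* RanGTP action is instantaneous release upon complete basket loading
  (the run simply stops there);
* no molecular traffic or competing species; one cargo per run.

## Parameters

All interactions in reduced units: energy kT (T = 310 K), length nm,
time 0.1 ns.  310 K with η = 5 cP is the unique pairing under which
`kT/(6πηR)` reproduces the published coefficients for R = 0.9, 4.5,
7.5 and 10 nm simultaneously.

| parameter | default | units | note |
|---|---|---|---|
| scaffold Young's modulus `E` | 17 | kPa | NE-like elasticity; sets `k_s = E·A/r₀` |
| strut cross-section `A` | 100 | nm² | effective scaffold rod section |
| scaffold bending `k_θ` | 100 | kT | minimal stiffness that keeps subunits assembled |
| WLC persistence `l_p` | 0.43 | nm | AFM force–extension value for FG domains |
| WLC segment `L_s` | 10 | nm | must be ≥ 10 `l_p` (discrete-WLC criterion) |
| WLC bending | `l_p/L_s` ≈ 0.043 | kT | three orders below the scaffold value |
| central / peripheral contour | 50 / 200 | nm | short cohesive chains inside, long noncohesive outside |
| kap–FG hydrophobic ε, ξ | 2, 1.5 | kT, nm | receptors are collectively more hydrophobic |
| FG–FG hydrophobic ε, ξ | 1.5, 1.0 | kT, nm | central chains only; peripheral FG have none |
| hydrophobic cutoff | 10.0 | nm | shifted to zero at the cutoff |
| repulsion ε_rep, σ, cutoff | 100, 1.0, 1.35 | kT, nm, nm | soft (finite at contact) |
| viscosity η | 5 | cP | cellular viscosity |
| protein density ρ | 1.35 | g/cm³ | lumped-mass → geometric = hydrodynamic radius |
| time step Δt | 0.1 reduced (0.01 ns) | — | equals the shortest resolvable bond lifetime |
| rejection threshold `f_max` | 0.99 | of `L_s` | "near the contour length" made concrete |

Geometry defaults (config-exposed; the cryo-EM figures behind them are
approximate): filaments 35 nm, channel length 60 nm (min diameter 50,
end diameter 70), basket 65 nm, distal ring 40 nm — chosen so the
entry-plane → exit-plane transport span is exactly 160 nm, the length
used by the free-diffusion baseline `t = L²/2D`.  Scaffold bead spacing
10 nm; scaffold bead radius 3 nm (inside the tabulated 1.2–4.7 nm
range).  The allocation of the 720 motifs over graft regions is not
published; the default splits them evenly between filaments, channel
wall and basket (240 each), i.e. 12 × 20-bead peripheral chains on the
filaments, 48 × 5-bead central chains on the wall, 12 × 20-bead chains
on the basket, split evenly between the spokes.  Equilibrium bond
lengths and scaffold angles are taken from the as-built geometry, so
the freshly built scaffold is stress-free; FG-chain bending equilibria
are π (straight), the WLC ground state.

## Functional forms chosen where the source forms are approximate

The hydrophobic attraction is implemented as the cutoff-shifted single
exponential `E(r) = −ε e^(−r/ξ) + ε e^(−cutoff/ξ)` — the standard
long-range hydrophobic form of colloid science, matching the published
strength/characteristic-length parameterization.  The excluded-volume
term is likewise a shifted exponential `ε_rep e^(−r/σ)`; it is soft
(74 kT at contact), which is what permits the large Brownian time
step.  Both are swappable behind `HydrophobicRule` / `RepulsiveRule`.
Cargo–bead separations are measured center-to-surface so cargo size
matters; kap spots sit on the cargo surface and interact
point-to-center with FG motifs.

## Integration, rejection and boundaries

Explicit overdamped Euler–Maruyama, per mobile bead and component:
`x ← x + F·D·Δt + N(0, 2DΔt)`.  Noise is drawn in bulk from one
numpy PCG64 stream per run, so trajectories are bit-reproducible and
independent of how the run is chunked; the numba kernels are compiled
without fastmath so results are identical across machines.

Finite extensibility: after each proposal, any bead adjacent to a WLC
segment at ≥ `f_max·L_s` reverts to its previous position (per-bead
rejection, the cheapest scheme consistent with Öttinger's recipe);
the check iterates (≤ 8 rounds) because partial reverts can re-stretch
a neighbor, then falls back to a full-step revert.  Rejected moves are
not redrawn.  The same mechanism enforces the rigid NE slab and the
simulation box (cargo clearance uses its radius).  A per-step monitor
records the maximum observed extension fraction; it never reaches
`f_max` in the test runs.

Nonbonded pairs come from a Verlet list with per-class cutoffs (10 nm
only for cohesive FG–FG pairs, 1.35 nm otherwise), a 2 nm skin,
rebuild every 50 steps *and* whenever accumulated displacement could
breach the skin; a brute-force O(N²) evaluation is the test oracle for
its correctness.  FG beads near the cargo are kept in a separate
sublist for the kap-spot terms.

## Contact bookkeeping: engagement vs bonds

Two thresholds, deliberately distinct:

* **occupancy** counts a binding spot as *participating in hydrophobic
  interaction* while ≥ 1 FG motif lies within the 10 nm kap–FG force
  cutoff — this is the spot-counted quantity whose full-model value is
  ≈ 7.9 of 8;
* **bond episodes** (lifetime statistics) use a tight geometric
  contact criterion, default 3 nm ≈ 2ξ (the well width).  Using the
  force cutoff here would declare near-permanent bonds and erase the
  nanosecond-scale transience; the contact radius is the single most
  influential free parameter of the lifetime statistics and is
  config-exposed (`IntegratorConfig.contact_radius`).

The minimum resolvable lifetime is one time step.  Event rules:
`t_start` = first step a spot is within the kap–FG cutoff of a
cytoplasmic-filament FG motif; `t_end` = first step the whole sphere
is past the nuclear-ring plane and above the distal-ring plane.  The
shuttle statistic counts completed mouth → mid-channel → mouth round
trips; the mid-channel plane is the axial midpoint of the channel.

## The surrogate (mini) pore

Full-fidelity transport statistics are cluster-scale: at a 0.01 ns
step, one 2.6 ms passage is ~2.6 × 10⁸ steps, and the reference
protocol is 150 such runs.  CI therefore verifies the transport
physics on `fixtures.mini_npc`: a 60 nm-span pore (filaments 16,
channel 24, basket 20 nm) with 144 motifs, built for geometric
similarity — cargo/channel diameter ratio 8/26 ≈ the reference 15/50,
peripheral contour ≈ 2× the mouth diameter (60 vs 32 nm) so the
filament FG brush still covers the entry.  Surrogate runs use Δt = 2
reduced units (0.2 ns), which the soft potentials and the rejection
step tolerate; the active-transport protocol starts the cargo just
inside the channel mouth (the reference protocol likewise starts
cargo near the entry to save computation).

What passing surrogate tests do show: right-skewed first-passage
samples, wall-biased radial statistics, near-saturated occupancy,
transient bonds, and a directional intact-vs-filament-deficient
difference in inert-cargo penetration.  What they do not show:
agreement with the full-size pore's absolute numbers (2.6 ms mean FPT,
53% channel residence, 7%/46% inert success, published shuttle
percentages) — those require the full geometry at full statistics,
which the same API (`run_batch`, `npcbd batch`) runs unchanged given
the budget.  The surrogate also shares the model's intrinsic
idealizations (2D plane, non-rotating cargo, rigid NE), so passing
tests validate the implementation, not the biology.

## Numerical choices and degenerate inputs

* Zero-length bonds/angle arms raise evaluation errors naming the
  overlapping beads; `r < 10⁻¹²` nm pair separations contribute no
  force (no direction is defined).
* For FG bending (θ₀ = π) the torque factor `sin(θ−θ₀)/sin θ` is the
  constant −1; this removes the 0/0 at straight configurations and all
  trigonometry from the chain-bending inner loop.
* The inverse-Gaussian scale MLE `λ̂ = n/Σ(1/tᵢ − 1/μ̂)` is declared
  degenerate when the implied λ exceeds 10¹² μ (numerically identical
  samples).
* Initial chain conformations are seeded self-avoiding random walks at
  0.8 `L_s` per segment, biased off the wall for the first step, with
  bounded retries (a blocked walk falls back to a straight step); the
  FG layer is then relaxed before cargo is introduced (equilibration
  length is a config knob; surrogate runs use 2 × 10⁴ steps, after
  which brush observables are stationary at surrogate scale).
* Cargo placement is deterministic: on-axis, one diameter beyond the
  filament tips, raised in 2 nm increments until every FG bead is
  outside the interaction cutoff so `t_start` fires dynamically.

## Known limitations

* 2D cross-section: excluded-volume and crowding effects are weaker
  than in 3D; absolute selectivity and FPT values are not comparable
  across dimensionality.
* No cargo rotation: the fixed arc orientation underestimates
  re-binding geometry; the arc center is config-exposed.
* The published figures for some subunit dimensions and the graft-site
  layout are approximate; all are config parameters.
* Bond-lifetime statistics depend directly on the contact radius (see
  above); report it alongside any lifetime numbers.
* The avidity (spot-count) sweep and MSD-based anomalous-diffusion
  analyses are out of scope; the spot count is exposed in the cargo
  config but the supplementary studies are not reproduced.
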