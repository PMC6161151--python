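# Methods

This note documents the models implemented in `asdmix`, their assumptions,
the defaults that matter, and the design decisions taken where more than one
convention exists. Units are GROMACS-style throughout: nm, ps, amu,
elementary charge, kJ/mol; conversions happen only at I/O edges
(PDB/XYZ are Å on disk) and in reported diffusion coefficients
(1e-10 cm²/s).

## Energy model

The potential is the classical fixed-charge force-field form
`E_tot = E_bond + E_angle + E_dih + E_LJ + E_Coul` with harmonic bonds
`½k_b(r−r₀)²`, harmonic angles `½k_a(θ−θ₀)²` and periodic dihedrals
`k_d(1+cos(nφ−φ₀))` (GAFF-style functional forms). Non-bonded terms skip
1–2 and 1–3 pairs; 1–4 pairs are scaled by the Amber convention (LJ ÷ 2,
Coulomb ÷ 1.2) inside `e_tot` and excluded entirely from `e_nb`, the
intermolecular-quality non-bonded sum. Both quantities are exposed because
reported blend energetics may or may not include scaled 1–4 terms; `e_nb`
is the one used for mixing-energy comparisons. Energies are potential-only.

Lennard-Jones uses Lorentz–Berthelot combining, a 0.9 nm default cutoff
under the minimum-image convention, and an optional isotropic long-range
dispersion correction `(8π/3V) Σ_ab N_a N_b ε σ³ [⅓(σ/r_c)⁹ − (σ/r_c)³]`
(uniform-density assumption; strictly negative for attractive systems).

Electrostatics has three routes:

* `direct` — non-periodic all-pairs sum (reference/oracle route);
* `minimum-image` — periodic nearest image with cutoff;
* `ewald` — classic Ewald summation: erfc-screened real-space sum over
  non-excluded pairs within the cutoff, reciprocal-space sum over the
  truncation ellipsoid, self term, explicit subtraction of the
  reciprocal-space contribution of excluded intramolecular pairs, and a
  uniform background-charge term (applied with a warning when the charge
  set is non-neutral, which legitimately happens inside the charge-zeroing
  decomposition). The splitting parameter and k-space extent are derived
  from a target relative accuracy (default 1e-5):
  `α = √(−ln ε)/r_c`, `n_max = ⌈αL√(−ln ε)/π⌉.`

Classic Ewald was chosen over mesh (PME) interpolation deliberately: at
analysis scale the O(N²)+O(N·N_k) cost is irrelevant, the result is exactly
testable (the rock-salt Madelung constant is reproduced to ~1e-6 relative
against an independent Evjen shell summation), and no interpolation error
enters the descriptor pipeline. Boxes are orthorhombic only; the Coulomb
constant is k_e = 138.935458 kJ·mol⁻¹·nm·e⁻².

## Charge-zeroing intermolecular Coulomb

The Coulomb energy is a quadratic form in the charge vector, so the
interaction of a molecule (or any atom set) with the rest of the system is
exactly `E_full − E_without − E_only`, where the second and third
evaluations zero the molecule's charges and everyone else's respectively.
This holds for every method above including the Ewald background term, and
is the only way to obtain intermolecular Coulomb energies that carry the
correct long-range contribution. All three evaluations must use the same
method; the implementation enforces this by construction.

The species-level aggregate applies the decomposition per molecule and
subtracts the within-species intermolecular energy once (obtained from one
further zeroing pass on the whole species), so every distinct-molecule pair
involving the species is counted exactly once. The per-molecule and
species-level routes are verified against explicit cross-molecule pair
summation to 1e-6 kJ/mol on random ≤300-atom systems.

## Mixing energies

`ΔE = E_blend − (N_api·e_api + N_pol·e_pol)` against pure amorphous
reference phases whose per-molecule (API) / per-chain (polymer) energies are
trajectory averages of the pure systems divided by molecule count. Three
normalizations are carried: raw per simulation cell, per nm³ of blend, and
per API molecule. Normalization by a positive scalar cannot change a sign,
but because each blend divides by its *own* volume or API count it can in
principle reorder blends; `energy_trend` therefore verifies rank agreement
across normalizations and raises on disagreement instead of silently
picking one. The raw value is labelled per-simulation-cell because
literature tables of this kind usually leave the basis implicit.
Trajectory averaging windows are caller-specified; analyses here use all
supplied frames, and callers following the common practice of late-time
windows should slice frames before averaging (the bundled descriptor table
was produced from late-time windows by its authors).

## Hydrogen bonds

Geometric criterion: donor–acceptor distance ≤ 0.35 nm (minimum image) and
hydrogen–donor–acceptor angle ≤ 30°, **vertex at the donor** — the defaults
of the widespread GROMACS-style analysis tool. The angle convention is
stated prominently because other tools measure at the hydrogen; both
cutoffs are configurable. Donors are O/N with a covalently bound hydrogen
(flagged in the topology); acceptors are flagged O/N; fluorine is not an
acceptor by default. Intramolecular bonds are counted if the geometry
passes, regardless of exclusion lists — exclusions are an energy concept,
not a structural one. ΔN_HB scales the pure-phase averages by
molecule-count ratios before subtracting, and a species-pair breakdown
(api–api / api–polymer / polymer–polymer) is available since cross bonds
are the mechanistically interesting ones.

## Mobility

**Diffusion.** Centre-of-mass MSD averaged over molecules and all time
origins; the all-origin average is computed exactly with the standard
FFT/autocorrelation split (O(N log N)), with a strided-origin direct path
for subsampling. MSD requires unwrapped coordinates; `unwrap` reconstructs
continuous displacements via nearest-image steps and refuses input whose
frame-to-frame displacement reaches half a box edge (beyond that the true
image is unknowable — a sampling problem no unwrapper can fix). The
Einstein fit `D = slope/6` uses lags in the 10–50% fraction of the maximum
lag by default: late enough to leave ballistic/caged regimes, early enough
that the origin average retains statistics. The window is configurable and
the fit r² is always reported so non-diffusive curves are visible. Negative
fitted slopes clamp to D = 0 with a warning. 1 nm²/ps = 1e8 × 1e-10 cm²/s.

**RMSF.** Each molecule's mass-weighted COM is moved to the origin frame by
frame with no rotational superposition, so rotation and conformational
motion contribute — this is a lumped proxy for local/secondary mobility,
not a vibrational analysis. Per-atom fluctuations `√⟨|r−⟨r⟩|²⟩` are averaged
over heavy (non-hydrogen) atoms of all molecules, unweighted.

**Replicates.** Descriptors are reported as mean ± sample standard
deviation (ddof = 1, the usual error-bar convention) over independent
replicate runs, four by default in the generators.

## Ranking and the limiting-factor call

Descriptor–stability association uses Spearman rank correlation against the
amorphicity index at 40 wt % drug load (AI40), with mid-ranks for ties —
rank-based because AI saturates at 100 and its scale is ordinal at best;
Pearson is reported alongside for transparency. Direction matters: a more
negative mixing energy and a lower mobility are the stability-favourable
directions, so a descriptor's *explanatory strength* is
`max(0, −ρ_Spearman)` (after orienting each descriptor so that favourable
is negative). A correlation in the physically wrong direction counts as
zero strength rather than as evidence: without this, a spurious
wrong-signed energy correlation can mask a genuine mobility signal. The
factor whose strength exceeds the other's by ≥ 0.3 (default, configurable)
is declared rate limiting, otherwise `indeterminate`. With the bundled
eight-blend table this yields thermodynamic for flufenamic acid
(strengths 0.74 vs 0) and kinetic for phenacetin (0 vs 0.32). When
replicate spreads are present, a descriptor whose per-polymer values all
overlap within one standard deviation is treated as non-discriminating;
without spreads the screening is skipped with a warning. The 0.3 margin is
this package's own quantitative rule for a judgement that is usually made
qualitatively; it is exposed precisely so users can stress it.

## Composition bookkeeping

Molecular masses use embedded IUPAC 2021 standard atomic weights (the
0.1-percentage-point checks are insensitive to the mass-table vintage).
Blend enumeration picks, for each drug/polymer/target-load combination, the
integer API count minimizing |w_api − target| by inverting
`w = 100·nM/(nM+m_pol)` and testing both neighbouring integers. Polymer
chain masses are taken as given (or from an explicit chain topology), never
inferred from monomer molecular weight — end groups matter at the 0.1%
level. `recompute_weight_percent` re-derives w(API) from molecule counts
and total masses and flags inconsistent rows; in the bundled composition
table the PSA rows disagree with their own counts by ~4.5 points (their
printed percents match a different mass bookkeeping), and they are
reported flagged rather than reconciled.

## Synthetic data: what it does and does not show

The generators produce data whose target property is known exactly, so
every analysis is validated as parameter recovery rather than against
opaque reference output:

* **Brownian** (default 95 molecules, mirroring a realistic per-blend drug
  count; dt 2 ps, the typical snapshot interval): exact Gaussian steps with
  per-axis variance 2·D·dt — no integrator, so recovery errors are purely
  statistical. D = 0 is allowed (static); D < 0 rejected.
* **Harmonic wells**: fluctuations are sampled directly in the molecular
  COM frame with per-axis variance kT/k, so the RMSF analysis (which
  removes the COM) recovers √(3kT/k) exactly in expectation. Lab-frame
  i.i.d. sampling would lose a factor √(1−1/n_atoms) to the COM
  projection — a property of the estimator, documented here because it is
  easy to mistake for a bug. An optional rigid drift verifies COM removal.
* **H-bond fixtures**: donor–H⋯acceptor triples at exactly requested
  (distance, angle) geometries, placed far apart so counts equal
  constructions.
* **Rock-salt / LJ lattices**: analytic (Madelung) and brute-force
  computable energies.
* **Toy blends** (≤500 atoms, 4 replicate seeds): a donor-rich three-atom
  "drug" docked onto an acceptor-only "polymer" comb at H-bonding geometry,
  jittered per replicate — every descriptor is computable end to end, and
  the construction realizes the mechanism where mixing is rewarded because
  pure polymer cannot hydrogen-bond.

None of this emulates real amorphous packing, force-field realism, glassy
relaxation or aging. Passing tests therefore demonstrate that the
*analysis* is correct and statistically calibrated at realistic shapes and
sizes — not that any particular force field or sampling protocol yields
accurate stability predictions. The bundled composition/descriptor tables
come from microsecond-scale production simulations plus experiments; they
enter as inputs, and the package's claims about them are arithmetic
consistency, trend extraction and classification, not regeneration.

## Numerical choices and degenerate inputs

* Overlapping charged/LJ atoms (r < 1e-6 nm) raise rather than return
  infinities; zero-length bond vectors in angle/dihedral evaluation raise.
* Ewald on a non-neutral charge set warns and applies the background
  correction (exact for the quadratic-form decomposition).
* Tie handling: trend groups are equal within 1e-9 of the value spread and
  reported as groups, never arbitrarily ordered; AI ties get mid-ranks.
* Trajectories enforce strictly increasing times and constant dt
  (1e-6 relative); file readers fall back to frame indices when a format
  carries no time metadata.
* GRO round-trips at 1e-3 nm (fixed columns), XYZ at 1e-7 nm, PDB at
  1e-4 nm; the Brownian-trajectory round-trip test uses XYZ for this
  reason.
* Problem sizes in tests and the acceptance script (100 molecules ×
  10⁴ frames × 4 seeds for diffusion; 64-ion Madelung cell; ≤300-atom
  decomposition toys) are chosen as the smallest sizes at which the
  statistical tolerances (10% on D, 2% on RMSF, 1e-4 on Ewald) have
  comfortable margins.

## Known limitations

Orthorhombic boxes only; no velocities, forces, minimization or dynamics;
no free-energy estimates (mixing *energies* approximate mixing free
energies only insofar as entropic terms cancel between blend and
references); H-bond detection is geometric, not energetic; proton
tunnelling and polarization are outside a fixed-charge classical model;
the limiting-factor rule is a two-descriptor heuristic with a configurable
margin, not a statistical test with calibrated error rates (n = 4 polymers
per drug is far too small for that).
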