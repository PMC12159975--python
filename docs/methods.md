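# Methods

## Thermodynamic layer

The six dissociation constants of the three ternary-assembly paths are
related to on/off rates by `Kd = k_off / k_on` and to standard binding free
energies by `ΔG° = RT ln Kd` (R = 1.98720425×10⁻³ kcal/mol/K, default
T = 300 K, 1 M standard state — the `ln` of a molar Kd implies it). Cycle
closure (`Kd^{A,L}·Kd^{AL,B} = Kd^{L,B}·Kd^{LB,A} = Kd^{A,B}·Kd^{AB,L}`) is
checked at construction: a relative spread above 10⁻⁶ errors in strict
mode, above 10⁻² warns in lenient mode. Experimental constant sets are
noisy, synthetic ones are exact, hence the two regimes.

**α orientation.** The literature writes the cooperativity ratio in both
orientations. We fix the convention by the sign rule: positive
cooperativity means ΔG_coop < 0 and α > 1, which forces
α₁ = Kd^{L,B}/Kd^{AL,B} (binary over ternary-step constant). All three α's
are *defined* through `ΔG_coop,X = −RT ln α_X`, with the ΔG_coop's computed
from the free-energy differences; the identity therefore holds to machine
precision by construction rather than being a numerical coincidence.

**Lenient-closure convention.** When closure is only approximate, the
ternary formation product `[A][L][B]/[ALB]` is taken as the geometric mean
of the three path products (equivalently, ΔG°_ALB is the arithmetic mean of
the three path sums). This is path-symmetric and coincides with each
product when closure is exact.

## Equilibrium solver

All four complex concentrations are rational functions of the free
monomers, so mass balance reduces to three equations in [A], [L], [B]. We
solve them with a damped Newton iteration in log-concentration space
(positivity is structural, not enforced), residuals scaled by each
component's total so convergence (∞-norm < 10⁻¹², cap 200 iterations) is
relative. Steps are capped at 50 log-units and halved until the residual
norm decreases; if Newton stalls, scipy's hybrid Powell solver takes over
from the last iterate. Components with zero total are pinned analytically.
The log parameterization is what makes the solver robust across the
12-orders-of-magnitude Kd range exercised in the tests (10⁻¹²–10⁻³ M).

The independent oracle is the 7-species mass-action ODE system integrated
with BDF (analytic Jacobian, rtol 10⁻¹⁰, atol 10⁻¹⁶·max(totals)); the
steady state is declared when the state change per decade of simulated time
falls below 10⁻⁹·max(totals). Solver and oracle agree to ~10⁻¹² relative in
practice; the advertised contract is 10⁻⁶.

**Recruitment baseline.** A ligand-free system has [ALB] = 0 identically,
so percent recruitment is reported relative to the glue-free [AB] baseline
(mode recorded in the output); the threshold concentration is found by
linear interpolation between grid points and transformed as RT ln C with C
in molar — the standard-state dependence of that number is inherited from
the unit choice and is flagged rather than hidden. Hook-effect unimodality
is asserted in tests only for scenario families constructed to exhibit it
(tight dual ligand edges, weak AB edge); it is not a universal property.

## Nonbonded energetics

Electrostatics use the CHARMM Coulomb constant 332.0636 kcal·Å/(mol·e²)
with a distance-dependent dielectric ε(r) = 2r, so the pair term is
`332.0636·q_iq_j/(2r²)` and decays as r⁻²; a constant ε = 2 mode
(`dielectric="const2"`) is exposed for sensitivity checks — the r⁻² scaling
test distinguishes the two. Van der Waals is Lennard-Jones 12-6 with
CHARMM-style combining (geometric ε, arithmetic rmin halves; the parameter
table carries rmin/2 directly to avoid σ↔rmin confusion, rmin = 2^{1/6}σ).
Only inter-component pairs are ever summed, so bonded exclusions never
arise. No distance cutoff is applied by default — a post-hoc interaction
energy over a finite complex needs none; an optional hard cutoff (no
switching) is available. Ensemble statistics are mean ± sample standard
deviation (n−1; a single frame reports std 0 and is flagged via
`n_frames`), and standard errors assume independent frames — no
autocorrelation correction, a documented limitation for genuinely
correlated trajectories.

Per-residue footprints sum each partner residue's pair energies with the
ligand group per frame; by construction they partition the group total
exactly, which the tests assert to 10⁻⁹ kcal/mol.

**SASA.** Shrake–Rupley with a golden-spiral point lattice (default 960
points, probe 1.4 Å). Coordinates are first re-expressed in a
principal-axes frame (centroid-centered, sign-fixed, right-handed) so the
lattice co-rotates with the molecule and the area is invariant under
rigid-body transforms of the input. Exactly coincident identical atoms are
de-duplicated (shared surface counted once); a boundary tolerance of
10⁻¹² Å decides burial. The nonpolar solvation term is G_np = γ·SASA with
γ = 0.0072 kcal/(mol·Å²). The implementation is cross-checked in the tests
against an analytic sphere and against biotite's independent SASA routine.

## Cooperativity-effect estimator

CE compares **ensemble means** (ternary minus dual), not per-frame
differences — the ensembles are independent samples and no frame pairing
exists. Uncertainty is the root-sum-square of the standard errors of the
contributing means. The ΔIntE_AB term is optional and off by default: the
protein–protein interaction energy converges slowly and the no-AB variant
is the intended high-throughput screen; `ce_full` is computed whenever a
dual A–B ensemble is supplied, and `ce_full − ce_no_ab ≡ ΔIntE_AB` exactly.
The screening IntE axis defaults to the ternary ligand total (AL + LB);
the AL-only axis is reported alongside. Ranking is a total order —
(CE, IntE, ligand id) ascending — making output permutation-invariant, and
the summary counts candidates strictly better than the reference on both
axes, in raw and mass-normalized modes.

## Synthetic data

The generators define the study conditions for every test:

* **Binding scenarios**: Kd's log-uniform in 10⁻⁹–10⁻⁴ M (nanomolar to
  hundred-micromolar, the range typical of glue-mediated ternary systems;
  widened to 10⁻¹²–10⁻³ M in the solver stress suite), totals log-uniform
  around 10⁻⁶ M (recruitment-assay scale), on-rates 10⁵–10⁷ M⁻¹ per unit
  time. Five constants are drawn and the sixth derived from closure, so
  closure is exact to rounding; an α₁ target plants known cooperativity.
* **Toy complexes**: three bead clusters (A, L, B; default 20/8/20 beads,
  radius 2 Å, centroid gaps 10 Å) with zero-sum random charges (±0.2 e),
  LJ ε 0.05–0.2 kcal/mol, rmin/2 1.0–1.5 Å, and optionally a +1/−1
  salt-bridge pair planted at 6 Å across a chosen interface. Ground-truth
  energies are computed by an independent scalar loop (plain `math`,
  no shared code with the vectorized engine) — this dual route is the
  central cross-validation of the energy engine.
* **Planted CE scenarios**: ternary frames scale the L–B (and optionally
  A–B) centroid gap by a stated factor relative to the duals; the default
  0.8 tightening of a salt-bridged interface yields a planted CE of about
  −5 kcal/mol, recovered by the estimator to 10⁻⁸ at zero noise.
  Conformational ensembles add i.i.d. Gaussian coordinate noise
  (default σ = 0.1 Å) — they emulate fluctuation statistics, not MD
  kinetics, correlated motions, or force-field realism, so passing tests
  validate the estimator's arithmetic and statistics, not its accuracy on
  real trajectories.

All generators are pure functions of an integer seed (bit-reproducible).

## Problem sizes

The default verification runs use 100 scenarios for the thermodynamic
identity suite, 50 for solver-vs-kinetics, 30 for pathway independence,
toy complexes up to 200 atoms for the energy oracle, and 500-frame
ensembles for the noisy CE check — sizes at which every contract above is
exercised across its full parameter range while the whole suite completes
in seconds.

## Known limitations

* The equilibrium model is closed (no competing endogenous substrates, no
  cellular context) and the CE estimator omits solvent polarization,
  entropy and internal-strain terms by design — it is a screening
  surrogate for ΔG_coop, not a binding free energy.
* Standard errors ignore frame autocorrelation.
* The distance-dielectric electrostatics can overweight charged contacts;
  the constant-ε mode is provided for sensitivity analysis, not as a
  calibrated alternative.
* PDB is the only structure format; binary trajectory formats are out of
  scope (multi-model PDB is the canonical ensemble carrier).
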