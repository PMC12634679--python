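# Methods

This note documents the models, numerical choices and limitations behind
`hybridfep`, in the order the method runs.

## Scope and philosophy

The package implements everything around the MD engine: structure
bookkeeping, topology/restraint construction, λ protocols, estimators,
cycle solving, scan enumeration and benchmark statistics.  It never runs
protein MD.  Wherever a claim depends on sampling, the sampling comes
from exactly solvable synthetic systems (`toysim`), so every estimator
path is validated against a closed form rather than against another
simulation.  Consequently, passing tests demonstrate the correctness of
the machinery — not the accuracy of any force field or the convergence
of protein simulations, which depend on MD that is out of scope here.

## Structures and the simulation sphere

PDB input is parsed with biotite; author (1-based) residue numbering is
the only convention exposed and only the first model of multi-model
files is kept.  Alternate locations are resolved deterministically:
prefer code `A`, then highest occupancy, then lowest serial.  Writing
and re-reading a structure preserves coordinates to the 3-decimal PDB
precision.

The simulation system is a sphere (default 50 Å diameter) centered on
the mutation site: the Cβ of the mutable residue, or the side-chain
α-hydrogen for glycine.  When the required atom is absent (e.g. a
glycine without hydrogens), an ideal Cβ is reconstructed in the N–CA–C
frame (r = 1.53 Å, θ = 109.5°, improper −120°, values measured from
ideal residue geometry; the reconstruction lands within 0.05 Å of
reference Cβ positions).  Atoms inside the sphere are free; protein
atoms outside are pinned (k = 200 kcal·mol⁻¹·Å⁻²) and excluded from
non-bonded interactions; non-protein atoms outside (waters,
heterogroups) are dropped.  Ionizable residues whose charged group lies
inside the sphere but within 3 Å of the surface are listed for
neutralization, since dielectric screening near the boundary cannot
support a bare charge.  The charged group is located by one reference
atom per type (ARG CZ, LYS NZ, ASP CG, GLU CD, HIS NE2); measuring the
shell from the charged-group atom rather than from any residue atom is a
documented design choice — the underlying convention is not fixed by the
problem itself.

## Residue templates

The template library (JSON, one file per residue plus the acetyl and
N-methylamide caps) records atom names/elements, a bond graph, atom type
codes, partial charges and side-chain internal coordinates rooted in the
N–CA–C(–CB) frame.  Geometry was measured once from ideal residue
conformers (chemical component dictionary) and frozen; rotatable χ
torsions carry canonical defaults (χ1 = −60°, aromatic χ2 = 90°, others
180°).  The charge/type set is deliberately minimal and self-consistent
— neutral side chains sum to exactly 0 e, ionizable ones to ±1 e — and
claims no fidelity to any published force field; force-field parameter
reproduction is a non-goal.  Atom types exist to drive restraint
type-matching (e.g. a hydroxyl-substituted aromatic carbon differs from
an aromatic CH carbon, so a Tyr→Phe comparison stops restraining at Cζ).

Proline is rejected explicitly: its ring closes onto the backbone
nitrogen and cannot be treated as a detachable side chain.

### Mutant side-chain placement

Mutant side chains are built deterministically from template internal
coordinates in the wild-type backbone frame.  The wild-type Cβ is reused
when present, and every χ torsion defined in both residues is copied
from the wild-type conformation, maximizing the initial overlap of
analogous atoms (for Tyr→Phe the whole ring superimposes).  This
replaces an interactive rotamer pick with a reproducible construction —
a deliberate simplification, justified by the observation that the
choice of initial mutant conformation has little effect when the
subsequent sampling is adequate.  L-chirality is preserved by
construction and asserted against ideal reference residues.

### Reference peptides

The unfolded state is a capped peptide in four schemes: ZXZ (natural
flanks, crystal coordinates), AXA/GXG (alanine/glycine side chains on
the natural flank backbones), and X (the mutable residue alone).  Caps
are acetyl (N-terminus) and N-methylamide (C-terminus); where a sequence
neighbor exists beyond the peptide, the cap reuses its backbone
coordinates (the neighbor's CA becomes the cap methyl), otherwise the
cap is built from ideal internal coordinates.  Tripeptide schemes refuse
terminal residues — their reference state would not be comparable.  The
mutable residue always keeps the protein-site coordinates, so protein
and reference legs start from the same local conformation.

## Hybrid topology

Analogous heavy atoms are paired breadth-first from Cα by topological
level.  Within a sibling group, candidate assignments are ranked by
(1) atom-type agreement, (2) similarity of downstream heavy-atom counts,
(3) total initial distance including recursively matched descendants,
(4) alphabetical tie-break.  Criterion 3 evaluates symmetric aromatic
branches (CD1/CD2) by the whole ring, preventing crossed mappings; the
ranking is symmetric, so mapping A→B reversed equals B→A.  Only heavy
atoms participate; hydrogens follow their parent atom for exclusions and
charges.  Glycine has no Cβ, so any mapping involving it is empty — a
valid outcome, not an error.

Restraints (k = 10.0 kcal·mol⁻¹·Å⁻², cutoff 0.5 Å) are a contiguous
prefix of the mapping: the walk stops at the first type mismatch or
distance violation, whichever comes first, and records why.  The uniform
rule applies to the Cβ pair too, making "Cβ only" the minimal non-empty
scheme.  Because the restraint scheme is computed from the placed
residues and the peptide keeps the protein-site coordinates, protein and
reference legs share the scheme by construction — both legs must run
under identical conditions for the cycle to close, which is also why
reference-leg results cannot be precomputed and cached across mutations.

The topology emits: the full A×B exclusion list (every wt side-chain
atom against every mut side-chain atom, hydrogens included), the
deactivated Cβ_wt–Cα–Cβ_mut angle plus every torsion through it, and the
end-state charge table (state 0: wt charged, mut dummy; state 1:
reversed; backbone unchanged).  A net side-chain charge difference
between the end states raises an explicit error — charge-changing
mutations are unsupported because the cycle does not close without
special treatment.  The soft-core van der Waals description is
declarative: the default form replaces r⁶ by r⁶ + α·σ⁶·(1−λ_vdw) with
α = 0.5 (configurable); the functional form is a package choice, since
only a consuming MD engine evaluates it.

## Protocols and budgets

λ schedules are linear (λ_i = i/(n−1)) or sigmoidal, the latter using
the symmetric sine map λ = ½(1 + sin(πs(x−½))/sin(πs/2)) with steepness
s = 1 by default; s → 0 degenerates to linear.  Only monotonicity, the
λ_i + λ_{n−1−i} = 1 symmetry and higher end-point density are treated as
contractual — the exact profile used by any particular MD package is not
reproduced.  Stage 1 λ measures the progress of discharging the wt side
chain, stage 2 of charging the mut side chain, both running 0 → 1.

Preset H is 2 stages × 50 sigmoidal windows × 10 000 steps of 2 fs
(20 ps/window) with 10 replicas: 1 M steps ≙ 2 ns per replica per leg,
20 ns aggregate per leg, 40 ns per cycle.  Preset J doubles the windows
per stage.  Other parameter combinations are reached via explicit
arguments; budgets are exact integer arithmetic, and a legacy mode
reproduces the accounting of single-topology annihilation protocols
(subperturbations × windows × steps at a 1 fs step).  The equilibration
stanza (10 ps optimization, heating to 298 K over 150 ps, 350 ps
restraint release, 0.5 ns free equilibration) is emitted declaratively
into job specs; the toolkit never executes it.  Job specs are
deterministic JSON documents in the package's own dialect — byte-level
compatibility with any MD engine's native input format is a non-goal —
and the restraint table is rendered identically in both legs.

## Estimators

Energies are in kcal/mol; R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298 K
by default, β = 1/RT.  Forward-only exponential averaging is the default
Zwanzig form, evaluated with log-sum-exp so extreme work values cannot
overflow (and are never clipped).

BAR solves, per window interface, the self-consistency condition that
the forward and reverse Fermi-function averages coincide; with equal
sample counts the constant C_i equals ΔG_i, and unequal counts are
handled by the standard ln(n_F/n_R) correction internally.  The residual
is strictly monotone in the trial ΔG, so the root is bracketed and
solved by Brent's method to 10⁻⁷ kcal·mol⁻¹ (the tolerance is a package
choice).  Non-overlapping forward/reverse work distributions attach a
warning to the result rather than failing, since the estimate is then
merely unreliable, not undefined.  An independent fixed-point BAR solver
(a different algorithm) serves as an oracle in the tests — never as the
implementation.

A leg is the arithmetic mean over replicas with SEM = s/√n using the
n−1 sample standard deviation (0 for a single replica).  Cycles subtract
legs and propagate SEMs in quadrature, and refuse legs sampled under
different window structures.  Experimental binding shifts convert via
ΔΔG = RT ln(Ki_mut/Ki_wt).

Sample files are plain CSV (stage, window, λ, U_self, U_forward,
U_reverse) with a commented header; forward evaluations are absent only
for the last window of a stage, reverse only for the first.

## Synthetic fixtures

`toysim` provides two systems with exact answers:

* **Gaussian work distributions** consistent with the Crooks relation:
  forward ~ N(ΔG + βσ²/2, σ²), reverse ~ N(−ΔG + βσ²/2, σ²).  The
  crossing point of the forward and negated-reverse densities is ΔG.
* **A 1-D harmonic λ-coupled system** U_λ = (1−λ)·½k_A x² +
  λ·½k_B(x−d)², sampled per window by Metropolis Monte Carlo with the
  step size adapted to a 0.3–0.7 acceptance ratio during equilibration
  only.  ΔG = ln(k_B/k_A)/(2β) exactly, independent of the displacement
  d — so a pure translation (k_A = k_B, d ≠ 0) is a strong null test,
  and a displaced stiffening transformation exposes λ-discretization
  bias (which shrinks monotonically from 5 to 50 windows).

Metropolis rather than molecular dynamics is intentional: only ensemble
correctness matters for validating estimators.  The default toy protocol
is a reduced single-stage analog of preset H (50 sigmoidal windows, 200
samples/window, 10 replicas) sized to run in well under a second per
replica; the Gaussian calibration study uses 200 seeded repetitions of
10 replicas × 2000 samples.  These sizes are the package's validation
conditions, chosen so the full suite runs interactively.  What the toy
systems do **not** emulate: multi-particle correlations, explicit
solvent, boundary-model artifacts, or conformational trapping — so toy
recovery says nothing about protein sampling adequacy.

One calibration subtlety: with 10 replicas the ratio (mean − truth)/SEM
follows Student's t with 9 degrees of freedom, whose ±3 coverage is
98.6%, not the ~99.7% a normal approximation suggests.  The calibration
test therefore requires ≥96% empirical coverage over the 200 seeded
repetitions, the level consistent with t₉ plus binomial fluctuation.

## Scan enumeration and benchmark statistics

A domain-wide scan excludes: terminal positions (no comparable
tripeptide reference), proline in either role, titratable residues
(ARG/LYS/ASP/GLU) in either role, and TRP/CYS both as targets
(fluorescence interference, disulfide formation) and as wild-type
positions, so every eligible position offers the same 12-residue target
wheel; self-mutations are never emitted.  Histidine is treated as
neutral.  On the classic 56-residue B1-domain sequence these rules give
38 positions × 12 targets = 456 entries.  "Terminal" means exactly the
first and last sequence positions.

Benchmark tables distinguish quantitative records (numeric experimental
ΔΔG) from qualitative ones (class label only, e.g. "totally unstable"),
which enter classification statistics but not error/correlation
statistics.  Figures of merit: MAE, R² (squared Pearson), Spearman ρ
(average ranks on ties), Kendall τ-b (tie-corrected; the choice is inert
on tie-free data), sign accuracy at a threshold (default 0, with an
optional neutrality dead-zone because "correct prediction" conventions
vary), and MCC from the 2×2 stabilizing/destabilizing confusion matrix —
reported as not-available when the experimental data contain one class
only.  Classification statistics are deliberately *not* invariant under
shifting both columns at a fixed threshold; rank statistics are
invariant under any monotone transform.

Confidence intervals use a seeded case-resampling bootstrap (default
10 000 resamples, percentile 2.5/97.5 bounds).  Resamples on which a
statistic is undefined (single-class draws, zero-variance draws) are
redrawn, with a cap of 10× the requested count before erroring.  Both
the point estimate and the bootstrap mean are reported; on small tables
they can differ in the second decimal (e.g. a point MAE of 0.32 with a
bootstrap mean near 0.33), and neither is silently preferred.

## Known limitations

* No MD engine, no solvent model, no long-range electrostatics: job
  specs describe a simulation, they do not run one.
* Charge-changing and proline mutations are rejected rather than
  approximated.
* Template charges/types are a self-consistent stand-in, not a published
  force field; absolute energies from the toy engine have no physical
  meaning beyond the harmonic model itself.
* Reference-peptide caps built without a sequence neighbor use ideal
  geometry and will not match a crystal environment.
* Per-window uncertainty ignores time-series autocorrelation (replicas
  are assumed independent); multi-state estimators over all windows
  simultaneously are out of scope.
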