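# Methods

This note documents the models implemented in `sesgb`, the numerical
choices behind them, and what the synthetic fixtures do and do not
demonstrate.

## Dielectric boundary

The solute/solvent dielectric boundary is a solvent-excluded surface (SES)
realized on an orthogonal grid. Given per-element intrinsic radii
{ρ_C, ρ_H, ρ_N, ρ_O, ρ_S} and a water-probe radius ρ_W, construction is
two-pass:

1. **Accessibility.** A voxel center y is *accessible* if a probe centered
   there clears every atom: |y − x_i| ≥ r_i + ρ_W for all i.
2. **Dilation.** Solvent is the union of probe spheres around accessible
   positions plus the exterior; solute is the complement. This keeps
   reentrant and interstitial volume (where the probe cannot pass) inside
   the solute, which a plain union of van-der-Waals spheres would miss.

Naively testing "distance to the nearest accessible *voxel center* ≤ ρ_W"
overestimates that distance by O(h) and systematically inflates the solute.
We cancel the bias to second order: each candidate accessible center c is
credited its accessibility margin G(c) = min_i(|c − x_i| − r_i − ρ_W).
Because G is 1-Lipschitz, the ball of radius G(c) around c is entirely
accessible, so dist(x, accessible) ≤ |x − c| − G(c). The candidate c is
optimized over a small neighborhood (offsets up to √5 voxels) of the
distance-transform nearest center. The test remains one-sided — a voxel is
never declared solvent unless a genuinely accessible probe position covers
it — so the interstitial SES volume survives exactly. For an isolated
sphere the construction reduces, voxel for voxel, to the vdW ball, as it
should (the reentrant surface of one sphere is the sphere itself).

The grid is padded by (max r_i + 2ρ_W + 2h) per side and its origin is
snapped to multiples of h relative to an anchor point (default: solute
centroid), so rigid translations reproduce energies exactly. Binding
deltas (complex − receptor − ligand) share the complex centroid as anchor;
with aligned voxelizations all ΔΔ terms cancel exactly for non-interacting
partners.

Default spacing is h = 0.5 Å (the customary grid-SES resolution);
convergence studies in the tests use h ∈ {1.0, 0.5, 0.25}.

The boundary itself is the set of voxel faces separating solute from
solvent ("orthogonal grid patches"), each of area h² with an axis-aligned
outward normal.

## Effective Born radii (R6)

The inverse-cube effective Born radius of atom i is the R6 integral over
solvent, evaluated on the patch set via the divergence theorem:

    R_i⁻³ = (1/4π) Σ_p [(c_p − x_i)·n̂_p / |c_p − x_i|⁶] · h²

This is exact for a spherical boundary (R equals the sphere radius for the
central atom) and well-behaved for off-center and buried atoms; tests
compare it against direct volume quadrature. Nonpositive integrals —
possible for atoms grazing staircase artifacts — clamp to the intrinsic
radius and are reported, not fatal.

## Polar solvation: ALPB

Pairs interact through Still's f_GB = sqrt(r² + R_iR_j exp(−r²/4R_iR_j)).
The total polar solvation energy uses the analytical linearized
Poisson–Boltzmann (ALPB) correction:

    ΔG_pol = −(k_e/2) · 1/(1+αβ) · Σ_ij q_iq_j (1/eps_in − e^(−κ f_ij)/eps_out)
             · [1/f_ij + αβ/A]

with α = 0.571412, β = eps_in/eps_out, and A the electrostatic size of the
solute, computed here as A = (3V_SES/4π)^(1/3) from the voxel volume —
exact for spheres, cheap for everything else (an Rg-based estimate would
also be defensible; the volume form was chosen because the validating
limit is the sphere). For A = R the expression reduces to the exact Born
ion result, −(k_e/2)(1/eps_in − 1/eps_out)q²/R. Setting `alpb=None`
recovers canonical Still GB, used in tests of superposition limits.

Monovalent salt enters as Debye–Hückel screening of the solvent term with
κ(Å⁻¹) = sqrt(0.10806·c[mol/L]), the common GB convention near 298 K.
Constants: k_e = 332.0636 kcal·Å/(mol·e²), k_B = 0.0019872 kcal/(mol·K).

## MM-GBSA

Single-trajectory protocol: receptor and ligand conformations are sliced
from each complex snapshot, so intramolecular gas-phase terms cancel and
per snapshot

    ΔG_effective = ΔE_el + ΔE_LJ + ΔΔG_pol + ΔΔG_np

with vacuum Coulomb and Lennard-Jones (Lorentz–Berthelot combining, no
cutoff — these are end-point energies on single structures), polar deltas
from the ALPB chain, and nonpolar deltas γ·ΔSASA with γ = 0.005
kcal/mol/Ų and zero offset by default. SASA is deterministic
golden-spiral Shrake–Rupley (960 points; boundary ties go to the lowest
atom index). LJ parameters come from a JSON sidecar keyed by atom serial,
since PQR carries none and force-field topology parsing is out of scope.

Averaging over snapshots and adding an externally supplied configurational
entropy term gives

    ΔG_bind⁰ = ⟨ΔG_effective⟩ + (−TΔS_conf − 1.92 kcal/mol)

where the 1.92 kcal/mol offset moves the translational-entropy reference
from the gas-phase to the 1 M solution standard state. Entropy itself
(normal-mode analysis) is an input, not computed here.

## Radii optimization

The tunable boundary parameters are the 5-vector (ρ_W, ρ_C, ρ_H, ρ_N,
ρ_O); sulfur stays at its Bondi value 1.80 Å. The objective is

    RMSE_total = w1·RMSE_solv + w2·RMSE_bind

where RMSE_solv covers polar solvation energies of small solutes and
RMSE_bind covers polar binding energies ΔG_bind^pol = ΔE_el + ΔΔG_pol of
complexes. Held-out validation lists are evaluated for reporting only.

Minimization uses canonical DIRECT: normalize to the unit cube, evaluate
the center, then repeatedly (i) select potentially optimal boxes on the
lower-right convex hull of (box half-diagonal, center value) with slack
ε|f_best|, ε = 1e−4; (ii) sample center ± side/3 along each longest
dimension; (iii) trisect, best dimension first. Ties prefer larger boxes,
then earlier creation. The search is deterministic; objectives that raise
are recorded as +∞ and skipped past. Default bounds are 0.3–3.0 Å per
radius, generously covering published boundary radii. No stopping rule
beyond the evaluation budget is imposed — the budget is a required user
choice. Objective evaluation is serial; the evaluation and reduction
order is fixed, so a parallel map over training structures could be added
without changing results.

The trace records every evaluation and can extract the k best points
pairwise separated by ≥ 0.15 Å (max-norm) to inspect distinct local
minima of the radii landscape.

## ΔG⁰ from binding/unbinding statistics

For weakly bound host–guest systems whose trajectories show many
binding/unbinding events,

    ΔG⁰ = −k_B T ln(N_B/N_U) − k_B T ln(V/V₀)

with N_B/N_U the bound/unbound frame counts, V the box volume, and
V₀ = 1660 ų the 1 M per-molecule standard-state volume. A frame is bound
when the host–guest center-of-mass distance is at or below a threshold
taken as the sum of the two radii of gyration (mass-weighted, matching
standard trajectory tooling; a uniform-weight option exists for closed-form
tests). Ties count as bound; classification is memoryless (no dwell-time
debouncing). The temperature defaults to 300 K (a typical production
thermostat) while V₀ keeps its printed 298 K value; both are explicit
parameters because the conventions are routinely mixed in practice. A
threshold-robustness scan (± halfwidth in steps) reports the maximum
relative change of ΔG⁰ and flags instability if any scanned threshold
empties one state.

## Metrics and bootstrap

MSE here is the **mean signed error**, following binding-benchmark usage;
SRC is Spearman's rank correlation (Pearson on average-ranked data).
Zero-variance inputs yield NaN correlations rather than 0. Bootstrap
intervals resample paired rows with replacement (B = 1000 typical,
seeded); two intervals are reported: the normal-approximation form
X̄ ± zσ/√n with σ the bootstrap-distribution standard deviation (kept for
fidelity with common usage — note σ already scales as 1/√n, so this form
shrinks twice), and the percentile interval, which carries the expected
~95% coverage and is the one validated by the Monte-Carlo coverage test.

## Synthetic fixtures: what they show and what they do not

All fixtures are pure functions of their seeds.

- **Born ions / sphere pairs** have closed-form energies and exercise the
  full numerical chain; they validate discretization, not chemistry.
- **Toy complexes** are pocket-like rings (default host 5 + guest 2 atoms,
  C/H/N/O, zero-sum charges, σ ≈ 0.25 e) with guaranteed non-overlap
  (min distance ≥ 0.8(r_i+r_j)). They make binding deltas and the
  optimizer objective well-defined and fast; they do not reproduce real
  host–guest chemistry, force-field charges, or conformational ensembles.
- **Two-state distance series** are Markov chains with a stationary bound
  fraction; the default switch rate 0.09 gives ≈25 transitions per 1000
  frames at p ≈ 0.84, mirroring a realistic weak binder. Consistency tests
  use switch rate 1 (i.i.d. frames) because their tolerances are stated in
  binomial standard errors, which correlated frames would inflate.
- **Planted-radii training sets** compute reference energies with this
  package's own pipeline at known radii (20 solutes + 6 complexes by
  default, h = 0.5 Å). The hydration entries are designed for
  identifiability: four of five are single-element clusters carrying net
  charge, so each atomic radius is pinned nearly independently (real
  mixed-composition molecules allow strong radius compensations that make
  recovery ill-conditioned), and every fifth is a "caliper" pair of atoms
  whose surface gap spans the probe-diameter range, so reentrant sealing
  constrains ρ_W, which convex clusters barely feel. The complexes couple
  all five dimensions through their binding deltas. Recovery of the
  planted 5-vector demonstrates that the objective is informative in all
  five dimensions and that the search works; it says nothing about
  agreement with explicit-solvent reference energies, which are out of
  scope.

Problem sizes used in the shipped tests (toy structures of 2–8 atoms,
grids of h ≥ 0.25 Å, budgets ≤ 3000 evaluations) keep the full suite
runnable on a laptop core in minutes while still crossing every numerical
regime the method uses.

## Known limitations

- Grid SES accuracy is first-order in h at the boundary even with the
  margin correction; Born radii of surface atoms carry a few-percent error
  at h = 0.5 Å.
- No Poisson–Boltzmann reference solver, no charge-hydration asymmetry,
  no multi-dielectric or membrane geometries.
- The R6 patch quadrature has no short-range self-correction near the
  atom's own surface; the sphere oracle bounds the resulting error.
- Periodic-boundary imaging, conformational sampling, and entropy
  computation are upstream concerns; inputs are assumed imaged and
  entropy is supplied by the caller.
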