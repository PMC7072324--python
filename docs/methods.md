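# Methods

This note records the models, conventions, parameter choices and
numerical decisions behind `fretscreen`, in the order the pipeline uses
them. All energies are kJ/mol; distances are nm unless a PDB context
makes them Å (atom coordinates only).

## 1. Steady-state quenching (`photophysics`)

**Model.** Stern–Volmer: F₀/F = 1 + K_SV[Q]. The fit is unweighted
least squares on (F₀/F, [Q]) with a **free intercept**: for clean 1:1
static quenching the intercept must be ~1, so leaving it free turns it
into a quality check instead of an assumption. F₀ is the measured
intensity of the first titration point, which must be at [Q] = 0.

The reported K_SV uncertainty is the ordinary least-squares slope
standard error. Because every F₀/F point shares the same noisy F₀
reference (a common-mode multiplicative error OLS residuals cannot
see), this understates the true sampling spread by roughly 20–30% for
1% multiplicative noise on six points; the docstring discloses this and
the test suite calibrates recovery against a Monte-Carlo sampling sigma
rather than the fitted one.

**Mechanism classification.** k_q = K_SV/τ₀ with τ₀ the unquenched
donor lifetime. Decision table (`classify_quenching`): k_q above the
diffusion limit (default 10¹⁰ M⁻¹s⁻¹) *and* lifetime unchanged within a
relative tolerance (default 5%) → `static`; k_q at or below the limit
*and* lifetime shortened in proportion to the intensity → `dynamic`;
anything else → `ambiguous`. Both thresholds are explicit keyword
arguments.

## 2. Lifetime fitting (`photophysics`)

TCSPC decays are fitted as a1·exp(−t/τ1) + a2·exp(−t/τ2) + baseline by
weighted nonlinear least squares, **tail fitting from the peak channel**
(no instrument-response deconvolution — adequate for nanosecond
lifetimes on sub-nanosecond instrument response). Weights are the
standard Poisson 1/max(counts, 1). Robustness choices:

* five deterministic multi-starts (seeded spreads around a
  moment-based initial guess with fixed lifetime-ratio patterns), best
  reduced-χ² wins;
* lifetimes bounded to 10× the observation window and the baseline to
  [0, peak], which removes the classic degeneracy where a huge τ trades
  against a free baseline;
* at least 20 post-peak channels required.

The headline lifetime is the **amplitude-weighted mean**
⟨τ⟩ = Σaᵢτᵢ/Σaᵢ — the convention appropriate for intensity-derived
efficiencies on nearly mono-exponential donors (the intensity-weighted
mean Σaᵢτᵢ²/Σaᵢτᵢ is the other common choice; for the mono-exponential
decays used here they coincide).

## 3. FRET distances (`fret`)

E = R₀⁶/(R₀⁶ + R⁶), inverted as R = R₀((1−E)/E)^(1/6). Three
efficiency routes:

* donor quenching: E = 1 − F_DA/F_D;
* acceptor enhancement: E = (F_AD/F_A − 1)·(ε_A/ε_D) with the
  acceptor/donor extinction coefficients at the excitation wavelength
  (defaults ε_A = 2700, ε_D = 1500 M⁻¹cm⁻¹);
* lifetime reduction: E = 1 − τ_DA/τ_D.

Uncertainty is first-order propagation, σ_R² = (∂R/∂E·σ_E)² +
(∂R/∂R₀·σ_R₀)² with ∂R/∂E = −R/(6E(1−E)) and ∂R/∂R₀ = R/R₀. Multiple
method estimates are combined as an **unweighted mean** (the methods are
not independent enough for inverse-variance weighting to be honest),
with σ = max(RMS of the individual sigmas, half the spread) so the
combined sigma can never be smaller than the disagreement between
methods. `forster_radius` implements R₀ = 0.02108·(κ²n⁻⁴Q_D·J)^(1/6) nm
with J in M⁻¹cm⁻¹nm⁴ for users who derive R₀ from spectra; the pipeline
default is R₀ = 2.5 ± 0.1 nm.

## 4. Structure measurements (`structure`)

**Parsing.** PDB files are read through Biopython: first MODEL only,
highest-occupancy altloc (ties prefer 'A'), Bondi van der Waals radii
with a warned 1.7 Å default for unknown elements.

**Anchors.** Donor: centroid of the nine Trp indole-ring atoms
(CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2); all nine are required.
Acceptor: the RNA 5′-terminal residue's P atom, falling back to O5′
then C5′ (both ′ and * primed-name spellings accepted). D_DA is the
Euclidean distance between the two, in nm.

**SASA.** Shrake–Rupley with golden-spiral quadrature points (default
960 per atom), probe 1.4 Å, neighbour search via a cKD-tree. Per-atom
areas sum exactly to the total, so residue SASA is a partition.

**Superposition and RMSD.** Kabsch SVD superposition constrained to a
proper rotation (det +1). The default RMSD is **all-atom, no-fit**:
docked poses share the receptor's frame, so no-fit RMSD is the right
dissimilarity for clustering poses (a fitted RMSD would call two poses
on opposite faces of the protein identical). `fit=True` and chain/range
selections are available.

## 5. Screening (`screening`)

* Window: [R − σ + linker, R + σ + linker] with a 0.1 nm dye-linker
  offset — the dye sits one linker beyond the geometric 5′ anchor, so
  the experimental interval is shifted, not widened. Bounds inclusive.
* Clustering: greedy leader clustering in docking-rank order with a
  0.1 nm RMSD threshold; a model joins the first leader closer than the
  threshold, else founds a group. Representatives are therefore always
  the best-docking-ranked member of their group, and the procedure is
  deterministic and order-reproducible.
* Ranking: representatives sorted by ascending ΔG_B; ties broken by
  docking rank. An empty window yields a report with `status: "empty"`
  rather than an error.
* The distance histogram uses 0.5 nm bins over [0, 7] nm.

## 6. Energetics (`energetics`)

ΔG_B = ΔG_nonpol + ΔE_MM + (−TΔS) + ΔG_pol, with the identity enforced
at construction. The polar term is *ingested* from external
Poisson–Boltzmann solver output via the component-table reader (solving
PB is out of scope); a screened-Coulomb surrogate exists solely to give
synthetic pipelines a physically-shaped polar term and is labelled
SYNTHETIC.

* Nonpolar: G = γ·SASA + β with γ = 2.27 kJ mol⁻¹ nm⁻² and
  β = 3.84 kJ/mol. β is a per-state constant, so it cancels in ΔG; both
  coefficients are keyword-overridable for other parameterisations.
* MM energy: pairwise Coulomb (interior dielectric, default 2) plus
  Lennard-Jones 12-6 with Lorentz–Berthelot combination, exclusions and
  a cutoff — a stand-in for toy systems, not a force field.
* Quasi-harmonic entropy: eigenvalues λᵢ (amu·nm²) of the mass-weighted
  coordinate covariance define modes ωᵢ = √(k_BT/λᵢ); T·S is the
  quantum harmonic-oscillator sum. MD units are used throughout
  (1 kJ/mol = 1 amu·nm²/ps² exactly; k_B = 0.008314462618 kJ/mol/K,
  ħ = 6.35077993×10⁻² kJ·ps/mol). Rigid-body motion must be removed
  beforehand; eigenvalues below 10⁻¹² amu·nm² are dropped.
* Component tables: two CSV layouts recognised by header — per-state
  (`model_id,label,E_elec,E_vdw,TS,G_pol,G_nonpol`) and per-binding
  delta (`model_id,dG_nonpol,dE_MM,minus_TdS,dG_pol[,dG_B][,D_DA]`).
  A stated dG_B disagreeing with the component sum by more than 0.5%
  is an error naming the line. Reported totals are also rounded to 3
  significant figures, the usual precision of published component
  tables.

## 7. Synthetic data (`synthetic_data`)

All generators are bit-reproducible given (spec, seed) and write a JSON
manifest of every planted fact.

* Titrations: F([Q]) = F₀/(1 + K_SV[Q]) with multiplicative Gaussian
  noise (CV 1% default) — the dominant steady-state instrument noise.
* Decays: biexponential expectations scaled to a 10⁴-count peak,
  Poisson-sampled per channel; the noiseless mode keeps the exact
  expectation so round-trip fits are exact.
* Pose ensembles: a rigid toy receptor (complete Trp146 indole ring,
  centroid exactly at the origin) and a toy RNA (5′ P at the template
  origin) — minimal valid PDB constructs, since the screening math
  needs geometry, not chemistry. Each pose translates the ligand so
  D_DA is exact; cluster members jitter the placement *direction* only,
  preserving D_DA while keeping intra-cluster no-fit RMSD below 40% of
  the clustering threshold (the no-fit RMSD of a pure ligand shift d is
  d·√(n_lig/n_total), which makes the jitter budget analytic).
  Docking ranks are a seeded permutation; planted energies make the
  chosen cluster's representative the global optimum. Default plan: 50
  poses, 16 in-window in 5 clusters (5/4/3/2/2 members at 3.9/3.8/4.1/
  4.0/4.2 nm), 34 scattered outside.
* Harmonic ensembles: independent Gaussian coordinates with the
  classical variance k_BT/k per degree of freedom, for entropy
  validation against the closed-form oscillator entropy.

## 8. Verification strategy

Where a published number exists, a test recomputes it from its stated
inputs (quenching rate, both Förster inversions, ledger sums, ranking,
window survival). Where the raw data were never deposited, closed-loop
statistical substitutes stand in: K_SV recovery on synthetic titrations
against a Monte-Carlo 3σ criterion, biexponential round trips, SASA
against the single-sphere closed form (<1%) and an independent
implementation (mdtraj), Kabsch RMSD against a quaternion
(Horn-method) oracle at 10⁻⁸, quasi-harmonic T·S within 2% of the
closed form at 10⁵ snapshots, and exact recovery of the planted
50 → 16 → 5 reduction by the full pipeline.
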