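# fretscreen

Integrative screening of docked protein–RNA models against fluorescence
observables, built around the complex between the p53 DNA-binding domain
(DBD) and the microRNA miR4749.

## The scientific problem

The p53 DBD contains a single tryptophan (Trp146) whose intrinsic
fluorescence reports on its environment. When a dye-labelled RNA binds
nearby, three things happen that can be measured at the bench:

1. **Quenching.** Titrating the RNA quenches the Trp emission. The
   Stern–Volmer slope K_SV and the apparent bimolecular rate
   k_q = K_SV/τ₀ diagnose the mechanism: a k_q far above the diffusion
   limit (~10¹⁰ M⁻¹s⁻¹) together with an unchanged fluorescence lifetime
   indicates *static* quenching, i.e. a ground-state complex.
2. **FRET.** With Trp146 as donor and a dye on the RNA 5′ end as
   acceptor, the transfer efficiency E falls with the sixth power of
   their separation: E = R₀⁶/(R₀⁶ + R⁶). E can be estimated three ways
   (donor quenching, acceptor enhancement, donor lifetime reduction) and
   each inverts to a donor–acceptor distance R.
3. **Docking.** Computational docking produces tens of candidate
   complex geometries. The FRET distance becomes an experimental
   restraint: only poses whose geometric donor–acceptor distance D_DA
   (Trp146 indole-ring centroid to RNA 5′ phosphate) falls inside the
   FRET window survive. Survivors are grouped by RMSD and the group
   representatives are ranked by an MM-PBSA–style binding free energy
   ΔG_B = ΔG_nonpol + ΔE_MM + (−TΔS) + ΔG_pol; the lowest ΔG_B wins.

`fretscreen` implements every step of that chain — quenching analysis,
TCSPC lifetime fitting, FRET inversion with error propagation, PDB
geometry (anchors, SASA, Kabsch superposition, RMSD), window filtering,
greedy RMSD clustering, energy bookkeeping — plus seeded synthetic-data
generators so the whole pipeline can be tested closed-loop against
planted ground truth.

## Worked example

Generate a complete synthetic study (50 docked poses with 16 planted
inside the FRET window in 5 clusters, a quenching titration, three TCSPC
decays, docking scores and an energy ledger), then run the pipeline:

```python
from pathlib import Path
from fretscreen import io as fio, screening as sc, synthetic_data as sd

root = Path("demo"); root.mkdir(exist_ok=True)
_, _, manifest = sd.gen_pose_ensemble(sd.PoseEnsembleSpec(), seed=7, out_dir=root)
fio.write_titration_csv(sd.gen_titration(sd.TitrationSpec(), seed=7),
                        root / "titration.csv")
for key, tau in {"free": 2.79, "donor": 2.82, "donor_acceptor": 2.68}.items():
    fio.write_decay_csv(
        sd.gen_decay(sd.DecaySpec(amplitudes=(1.0, 0.0),
                                  lifetimes_ns=(tau, tau)), seed=7),
        root / f"{key}.csv")

config = {
    "titration": str(root / "titration.csv"),
    "decays": {k: str(root / f"{k}.csv")
               for k in ("free", "donor", "donor_acceptor")},
    "fret": {"r0": 2.5, "r0_sigma": 0.1, "distance": {"R": 3.9, "sigma": 0.3}},
    "screening": {"poses_dir": str(root / "poses"),
                  "scores_csv": str(root / "scores.csv"),
                  "donor_chain": "A", "donor_residue": 146,
                  "acceptor_chain": "B",
                  "linker_offset": 0.1, "rmsd_threshold": 0.1},
    "energies_csv": str(root / "energies.csv"),
}
report = sc.run_pipeline(config, seed=0)
p = report.photophysics
print("K_SV        ", p["K_SV_per_M"])
print("k_q         ", p["k_q_per_M_s"], "->", p["quenching_mechanism"])
print("window (nm) ", report.window)
print("retained    ", len(report.retained), "of", len(report.distances))
print("clusters    ", len(report.clusters.groups))
print("best model  ", report.best_model, "dG_B =",
      report.energies[report.best_model])
print("planted best", manifest["planted_best_model"])
```

Output (exact, given these seeds):

```
K_SV         174128.19759362718
k_q          62570926649180.18 -> static
window (nm)  (3.7, 4.3)
retained     16 of 50
clusters     5
best model   pose_000 dG_B = -55089.89221199999
planted best pose_000
```

The fitted K_SV sits 3.6% from the generator's 1.68×10⁵ M⁻¹ (1%
multiplicative noise on six points), k_q ≈ 6.3×10¹³ M⁻¹s⁻¹ is three
orders of magnitude above the diffusion limit while the fitted lifetimes
are unchanged — hence "static" — and the pipeline recovers the planted
50 → 16 → 5 reduction and the planted best model exactly.

The FRET arithmetic is also available piecewise:

```python
from fretscreen import fret
est = fret.efficiency_from_lifetimes(2.68, 2.82)   # E = 0.04964...
pair = fret.ForsterPair(R0=2.5, R0_sigma=0.1)
d = fret.distance_from_efficiency(est, pair)
print(d.R, d.R_sigma)   # 4.08891235584501 0.16355649423380042
```

Everything is also exposed on the command line, e.g.:

```bash
fretscreen fret distance -e 0.0496          # {"R_nm": 4.0895..., ...}
fretscreen quench classify --k-q 6.02e13 --tau-free 2.79 --tau-quenched 2.82
fretscreen screen run --config config.yaml --seed 0
fretscreen simulate poses --seed 7 --out demo/
```

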