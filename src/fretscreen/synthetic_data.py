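"""Synthetic input generators for closed-loop testing of the pipeline.

No raw data are deposited for the kind of study this package supports
(quencher titrations, TCSPC decays, docked pose ensembles, MD snapshot
ensembles), so every pipeline input can be generated here with known ground
truth instead:

* Stern-Volmer titrations F([Q]) = F0 / (1 + K_SV [Q]) with multiplicative
  Gaussian noise (the dominant steady-state instrument noise);
* biexponential TCSPC decays with Poisson counting noise, acquired to a
  target peak count;
* rigid toy receptor/ligand pose ensembles with exactly controlled
  donor-acceptor distances, planted RMSD clusters and planted best model;
* Gaussian ensembles of harmonic oscillators for entropy validation.

All generators are bit-reproducible given (spec, seed), and every planted
fact is recorded in a machine-readable manifest so tests can close the loop
through the analysis modules.

The toy molecules are minimal valid PDB constructs (a tryptophan with a
complete indole ring, an RNA-like chain with a 5' phosphate): the screening
math needs geometry, not chemistry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .photophysics import DecayCurve, EmissionSpectrum, QuenchTitration
from .structure import Atom, StructureModel, write_pdb

__all__ = [
    "TitrationSpec",
    "DecaySpec",
    "ClusterPlan",
    "PoseEnsembleSpec",
    "HarmonicSpec",
    "gen_titration",
    "gen_emission_spectra",
    "gen_decay",
    "gen_pose_ensemble",
    "gen_harmonic_ensemble",
    "DEFAULT_CONCENTRATIONS_M",
]

#: default quencher concentrations: 0 plus 0.5-2.5 uM in 0.5 uM steps, the
#: usual titration range for a ~1e5 M^-1 affinity at ~1 uM protein
DEFAULT_CONCENTRATIONS_M = (0.0, 0.5e-6, 1.0e-6, 1.5e-6, 2.0e-6, 2.5e-6)


@dataclass(frozen=True)
class TitrationSpec:
    """Parameters of a synthetic static-quenching titration."""

    K_SV: float = 1.68e5                     # M^-1
    F0: float = 1.0e6                        # arbitrary units
    concentrations: tuple = DEFAULT_CONCENTRATIONS_M
    noise_cv: float = 0.01                   # multiplicative Gaussian CV
    analysis_wavelength: float = 346.0

    def __post_init__(self) -> None:
        if self.K_SV < 0 or self.F0 <= 0 or self.noise_cv < 0:
            raise ValueError("K_SV >= 0, F0 > 0 and noise_cv >= 0 required")


@dataclass(frozen=True)
class DecaySpec:
    """Parameters of a synthetic biexponential TCSPC decay."""

    amplitudes: tuple = (1.0, 0.0)           # relative a1, a2
    lifetimes_ns: tuple = (2.79, 2.79)       # tau1, tau2
    peak_counts: int = 10000                 # acquisition stop criterion
    t_max_ns: float = 30.0
    n_channels: int = 600
    poisson: bool = True

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 2 or len(self.lifetimes_ns) != 2:
            raise ValueError("two amplitudes and two lifetimes required")
        if min(self.lifetimes_ns) <= 0 or min(self.amplitudes) < 0:
            raise ValueError("lifetimes must be positive, amplitudes non-negative")
        if sum(self.amplitudes) <= 0:
            raise ValueError("amplitudes cannot both be zero")


@dataclass(frozen=True)
class ClusterPlan:
    """One planted cluster of docked poses sharing a donor-acceptor distance."""

    n_members: int
    dda_nm: float

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.dda_nm <= 0:
            raise ValueError("cluster needs >= 1 member and a positive distance")


@dataclass(frozen=True)
class PoseEnsembleSpec:
    """Plan for a synthetic docked-pose ensemble with planted structure.

    The defaults mirror the study conditions the screening procedure is built
    for: 50 poses, 16 of which fall inside the 3.7-4.3 nm FRET window and
    form 5 tight clusters; the remainder are scattered outside the window.
    ``best_cluster`` names the cluster whose representative is planted as the
    energetically best model.
    """

    clusters: tuple = (
        ClusterPlan(5, 3.9), ClusterPlan(4, 3.8), ClusterPlan(3, 4.1),
        ClusterPlan(2, 4.0), ClusterPlan(2, 4.2),
    )
    out_of_window_dda_nm: tuple = tuple(
        [1.2, 1.5, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0, 3.1, 3.2, 3.3, 3.4,
         3.45, 3.5, 3.55, 3.6, 4.45, 4.5, 4.6, 4.7, 4.8, 4.9, 5.0, 5.1,
         5.2, 5.3, 5.4, 5.5, 5.6, 5.7, 5.8, 5.9, 6.0]
    )
    best_cluster: int = 0
    rmsd_threshold_nm: float = 0.1
    score_range: tuple = (-250.0, -180.0)    # docking scores, lower = better

    @property
    def n_in_window(self) -> int:
        return sum(c.n_members for c in self.clusters)

    @property
    def n_poses(self) -> int:
        return self.n_in_window + len(self.out_of_window_dda_nm)


@dataclass(frozen=True)
class HarmonicSpec:
    """Plan for a Gaussian ensemble of independent harmonic oscillators."""

    force_constants: tuple = (1000.0,)   # kJ mol^-1 nm^-2, one per atom (isotropic)
    masses_amu: tuple = (12.0,)
    temperature_K: float = 300.0
    n_snapshots: int = 100000

    def __post_init__(self) -> None:
        if min(self.force_constants) <= 0 or min(self.masses_amu) <= 0:
            raise ValueError("force constants and masses must be positive")
        if self.temperature_K < 0 or self.n_snapshots < 2:
            raise ValueError("need T >= 0 and >= 2 snapshots")


# ---------------------------------------------------------------------------
# photophysics inputs
# ---------------------------------------------------------------------------

def gen_titration(spec: TitrationSpec, seed: int) -> QuenchTitration:
    """Static-quenching titration F([Q]) = F0 / (1 + K_SV [Q]) + noise.

    Multiplicative Gaussian noise of coefficient of variation ``noise_cv``
    is applied to every point except the [Q] = 0 reference is noised too
    (all points share the instrument noise model).
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    ideal = spec.F0 / (1.0 + spec.K_SV * conc)
    if spec.noise_cv > 0:
        ideal = ideal * (1.0 + spec.noise_cv * rng.standard_normal(conc.size))
    return QuenchTitration(
        quencher_concentrations=conc, peak_intensities=ideal,
        analysis_wavelength=spec.analysis_wavelength,
    )


def gen_emission_spectra(spec: TitrationSpec, seed: int,
                         wavelengths_nm: np.ndarray | None = None) -> list[EmissionSpectrum]:
    """Render the titration as Gaussian emission bands peaked at 346 nm.

    One spectrum per quencher concentration, each a Gaussian band (55 nm
    FWHM, typical of tryptophan emission in water) whose peak follows the
    Stern-Volmer law, with the titration's multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    wl = (np.arange(305.0, 581.0, 1.0) if wavelengths_nm is None
          else np.asarray(wavelengths_nm, dtype=float))
    sigma_nm = 55.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    spectra = []
    for q in spec.concentrations:
        peak = spec.F0 / (1.0 + spec.K_SV * q)
        band = peak * np.exp(-0.5 * ((wl - spec.analysis_wavelength) / sigma_nm) ** 2)
        if spec.noise_cv > 0:
            band = band * (1.0 + spec.noise_cv * rng.standard_normal(wl.size))
        spectra.append(EmissionSpectrum(
            wavelengths=wl, intensities=np.clip(band, 0.0, None),
            excitation_wavelength=295.0, label=f"[Q]={q:g} M",
        ))
    return spectra


def gen_decay(spec: DecaySpec, seed: int) -> DecayCurve:
    """Biexponential TCSPC decay scaled so the peak reaches ``peak_counts``.

    Expected counts follow a1 exp(-t/tau1) + a2 exp(-t/tau2); with
    ``poisson=True`` each channel is Poisson-sampled (photon counting
    noise), otherwise the noiseless expectation is rounded.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, spec.t_max_ns, spec.n_channels)
    a1, a2 = spec.amplitudes
    t1, t2 = spec.lifetimes_ns
    expected = a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)
    expected *= spec.peak_counts / expected.max()
    # noiseless mode keeps the exact expectation so round-trip fits are exact
    counts = rng.poisson(expected).astype(float) if spec.poisson else expected
    return DecayCurve(times=t, counts=counts, peak_target_counts=spec.peak_counts)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def _toy_receptor() -> list[Atom]:
    """A rigid toy protein (chain A) with one complete tryptophan.

    The indole ring atoms of TRP 146 lie on a ring of radius 1.2 A centred
    at the origin, so the donor centroid is exactly (0, 0, 0). A short
    backbone of glycines gives the receptor enough atoms that all-atom RMSD
    between poses is dominated by neither partner alone.
    """
    atoms: list[Atom] = []
    ring_names = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    for k, name in enumerate(ring_names):
        angle = 2.0 * math.pi * k / len(ring_names)
        element = "N" if name.startswith("N") else "C"
        atoms.append(Atom(name, element, "TRP", 146, "A",
                          np.array([1.2 * math.cos(angle), 1.2 * math.sin(angle), 0.0]),
                          vdw_radius=1.55 if element == "N" else 1.70))
    atoms.append(Atom("CB", "C", "TRP", 146, "A", np.array([0.0, 0.0, 1.5])))
    atoms.append(Atom("CA", "C", "TRP", 146, "A", np.array([0.0, 0.8, 2.7])))
    # glycine backbone arc below the Trp
    for i, resnum in enumerate(range(140, 146)):
        angle = 0.5 * i
        pos = np.array([6.0 * math.cos(angle), 6.0 * math.sin(angle), 4.0])
        atoms.append(Atom("CA", "C", "GLY", resnum, "A", pos))
        atoms.append(Atom("N", "N", "GLY", resnum, "A", pos + np.array([0.0, 0.0, 1.2]),
                          vdw_radius=1.55))
        atoms.append(Atom("O", "O", "GLY", resnum, "A", pos + np.array([1.0, 0.0, -1.0]),
                          vdw_radius=1.52))
    return atoms


def _toy_rna_template() -> list[Atom]:
    """A toy RNA strand (chain B) whose residue-1 P atom sits at the origin."""
    atoms: list[Atom] = []
    for resnum in range(1, 4):
        base = np.array([0.0, 0.0, 5.5 * (resnum - 1)])
        names = (("P", "P", 1.80), ("O5'", "O", 1.52),
                 ("C5'", "C", 1.70), ("C4'", "C", 1.70), ("N1", "N", 1.55))
        offsets = (np.zeros(3), np.array([1.0, 0.5, 0.8]),
                   np.array([2.0, 1.0, 1.6]), np.array([3.0, 0.5, 2.4]),
                   np.array([4.0, 0.0, 3.0]))
        for (name, element, r), off in zip(names, offsets):
            atoms.append(Atom(name, element, "U", resnum, "B", base + off, vdw_radius=r))
    return atoms


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# well-separated cluster directions (unit vectors); the receptor sits near
# the origin so these spread the in-window poses over distinct regions
_CLUSTER_DIRECTIONS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
    [0.0, -1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
    [0.707, 0.707, 0.0], [0.707, -0.707, 0.0],
])


def gen_pose_ensemble(spec: PoseEnsembleSpec, seed: int,
                      out_dir: str | Path | None = None):
    """Build a pose ensemble with exactly controlled D_DA and planted clusters.

    Every pose shares the same rigid toy receptor; the toy RNA ligand is
    rigidly translated so its 5' P atom lies at exactly the planned
    donor-acceptor distance from the tryptophan indole centroid (to < 1e-6
    nm). Members of a planted cluster share their leader's distance and
    direction up to a small angular jitter chosen so that all-atom no-fit
    RMSD within a cluster stays below 40% of the clustering threshold while
    distinct clusters stay far apart. Docking scores are drawn from the
    planned score range and assigned so that rank order is a seeded
    permutation of the poses; per-model binding free energies are planted so
    that the representative of ``spec.best_cluster`` is the energetic
    optimum.

    Returns
    -------
    (models, sites, manifest) : (list[StructureModel], SitePair, dict)
        Models sorted by docking score (rank order); the manifest records
        every planted fact. With ``out_dir`` set, also writes
        ``poses/<id>.pdb``, ``scores.csv``, ``energies.csv`` and
        ``manifest.json`` in the pipeline's file dialects.
    """
    from .structure import SitePair, trp_ring_centroid

    if len(spec.clusters) > len(_CLUSTER_DIRECTIONS):
        raise ValueError(
            f"at most {len(_CLUSTER_DIRECTIONS)} planted clusters supported")
    rng = np.random.default_rng(seed)

    receptor = _toy_receptor()
    ligand_template = _toy_rna_template()
    probe = StructureModel("probe", receptor)
    centroid_nm = trp_ring_centroid(probe, "A", 146)

    n_rec = len(receptor)
    n_lig = len(ligand_template)
    n_tot = n_rec + n_lig
    rmsd_scale = math.sqrt(n_lig / n_tot)   # no-fit RMSD per nm of ligand shift

    plans = []  # (pose_index order of creation) -> dict of planted facts
    placements = []  # P-atom positions in nm

    for ci, cluster in enumerate(spec.clusters):
        direction = _unit(_CLUSTER_DIRECTIONS[ci])
        # intra-cluster jitter: ligand shift d gives RMSD d * rmsd_scale;
        # keep member-to-leader RMSD below 0.4 * threshold
        max_shift_nm = 0.4 * spec.rmsd_threshold_nm / rmsd_scale
        for mi in range(cluster.n_members):
            if mi == 0:
                v = direction
            else:
                perp = rng.standard_normal(3)
                perp -= perp.dot(direction) * direction
                angle = (max_shift_nm / cluster.dda_nm) * rng.uniform(0.2, 0.9)
                v = _unit(direction + angle * _unit(perp))
            placements.append(centroid_nm + cluster.dda_nm * v)
            plans.append({"cluster": ci, "dda_nm": cluster.dda_nm})

    for dda in spec.out_of_window_dda_nm:
        v = _unit(rng.standard_normal(3))
        placements.append(centroid_nm + dda * v)
        plans.append({"cluster": None, "dda_nm": float(dda)})

    n_poses = len(plans)
    # seeded rank permutation and evenly spread docking scores
    order = rng.permutation(n_poses)
    lo, hi = spec.score_range
    scores_sorted = np.linspace(lo, hi, n_poses)
    scores = np.empty(n_poses)
    scores[order] = scores_sorted     # order[k] is the pose holding rank k

    models: list[StructureModel] = []
    for idx, (plan, p_nm) in enumerate(zip(plans, placements)):
        shift_angstrom = p_nm * 10.0  # template P is at the origin (Angstrom)
        atoms = receptor + [
            Atom(a.name, a.element, a.residue_name, a.residue_number,
                 a.chain_id, a.coordinates + shift_angstrom, a.vdw_radius)
            for a in ligand_template
        ]
        model_id = f"pose_{idx:03d}"
        models.append(StructureModel(model_id, atoms, float(scores[idx])))
        plan["model_id"] = model_id
        plan["docking_score"] = float(scores[idx])

    models.sort(key=lambda m: m.docking_score)

    # planted energies: delta-ledger components whose sum ranks best_cluster first
    cluster_base = {ci: -4.0e4 - rng.uniform(0, 5e3) for ci in range(len(spec.clusters))}
    cluster_base[spec.best_cluster] = -5.5e4
    energies = {}
    for plan in plans:
        ci = plan["cluster"]
        base = cluster_base[ci] if ci is not None else -1.0e4
        dg_b = base + rng.uniform(0, 500)
        dg_nonpol = -30.0 - rng.uniform(0, 8)
        de_mm = 2.7e4 + rng.uniform(0, 500)
        minus_tds = 530.0 + rng.uniform(0, 15)
        dg_pol = dg_b - dg_nonpol - de_mm - minus_tds
        energies[plan["model_id"]] = {
            "dG_nonpol": dg_nonpol, "dE_MM": de_mm,
            "minus_TdS": minus_tds, "dG_pol": dg_pol, "dG_B": dg_b,
        }
        plan["dG_B"] = dg_b

    # the planted best model: best-ranked member of the best cluster
    best_members = [p for p in plans if p["cluster"] == spec.best_cluster]
    planted_best = min(best_members, key=lambda p: p["docking_score"])["model_id"]
    # make the planted representative carry its cluster's minimum energy
    member_ids = [p["model_id"] for p in best_members]
    min_e = min(energies[m]["dG_B"] for m in member_ids)
    rep_row = energies[planted_best]
    delta_fix = (min_e - 100.0) - rep_row["dG_B"]
    rep_row["dG_pol"] += delta_fix
    rep_row["dG_B"] += delta_fix
    for p in plans:
        if p["model_id"] == planted_best:
            p["dG_B"] = rep_row["dG_B"]

    sites = SitePair(donor_chain="A", donor_residue=146, acceptor_chain="B",
                     linker_offset=0.1)
    manifest = {
        "seed": seed,
        "n_poses": n_poses,
        "n_in_window": spec.n_in_window,
        "n_clusters": len(spec.clusters),
        "rmsd_threshold_nm": spec.rmsd_threshold_nm,
        "planted_best_model": planted_best,
        "poses": sorted(plans, key=lambda p: p["docking_score"]),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        pose_dir = out_dir / "poses"
        pose_dir.mkdir(parents=True, exist_ok=True)
        for m in models:
            write_pdb(m, pose_dir / f"{m.model_id}.pdb")
        with (out_dir / "scores.csv").open("w") as fh:
            fh.write("model_id,score\n")
            for m in models:
                fh.write(f"{m.model_id},{m.docking_score:.6f}\n")
        with (out_dir / "energies.csv").open("w") as fh:
            fh.write("model_id,dG_nonpol,dE_MM,minus_TdS,dG_pol,dG_B\n")
            for m in models:
                e = energies[m.model_id]
                fh.write(f"{m.model_id},{e['dG_nonpol']:.6f},{e['dE_MM']:.6f},"
                         f"{e['minus_TdS']:.6f},{e['dG_pol']:.6f},{e['dG_B']:.6f}\n")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return models, sites, manifest


def gen_harmonic_ensemble(spec: HarmonicSpec, seed: int) -> np.ndarray:
    """Sample a classical Gaussian ensemble of isotropic harmonic atoms.

    Each atom fluctuates independently in x, y, z with variance
    k_B T / k (nm^2), the classical equilibrium distribution of a harmonic
    oscillator; at T = 0 the ensemble collapses to a point.

    Returns an (n_snapshots, n_atoms, 3) array in nm.
    """
    from .energetics import KB_KJ_PER_MOL_K

    rng = np.random.default_rng(seed)
    k = np.asarray(spec.force_constants, dtype=float)
    n_atoms = k.size
    std = np.sqrt(KB_KJ_PER_MOL_K * spec.temperature_K / k)   # nm
    return rng.standard_normal((spec.n_snapshots, n_atoms, 3)) * std[None, :, None]
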