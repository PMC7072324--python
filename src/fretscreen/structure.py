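"""Structural models: PDB ingestion, donor/acceptor anchors, SASA, RMSD.

Reads docked complex models in PDB format, locates the FRET donor (the
centroid of the tryptophan indole ring) and the acceptor anchor (the 5'
end of the RNA strand, where the dye is attached), measures the
donor-acceptor distance D_DA, computes solvent-accessible surface area with
the Shrake-Rupley point-sampling algorithm, and superposes/compares models
(Kabsch least-squares fit, coordinate RMSD).

Coordinates are ingested in Angstrom (the PDB convention) and exposed in nm
where the quantity is a donor-acceptor distance or an RMSD; SASA stays in
Angstrom^2, the unit the field reports it in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "SitePair",
    "BONDI_RADII",
    "read_pdb",
    "write_pdb",
    "trp_ring_centroid",
    "rna_5prime_anchor",
    "dda_distance",
    "shrake_rupley_sasa",
    "residue_sasa",
    "kabsch_superpose",
    "rmsd",
    "parse_selection",
]

ANGSTROM_PER_NM = 10.0

#: Bondi van der Waals radii (Angstrom) for common elements; unknown
#: elements fall back to 1.7 A with a warning.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "SE": 1.90, "MG": 1.73, "NA": 2.27, "K": 2.75,
}
DEFAULT_VDW_RADIUS = 1.70

#: heavy atoms of the tryptophan indole ring system (both rings)
INDOLE_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

#: ribo- and deoxyribonucleotide residue names accepted as RNA/DNA
NUCLEOTIDE_NAMES = {"A", "U", "G", "C", "DA", "DT", "DG", "DC", "RA", "RU", "RG", "RC"}


@dataclass(frozen=True)
class Atom:
    """One atom of a structural model (coordinates in Angstrom)."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", xyz)


@dataclass
class StructureModel:
    """An ordered collection of atoms with an optional docking score.

    Lower docking scores are better (docking-energy convention). Atom keys
    (chain, residue number, atom name) must be unique.
    """

    model_id: str
    atoms: list[Atom]
    docking_score: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a structure model needs at least one atom")
        keys = [(a.chain_id, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom name) keys in model")

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coordinates for a in self.atoms])

    def chain(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residue(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms
                if a.chain_id == chain_id and a.residue_number == residue_number]

    def translated(self, shift_angstrom: np.ndarray, model_id: str | None = None) -> "StructureModel":
        """A copy with every atom shifted by ``shift_angstrom`` (Angstrom)."""
        shift = np.asarray(shift_angstrom, dtype=float)
        atoms = [Atom(a.name, a.element, a.residue_name, a.residue_number,
                      a.chain_id, a.coordinates + shift, a.vdw_radius)
                 for a in self.atoms]
        return StructureModel(model_id or self.model_id, atoms, self.docking_score)


@dataclass(frozen=True)
class SitePair:
    """Locators for the FRET donor and acceptor within a complex model.

    ``linker_offset`` (nm) is the extra separation contributed by the dye
    and its linker beyond the geometric anchor point; it is applied by the
    screening window, not by the geometric distance itself.
    """

    donor_chain: str
    donor_residue: int
    acceptor_chain: str
    linker_offset: float = 0.1

    def __post_init__(self) -> None:
        if self.linker_offset < 0:
            raise ValueError("linker_offset must be non-negative")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _vdw_for_element(element: str) -> float:
    el = element.strip().upper()
    if el in BONDI_RADII:
        return BONDI_RADII[el]
    logger.warning("unknown element %r; using default vdW radius %.2f A",
                   element, DEFAULT_VDW_RADIUS)
    return DEFAULT_VDW_RADIUS


def read_pdb(path: str | Path, model_id: str | None = None,
             docking_score: float | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    ATOM and HETATM records are parsed via Bio.PDB; for multi-model files
    only the first MODEL is used. Disordered atoms keep the highest-occupancy
    altloc (ties broken in favour of altloc 'A'). Van der Waals radii are
    assigned from the Bondi table; unknown elements default to 1.7 A with a
    warning.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id or path.stem, str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"no atoms found in {path}")
    first = models[0]

    atoms: list[Atom] = []
    for chain in first:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    children = atom.disordered_get_list()
                    atom = max(children,
                               key=lambda a: (a.get_occupancy() or 0.0,
                                              a.get_altloc() in ("A", " ")))
                elif atom.get_altloc() not in (" ", "", "A"):
                    continue
                element = (atom.element or "").strip() or atom.get_name()[0]
                atoms.append(Atom(
                    name=atom.get_name(),
                    element=element,
                    residue_name=residue.get_resname().strip(),
                    residue_number=residue.get_id()[1],
                    chain_id=chain.get_id(),
                    coordinates=np.asarray(atom.get_coord(), dtype=float),
                    vdw_radius=_vdw_for_element(element),
                ))
    if not atoms:
        raise ValueError(f"no atoms found in {path}")
    return StructureModel(model_id or path.stem, atoms, docking_score)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as minimal ATOM records (one MODEL, TER per chain)."""
    path = Path(path)
    lines = []
    serial = 1
    prev_chain = None
    for a in model.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        x, y, z = a.coordinates
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{a.residue_name:>4s} {a.chain_id}"
            f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# donor / acceptor anchors
# ---------------------------------------------------------------------------

def trp_ring_centroid(model: StructureModel, chain: str, residue_number: int) -> np.ndarray:
    """Centroid of the tryptophan indole ring system, in nm.

    Uses the unweighted mean of the available indole heavy atoms (CG, CD1,
    CD2, NE1, CE2, CE3, CZ2, CZ3, CH2); at least 6 of the 9 must be present.
    """
    res_atoms = model.residue(chain, residue_number)
    if not res_atoms:
        raise ValueError(f"residue {chain}/{residue_number} not found")
    if res_atoms[0].residue_name != "TRP":
        raise ValueError(
            f"residue {chain}/{residue_number} is {res_atoms[0].residue_name}, not TRP")
    by_name = {a.name: a for a in res_atoms}
    ring = [by_name[n] for n in INDOLE_ATOMS if n in by_name]
    if len(ring) < 6:
        missing = [n for n in INDOLE_ATOMS if n not in by_name]
        raise ValueError(
            f"tryptophan {chain}/{residue_number} has only {len(ring)} indole "
            f"atoms; missing {missing}")
    centroid = np.mean([a.coordinates for a in ring], axis=0)
    return centroid / ANGSTROM_PER_NM


def rna_5prime_anchor(model: StructureModel, chain: str) -> np.ndarray:
    """Coordinate of the RNA 5' end (dye attachment point), in nm.

    The anchor is the P atom of the first (lowest-numbered) residue on the
    chain, falling back to O5' then C5' for 5'-OH constructs.
    """
    chain_atoms = model.chain(chain)
    if not chain_atoms:
        raise ValueError(f"chain {chain!r} not found")
    first_resnum = min(a.residue_number for a in chain_atoms)
    first_res = [a for a in chain_atoms if a.residue_number == first_resnum]
    by_name = {a.name.replace("*", "'"): a for a in first_res}
    for candidate in ("P", "O5'", "C5'"):
        if candidate in by_name:
            if candidate != "P":
                logger.info("chain %s 5' residue lacks a phosphate; using %s",
                            chain, candidate)
            return by_name[candidate].coordinates / ANGSTROM_PER_NM
    raise ValueError(
        f"chain {chain!r} first residue ({first_res[0].residue_name} {first_resnum}) "
        "has none of P/O5'/C5'; not a nucleotide chain?")


def dda_distance(model: StructureModel, sites: SitePair) -> float:
    """Geometric donor-acceptor distance D_DA in nm.

    Euclidean distance between the tryptophan indole centroid and the RNA 5'
    anchor. The dye linker offset is *not* added here; it enters through the
    screening window bounds.
    """
    donor = trp_ring_centroid(model, sites.donor_chain, sites.donor_residue)
    acceptor = rna_5prime_anchor(model, sites.acceptor_chain)
    return float(np.linalg.norm(donor - acceptor))


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the golden-spiral construction."""
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k      # golden angle increments
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(model: StructureModel, probe_radius: float = 1.4,
                       n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Shrake-Rupley point sampling: each atom's van der Waals sphere is
    expanded by the probe radius and covered with ``n_sphere_points``
    golden-spiral test points; a point is solvent-accessible iff it lies
    outside every neighbouring expanded sphere. The atom's SASA is the
    accessible fraction of its expanded sphere area 4*pi*(r_i + probe)^2.
    Neighbours are found with a KD-tree within
    max_j(r_j) + r_i + 2*probe of each atom.

    Parameters
    ----------
    model : StructureModel
        Atoms with vdW radii assigned.
    probe_radius : float
        Solvent probe radius in Angstrom (water: 1.4).
    n_sphere_points : int
        Test points per sphere (>= 92; more points, finer quadrature).
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_sphere_points < 92:
        raise ValueError("need at least 92 sphere points")

    coords = model.coordinates
    radii = np.array([a.vdw_radius for a in model.atoms])
    if np.any(radii <= 0):
        raise ValueError("all atoms need positive vdW radii for SASA")
    expanded = radii + probe_radius
    unit_sphere = _golden_spiral_points(n_sphere_points)

    tree = cKDTree(coords)
    max_radius = float(expanded.max())
    sasa = np.zeros(len(model.atoms))
    for i in range(len(model.atoms)):
        cutoff = expanded[i] + max_radius
        neighbours = [j for j in tree.query_ball_point(coords[i], cutoff) if j != i]
        points = coords[i] + expanded[i] * unit_sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_sphere_points
        sasa[i] = frac * 4.0 * math.pi * expanded[i] ** 2
    return sasa


def residue_sasa(per_atom: np.ndarray, model: StructureModel,
                 chain: str, residue_number: int) -> float:
    """Summed SASA (Angstrom^2) of one residue from a per-atom SASA array."""
    idx = [i for i, a in enumerate(model.atoms)
           if a.chain_id == chain and a.residue_number == residue_number]
    if not idx:
        raise ValueError(f"residue {chain}/{residue_number} not found")
    return float(np.sum(np.asarray(per_atom)[idx]))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def parse_selection(selection: str | None) -> tuple[str | None, int | None, int | None]:
    """Parse a 'chain' or 'chain:first-last' selection string.

    ``None`` or '' selects everything; 'B' selects chain B; 'B:10-20'
    selects residues 10..20 of chain B (inclusive).
    """
    if not selection:
        return None, None, None
    if ":" not in selection:
        return selection, None, None
    chain, rng = selection.split(":", 1)
    lo_s, _, hi_s = rng.partition("-")
    lo = int(lo_s)
    hi = int(hi_s) if hi_s else lo
    return chain, lo, hi


def _selected_indices(model: StructureModel, selection: str | None) -> list[int]:
    chain, lo, hi = parse_selection(selection)
    out = []
    for i, a in enumerate(model.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if lo is not None and not (lo <= a.residue_number <= hi):
            continue
        out.append(i)
    return out


def _matched_coordinates(a: StructureModel, b: StructureModel,
                         selection: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms matched 1:1 by (chain, residue, name)."""
    idx_a = _selected_indices(a, selection)
    key = lambda at: (at.chain_id, at.residue_number, at.name)
    lookup_b = {key(at): at for j, at in enumerate(b.atoms)}
    xa, xb = [], []
    for i in idx_a:
        at = a.atoms[i]
        k = key(at)
        if k not in lookup_b:
            raise ValueError(f"atom {k} present in {a.model_id} but not in {b.model_id}")
        xa.append(at.coordinates)
        xb.append(lookup_b[k].coordinates)
    if not xa:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return np.array(xa), np.array(xb)


def kabsch_superpose(mobile: StructureModel, reference: StructureModel,
                     selection: str | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition (Kabsch algorithm).

    Returns (rotation, translation, fitted RMSD in nm) such that
    ``rotation @ x_mobile + translation`` best matches the reference over the
    selection. The rotation is proper (determinant +1): reflections are
    never used, so mirror-related structures keep a positive residual.
    Requires >= 3 matched, non-collinear atoms.
    """
    xm, xr = _matched_coordinates(mobile, reference, selection)
    if xm.shape[0] < 3:
        raise ValueError("superposition needs at least 3 matched atoms")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    am, ar = xm - cm, xr - cr
    if np.linalg.matrix_rank(am, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")
    H = am.T @ ar
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    fitted = (R @ xm.T).T + t
    rmsd_a = math.sqrt(np.mean(np.sum((fitted - xr) ** 2, axis=1)))
    return R, t, rmsd_a / ANGSTROM_PER_NM


def rmsd(a: StructureModel, b: StructureModel, selection: str | None = None,
         fit: bool = False) -> float:
    """Coordinate RMSD between two models over a selection, in nm.

    With ``fit=False`` (default) the RMSD is computed directly in the shared
    frame — the right choice for docked poses that share the receptor frame.
    With ``fit=True`` the mobile model is first Kabsch-superposed onto the
    reference over the same selection.
    """
    if fit:
        return kabsch_superpose(a, b, selection)[2]
    xa, xb = _matched_coordinates(a, b, selection)
    value = math.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1)))
    return value / ANGSTROM_PER_NM
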