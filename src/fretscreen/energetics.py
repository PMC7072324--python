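"""MM-PBSA-style binding free-energy bookkeeping.

End-point binding free energy of a complex from per-state components:

    dG_B = G_complex - (G_receptor + G_ligand),
    G    = E_MM - T*S_MM + G_solv,
    E_MM = E_elec + E_vdw,
    G_solv = G_polar + G_nonpolar,   G_nonpolar = gamma * SASA + beta.

The polar solvation term is *ingested* from an external Poisson-Boltzmann
solver's output (finite-difference PB solving is out of scope here); this
module owns the nonpolar surface-area term, a simplified pairwise
molecular-mechanics energy, the quasi-harmonic configurational entropy, and
the component combination arithmetic. A screened-Coulomb polar surrogate is
provided for synthetic end-to-end runs only and is labelled as such.

All energies are in kJ/mol.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "EnergyComponents",
    "BindingComponents",
    "ForceFieldParams",
    "GAMMA_KJ_PER_MOL_NM2",
    "BETA_KJ_PER_MOL",
    "nonpolar_solvation",
    "mm_energy",
    "quasi_harmonic_entropy",
    "binding_free_energy",
    "combine_components",
    "round_sig",
    "read_component_table",
    "screened_coulomb_polar_surrogate",
]

# surface-tension coefficients of the nonpolar solvation model
GAMMA_KJ_PER_MOL_NM2 = 2.27   # kJ mol^-1 nm^-2
BETA_KJ_PER_MOL = 3.84        # kJ/mol

# physical constants in MD units (kJ/mol, nm, ps, amu, K);
# note 1 kJ/mol == 1 amu nm^2 ps^-2 exactly in this unit system
KB_KJ_PER_MOL_K = 0.008314462618       # Boltzmann x Avogadro
HBAR_KJ_PS_PER_MOL = 6.35077993e-2     # hbar x Avogadro, kJ ps / mol
COULOMB_KJ_NM_PER_MOL_E2 = 138.935458  # 1/(4 pi eps0), kJ nm mol^-1 e^-2


@dataclass(frozen=True)
class EnergyComponents:
    """Free-energy components of one thermodynamic state (kJ/mol)."""

    E_elec: float
    E_vdw: float
    TS: float              # entropic term T*S at the simulation temperature
    G_polar_solv: float
    G_nonpolar_solv: float
    state_label: str = "complex"

    def __post_init__(self) -> None:
        values = (self.E_elec, self.E_vdw, self.TS,
                  self.G_polar_solv, self.G_nonpolar_solv)
        if not all(math.isfinite(v) for v in values):
            raise ValueError("all energy components must be finite")
        if self.state_label not in ("complex", "receptor", "ligand"):
            raise ValueError("state_label must be complex/receptor/ligand")

    @property
    def E_MM(self) -> float:
        return self.E_elec + self.E_vdw

    @property
    def G(self) -> float:
        """G = E_MM - T*S + G_polar + G_nonpolar."""
        return self.E_MM - self.TS + self.G_polar_solv + self.G_nonpolar_solv


@dataclass(frozen=True)
class BindingComponents:
    """Binding free energy and its components (kJ/mol).

    dG_B = dG_nonpol + dE_MM + (-T dS) + dG_pol holds exactly by
    construction; ``D_DA`` is an optional donor-acceptor distance annotation
    in nm.
    """

    dG_nonpol: float
    dE_MM: float
    minus_TdS: float
    dG_pol: float
    dG_B: float
    D_DA: float | None = None
    model_id: str = ""

    def __post_init__(self) -> None:
        total = self.dG_nonpol + self.dE_MM + self.minus_TdS + self.dG_pol
        if not math.isclose(total, self.dG_B,
                            rel_tol=0.0, abs_tol=max(1e-6, 1e-9 * abs(total))):
            raise ValueError(
                f"component sum {total:g} disagrees with dG_B {self.dG_B:g}")


@dataclass(frozen=True)
class ForceFieldParams:
    """Per-atom nonbonded parameters for the simplified MM energy.

    ``charges`` in elementary charge, LJ ``sigma`` in nm and ``epsilon`` in
    kJ/mol, in atom order. ``excluded_pairs`` lists (i, j) index pairs
    (1-2 / 1-3 bonded neighbours) removed from the nonbonded sums.
    """

    charges: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    excluded_pairs: frozenset = frozenset()
    interior_dielectric: float = 2.0
    solvent_dielectric: float = 87.5

    def __post_init__(self) -> None:
        q = np.asarray(self.charges, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        e = np.asarray(self.epsilon, dtype=float)
        if not (q.shape == s.shape == e.shape) or q.ndim != 1:
            raise ValueError("charges, sigma, epsilon must be equal-length 1-D arrays")
        if np.any(e < 0):
            raise ValueError("LJ epsilon must be non-negative")
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be positive")
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "epsilon", e)
        norm = frozenset(tuple(sorted(p)) for p in self.excluded_pairs)
        object.__setattr__(self, "excluded_pairs", norm)


def nonpolar_solvation(sasa_nm2: float, gamma: float = GAMMA_KJ_PER_MOL_NM2,
                       beta: float = BETA_KJ_PER_MOL) -> float:
    """Nonpolar solvation free energy gamma*SASA + beta (kJ/mol; SASA in nm^2)."""
    if sasa_nm2 < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa_nm2 + beta


def mm_energy(coords_nm: np.ndarray, params: ForceFieldParams,
              pair_cutoff_nm: float = 1.2) -> tuple[float, float]:
    """Simplified pairwise molecular-mechanics energy (E_elec, E_vdw), kJ/mol.

    Sums Coulomb q_i q_j / (4 pi eps0 eps_int r_ij) and Lennard-Jones 12-6
    terms over all nonbonded pairs within the cutoff, with Lorentz-Berthelot
    combination rules. Pairs in ``params.excluded_pairs`` (1-2/1-3 bonded
    neighbours) are skipped. A stand-in energy for toy systems, not a full
    force-field evaluation.
    """
    x = np.asarray(coords_nm, dtype=float)
    n = x.shape[0]
    if params.charges.shape[0] != n:
        raise ValueError(
            f"parameter arrays cover {params.charges.shape[0]} atoms but the "
            f"model has {n}")
    if pair_cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")

    e_elec = 0.0
    e_vdw = 0.0
    kq = COULOMB_KJ_NM_PER_MOL_E2 / params.interior_dielectric
    for i in range(n - 1):
        d = x[i + 1:] - x[i]
        r = np.linalg.norm(d, axis=1)
        for off, rij in enumerate(r):
            j = i + 1 + off
            if rij > pair_cutoff_nm or (i, j) in params.excluded_pairs:
                continue
            if rij <= 0:
                raise ValueError(f"coincident atoms {i} and {j}")
            e_elec += kq * params.charges[i] * params.charges[j] / rij
            eps = math.sqrt(params.epsilon[i] * params.epsilon[j])
            if eps > 0:
                sig = 0.5 * (params.sigma[i] + params.sigma[j])
                sr6 = (sig / rij) ** 6
                e_vdw += 4.0 * eps * (sr6 * sr6 - sr6)
    return float(e_elec), float(e_vdw)


def quasi_harmonic_entropy(ensemble_nm: np.ndarray, masses_amu: np.ndarray,
                           temperature_K: float,
                           eigenvalue_floor: float = 1e-12) -> float:
    """Quasi-harmonic configurational entropy term T*S, in kJ/mol.

    The mass-weighted covariance of the coordinate fluctuations is
    diagonalised; each eigenvalue lambda_i (amu nm^2) defines an effective
    harmonic mode of frequency omega_i = sqrt(k_B T / lambda_i), and the
    entropy is the quantum harmonic-oscillator sum

        S = k_B sum_i [ x_i/(e^{x_i}-1) - ln(1-e^{-x_i}) ],
        x_i = hbar omega_i / (k_B T).

    Rigid-body motion must have been removed by superposing the snapshots
    onto a common reference beforehand. Eigenvalues below
    ``eigenvalue_floor`` (amu nm^2; numerically empty modes) are dropped so
    they cannot produce divergent log terms.

    Parameters
    ----------
    ensemble_nm : ndarray, shape (n_snapshots, n_atoms, 3)
        Coordinate snapshots in nm. A 2-D (n_snapshots, n_dof) array of
        scalar modes is also accepted, with one mass per dof.
    masses_amu : ndarray, shape (n_atoms,)
        Atomic masses in amu.
    temperature_K : float
        Absolute temperature in K.
    """
    x = np.asarray(ensemble_nm, dtype=float)
    if x.ndim == 2:
        x = x.reshape(x.shape[0], x.shape[1], 1)
    if x.ndim != 3 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need an (n_snapshots >= 2, n_atoms >= 1, 3) ensemble")
    m = np.asarray(masses_amu, dtype=float)
    if m.shape != (x.shape[1],) or np.any(m <= 0):
        raise ValueError("need one positive mass per atom")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")

    n_snap, n_atoms, n_dim = x.shape
    flat = x.reshape(n_snap, n_atoms * n_dim)
    weights = np.sqrt(np.repeat(m, n_dim))
    fluct = (flat - flat.mean(axis=0)) * weights
    cov = fluct.T @ fluct / n_snap                  # amu nm^2
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = eigvals[eigvals > eigenvalue_floor]
    if eigvals.size == 0:
        return 0.0

    kbt = KB_KJ_PER_MOL_K * temperature_K           # kJ/mol == amu nm^2 / ps^2
    omega = np.sqrt(kbt / eigvals)                  # 1/ps
    xq = HBAR_KJ_PS_PER_MOL * omega / kbt
    s_over_kb = xq / np.expm1(xq) - np.log1p(-np.exp(-xq))
    entropy = KB_KJ_PER_MOL_K * float(np.sum(s_over_kb))
    return temperature_K * entropy


def binding_free_energy(complex_state: EnergyComponents,
                        receptor: EnergyComponents,
                        ligand: EnergyComponents,
                        model_id: str = "", D_DA: float | None = None
                        ) -> BindingComponents:
    """Componentwise binding free energy dG = G_complex - G_receptor - G_ligand."""
    def delta(f):
        return f(complex_state) - f(receptor) - f(ligand)

    dG_nonpol = delta(lambda s: s.G_nonpolar_solv)
    dE_MM = delta(lambda s: s.E_MM)
    minus_TdS = -delta(lambda s: s.TS)
    dG_pol = delta(lambda s: s.G_polar_solv)
    return BindingComponents(
        dG_nonpol=dG_nonpol, dE_MM=dE_MM, minus_TdS=minus_TdS, dG_pol=dG_pol,
        dG_B=dG_nonpol + dE_MM + minus_TdS + dG_pol,
        D_DA=D_DA, model_id=model_id,
    )


def combine_components(dG_nonpol: float, dE_MM: float, minus_TdS: float,
                       dG_pol: float) -> tuple[float, float]:
    """Sum the four binding components.

    Returns the exact sum and a 3-significant-figure rounding of it — the
    precision at which MM-PBSA component tables are usually reported.
    """
    for v in (dG_nonpol, dE_MM, minus_TdS, dG_pol):
        if not math.isfinite(v):
            raise ValueError("components must be finite")
    total = dG_nonpol + dE_MM + minus_TdS + dG_pol
    return total, round_sig(total, 3)


def round_sig(value: float, n_digits: int) -> float:
    """Round to ``n_digits`` significant figures (0 stays 0)."""
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, n_digits - 1 - magnitude)


# ---------------------------------------------------------------------------
# component-table I/O
# ---------------------------------------------------------------------------

_STATE_HEADER = {"model_id", "label", "E_elec", "E_vdw", "TS", "G_pol", "G_nonpol"}
_DELTA_HEADER = {"model_id", "dG_nonpol", "dE_MM", "minus_TdS", "dG_pol"}


def read_component_table(path: str | Path):
    """Read an energy-component CSV ledger.

    Two layouts are recognised by header:

    * per-state: ``model_id,label,E_elec,E_vdw,TS,G_pol,G_nonpol`` →
      list of :class:`EnergyComponents`;
    * per-binding (delta): ``model_id,dG_nonpol,dE_MM,minus_TdS,dG_pol``
      with optional ``dG_B`` and ``D_DA`` columns → list of
      :class:`BindingComponents`. When ``dG_B`` is present it is checked
      against the component sum; a mismatch above 0.5% is an error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        fields = set(reader.fieldnames)
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    if _DELTA_HEADER <= fields:
        return [_parse_delta_row(row, path, i + 2) for i, row in enumerate(rows)]
    if _STATE_HEADER <= fields:
        return [_parse_state_row(row, path, i + 2) for i, row in enumerate(rows)]
    raise ValueError(
        f"{path}: unrecognised header {sorted(fields)}; expected a per-state "
        f"or per-binding component ledger")


def _float_field(row: Mapping[str, str], key: str, path: Path, lineno: int) -> float:
    try:
        return float(row[key])
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"{path}:{lineno}: bad or missing value for {key!r}") from None


def _parse_delta_row(row: Mapping[str, str], path: Path, lineno: int) -> BindingComponents:
    dG_nonpol = _float_field(row, "dG_nonpol", path, lineno)
    dE_MM = _float_field(row, "dE_MM", path, lineno)
    minus_TdS = _float_field(row, "minus_TdS", path, lineno)
    dG_pol = _float_field(row, "dG_pol", path, lineno)
    total = dG_nonpol + dE_MM + minus_TdS + dG_pol
    if row.get("dG_B") not in (None, ""):
        stated = _float_field(row, "dG_B", path, lineno)
        scale = max(abs(stated), abs(total), 1.0)
        if abs(stated - total) > 0.005 * scale:
            raise ValueError(
                f"{path}:{lineno}: dG_B {stated:g} inconsistent with component "
                f"sum {total:g} (>0.5%)")
    dda = row.get("D_DA")
    return BindingComponents(
        dG_nonpol=dG_nonpol, dE_MM=dE_MM, minus_TdS=minus_TdS, dG_pol=dG_pol,
        dG_B=total, D_DA=float(dda) if dda not in (None, "") else None,
        model_id=row.get("model_id", ""),
    )


def _parse_state_row(row: Mapping[str, str], path: Path, lineno: int) -> EnergyComponents:
    return EnergyComponents(
        E_elec=_float_field(row, "E_elec", path, lineno),
        E_vdw=_float_field(row, "E_vdw", path, lineno),
        TS=_float_field(row, "TS", path, lineno),
        G_polar_solv=_float_field(row, "G_pol", path, lineno),
        G_nonpolar_solv=_float_field(row, "G_nonpol", path, lineno),
        state_label=row.get("label", "complex"),
    )


def screened_coulomb_polar_surrogate(coords_nm: np.ndarray, charges: np.ndarray,
                                     interior_dielectric: float = 2.0,
                                     solvent_dielectric: float = 87.5,
                                     screening_length_nm: float = 1.0) -> float:
    """SYNTHETIC polar-solvation surrogate (kJ/mol) for toy end-to-end runs.

    A generalized-Born-flavoured screened Coulomb estimate:
    -(1/eps_int - 1/eps_solv) * [ sum_i kq q_i^2 / (2 l) +
    sum_pairs kq q_i q_j exp(-r/l) / r ]. It is *not* a Poisson-Boltzmann
    solution and is only used to give synthetic pipelines a
    physically-shaped polar term; real analyses ingest solver output via
    :func:`read_component_table`.
    """
    x = np.asarray(coords_nm, dtype=float)
    q = np.asarray(charges, dtype=float)
    pref = -COULOMB_KJ_NM_PER_MOL_E2 * (1.0 / interior_dielectric
                                        - 1.0 / solvent_dielectric)
    total = 0.0
    n = x.shape[0]
    for i in range(n):
        total += 0.5 * pref * q[i] ** 2 / screening_length_nm
        for j in range(i + 1, n):
            r = float(np.linalg.norm(x[i] - x[j]))
            if r > 0:
                total += pref * q[i] * q[j] * math.exp(-r / screening_length_nm) / r
    return float(total)
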