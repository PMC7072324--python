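"""Förster resonance energy transfer: efficiencies, distances, uncertainties.

Implements the three standard routes to the FRET efficiency E — donor
quenching, acceptor enhancement and donor lifetime reduction — the Förster
relation E = R0^6 / (R0^6 + R^6) and its inversion, first-order uncertainty
propagation for the derived distance, and a conservative rule for combining
distance estimates from independent methods.

All distances are carried in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ForsterPair",
    "EfficiencyEstimate",
    "DistanceEstimate",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "efficiency_donor_quench",
    "efficiency_acceptor_enhance",
    "efficiency_from_lifetimes",
    "forster_radius",
    "propagate_distance_sigma",
    "combine_distances",
]

#: prefactor of the Förster-radius formula for R0 in nm and the spectral
#: overlap integral J in M^-1 cm^-1 nm^4 (equivalently R0^6 = 8.79e-5 *
#: kappa^2 n^-4 Q_D J in Angstrom^6): R0 = 0.02108 (kappa^2 n^-4 Q_D J)^(1/6) nm
FORSTER_PREFACTOR_NM = 0.02108

METHODS = ("donor_quench", "acceptor_enhance", "lifetime")


@dataclass(frozen=True)
class ForsterPair:
    """A donor-acceptor chromophore pair characterised by its Förster radius.

    R0 (nm) is the separation at which the transfer efficiency is 0.5. The
    extinction coefficients (M^-1 cm^-1 at the excitation wavelength) are
    required only by the acceptor-enhancement method.
    """

    R0: float
    R0_sigma: float = 0.0
    donor_label: str = ""
    acceptor_label: str = ""
    epsilon_donor: float | None = None
    epsilon_acceptor: float | None = None

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.R0_sigma < 0:
            raise ValueError("R0_sigma must be non-negative")
        for eps in (self.epsilon_donor, self.epsilon_acceptor):
            if eps is not None and eps <= 0:
                raise ValueError("extinction coefficients must be positive when given")


@dataclass(frozen=True)
class EfficiencyEstimate:
    """A FRET efficiency in (0, 1) with its uncertainty and the method used."""

    E: float
    E_sigma: float = 0.0
    method: str = "donor_quench"

    def __post_init__(self) -> None:
        if not (0.0 < self.E < 1.0):
            raise ValueError(f"FRET efficiency must lie strictly in (0, 1); got {self.E:g}")
        if self.E_sigma < 0:
            raise ValueError("E_sigma must be non-negative")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")


@dataclass(frozen=True)
class DistanceEstimate:
    """A donor-acceptor distance (nm) with uncertainty and originating method."""

    R: float
    R_sigma: float = 0.0
    method: str = "donor_quench"

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("distance must be positive")
        if self.R_sigma < 0:
            raise ValueError("R_sigma must be non-negative")


def efficiency_from_distance(R: float, pair: ForsterPair) -> float:
    """E = R0^6 / (R0^6 + R^6) for a donor-acceptor separation R (nm)."""
    if R <= 0:
        raise ValueError("distance must be positive")
    r6 = (R / pair.R0) ** 6
    return 1.0 / (1.0 + r6)


def distance_from_efficiency(est: EfficiencyEstimate, pair: ForsterPair) -> DistanceEstimate:
    """Invert the Förster relation: R = R0 ((1 - E) / E)^(1/6).

    The uncertainty combines the R0 uncertainty of the pair and the
    efficiency uncertainty via first-order propagation
    (:func:`propagate_distance_sigma`).
    """
    E = est.E
    R = pair.R0 * ((1.0 - E) / E) ** (1.0 / 6.0)
    sigma = propagate_distance_sigma(E, est.E_sigma, pair.R0, pair.R0_sigma)
    return DistanceEstimate(R=R, R_sigma=sigma, method=est.method)


def efficiency_donor_quench(F_D: float, F_DA: float) -> EfficiencyEstimate:
    """E = 1 - F_DA / F_D from the quenching of donor emission by the acceptor.

    F_D is the donor intensity without acceptor, F_DA with acceptor; a valid
    FRET signal requires 0 < F_DA < F_D.
    """
    if F_D <= 0:
        raise ValueError("F_D must be positive")
    if not (0 < F_DA < F_D):
        raise ValueError("donor quenching requires 0 < F_DA < F_D (no quench observed)")
    return EfficiencyEstimate(E=1.0 - F_DA / F_D, method="donor_quench")


def efficiency_acceptor_enhance(F_A: float, F_AD: float, pair: ForsterPair) -> EfficiencyEstimate:
    """E = (F_AD / F_A - 1) * (eps_A / eps_D) from acceptor emission enhancement.

    F_A is the acceptor intensity without donor, F_AD with donor; the
    extinction-coefficient ratio at the excitation wavelength corrects for
    direct acceptor excitation.
    """
    if F_A <= 0:
        raise ValueError("F_A must be positive")
    if F_AD <= F_A:
        raise ValueError("acceptor enhancement requires F_AD > F_A (no enhancement observed)")
    if pair.epsilon_acceptor is None or pair.epsilon_donor is None:
        raise ValueError("extinction coefficients must be set on the ForsterPair")
    E = (F_AD / F_A - 1.0) * (pair.epsilon_acceptor / pair.epsilon_donor)
    return EfficiencyEstimate(E=E, method="acceptor_enhance")


def efficiency_from_lifetimes(tau_DA: float, tau_D: float) -> EfficiencyEstimate:
    """E = 1 - tau_DA / tau_D from the reduction of the donor lifetime."""
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    if not (0 < tau_DA < tau_D):
        raise ValueError("lifetime method requires 0 < tau_DA < tau_D")
    return EfficiencyEstimate(E=1.0 - tau_DA / tau_D, method="lifetime")


def forster_radius(kappa2: float, refractive_index: float, Q_D: float, J: float) -> float:
    """Förster radius from photophysical parameters.

    R0 = 0.02108 * (kappa^2 * n^-4 * Q_D * J)^(1/6) nm, with the orientation
    factor kappa^2, medium refractive index n, donor quantum yield Q_D and
    spectral overlap integral J in M^-1 cm^-1 nm^4.
    """
    for name, v in (("kappa2", kappa2), ("refractive_index", refractive_index),
                    ("Q_D", Q_D), ("J", J)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if Q_D > 1:
        raise ValueError("quantum yield cannot exceed 1")
    return FORSTER_PREFACTOR_NM * (kappa2 * refractive_index ** -4 * Q_D * J) ** (1.0 / 6.0)


def propagate_distance_sigma(E: float, E_sigma: float, R0: float, R0_sigma: float) -> float:
    """First-order uncertainty of R = R0 ((1-E)/E)^(1/6).

    sigma_R^2 = (dR/dR0)^2 sigma_R0^2 + (dR/dE)^2 sigma_E^2 with
    dR/dR0 = R/R0 and dR/dE = -R / (6 E (1 - E)).
    """
    if not (0.0 < E < 1.0):
        raise ValueError("E must lie strictly in (0, 1)")
    R = R0 * ((1.0 - E) / E) ** (1.0 / 6.0)
    dR_dR0 = R / R0
    dR_dE = R / (6.0 * E * (1.0 - E))
    return math.sqrt((dR_dR0 * R0_sigma) ** 2 + (dR_dE * E_sigma) ** 2)


def combine_distances(estimates: Sequence[DistanceEstimate]) -> DistanceEstimate:
    """Combine distance estimates from independent methods.

    The value is the unweighted mean. The reported uncertainty is
    conservative: the larger of the root-mean-square of the individual sigmas
    and half the max-min spread, so that disagreement between methods is
    never hidden by small per-method errors.
    """
    if not estimates:
        raise ValueError("need at least one distance estimate")
    values = np.array([e.R for e in estimates])
    sigmas = np.array([e.R_sigma for e in estimates])
    mean = float(values.mean())
    rms_sigma = float(np.sqrt(np.mean(sigmas ** 2)))
    half_spread = float(values.max() - values.min()) / 2.0
    method = estimates[0].method if len(estimates) == 1 else "combined"
    return DistanceEstimate(R=mean, R_sigma=max(rms_sigma, half_spread), method=method)
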