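"""Förster resonance energy transfer: efficiency and donor-acceptor distance.

The transfer efficiency from donor lifetimes is E = 1 - <tau_DA>/<tau_D>,
where tau_D is the donor lifetime in the *unlabelled* complex (the acceptor
absent but the binder bound) and tau_DA the lifetime with the acceptor
attached.  Distance follows from the Förster relation

    E = R0^6 / (R0^6 + R^6)   <=>   R = R0 * (1/E - 1)^(1/6),

with R0 the Förster radius (distance at E = 0.5).  R0 depends on spectral
overlap, quantum yield and orientation factor and must be supplied by the
caller; no default is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FretMeasurement",
    "efficiency_from_lifetimes",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "propagate_distance_uncertainty",
    "fret_distance_report",
]


@dataclass(frozen=True)
class FretMeasurement:
    """A lifetime-based FRET distance determination."""

    tau_D: float  # ns, donor without acceptor
    tau_DA: float  # ns, donor with acceptor
    R0: float  # nm, Förster radius (user-supplied)
    E: float  # transfer efficiency
    R: float  # nm
    sigma_R: float = 0.0  # nm

    def __post_init__(self) -> None:
        if not (0 < self.tau_DA <= self.tau_D):
            raise ValueError("require 0 < tau_DA <= tau_D")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if abs(self.E - (1.0 - self.tau_DA / self.tau_D)) > 1e-12:
            raise ValueError("E inconsistent with lifetimes")


def efficiency_from_lifetimes(tau_DA: float, tau_D: float) -> float:
    """E = 1 - tau_DA / tau_D, in [0, 1)."""
    if tau_D <= 0 or tau_DA <= 0:
        raise ValueError("lifetimes must be positive")
    if tau_DA > tau_D:
        raise ValueError(
            "tau_DA > tau_D: no transfer is resolvable (check trace assignment)"
        )
    return 1.0 - tau_DA / tau_D


def efficiency_from_distance(R: float, R0: float) -> float:
    """Förster relation E = R0^6 / (R0^6 + R^6)."""
    if R <= 0 or R0 <= 0:
        raise ValueError("distances must be positive")
    x = (R / R0) ** 6
    return 1.0 / (1.0 + x)


def distance_from_efficiency(E: float, R0: float) -> float:
    """Inverse Förster relation R = R0 (1/E - 1)^(1/6)."""
    if not (0.0 < E < 1.0):
        raise ValueError("E must lie strictly between 0 and 1")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def propagate_distance_uncertainty(
    tau_DA: float,
    sigma_DA: float,
    tau_D: float,
    sigma_D: float,
    R0: float,
    sigma_R0: float = 0.0,
) -> float:
    """First-order (delta-method) uncertainty of R from lifetime and R0 errors.

    Propagates through E = 1 - tau_DA/tau_D and R = R0 (1/E - 1)^(1/6):

        dR/dE  = -R / (6 E (1-E)),     dR/dR0 = R / R0,
        dE/dtau_DA = -1/tau_D,         dE/dtau_D = tau_DA / tau_D^2.
    """
    if min(sigma_DA, sigma_D, sigma_R0) < 0:
        raise ValueError("uncertainties must be non-negative")
    E = efficiency_from_lifetimes(tau_DA, tau_D)
    if E == 0.0:
        raise ValueError("E = 0: distance (and its uncertainty) undefined")
    R = distance_from_efficiency(E, R0)
    var_E = (sigma_DA / tau_D) ** 2 + (tau_DA / tau_D**2 * sigma_D) ** 2
    dR_dE = -R / (6.0 * E * (1.0 - E))
    var_R = dR_dE**2 * var_E + (R / R0) ** 2 * sigma_R0**2
    return float(np.sqrt(var_R))


def fret_distance_report(
    tau_DA: float,
    tau_D: float,
    R0: float,
    sigma_DA: float = 0.0,
    sigma_D: float = 0.0,
    sigma_R0: float = 0.0,
) -> FretMeasurement:
    """Full lifetime -> efficiency -> distance chain with error propagation."""
    E = efficiency_from_lifetimes(tau_DA, tau_D)
    R = distance_from_efficiency(E, R0)
    sigma_R = propagate_distance_uncertainty(tau_DA, sigma_DA, tau_D, sigma_D, R0, sigma_R0)
    return FretMeasurement(tau_D=tau_D, tau_DA=tau_DA, R0=R0, E=E, R=R, sigma_R=sigma_R)
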