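"""Steady-state fluorescence quenching (Stern-Volmer) analysis.

A titration of a single-Trp protein with increasing quencher is summarised by
the ratio F0/F of emission intensities without/with quencher.  Two models are
fitted:

* the linear Stern-Volmer relation  F0/F = 1 + K_SV [Q], whose slope K_SV is
  the Stern-Volmer constant (an affinity estimate under static quenching);
* a quadratic 1:1-binding expression for the quenched fraction (F0-F)/F0 that
  accounts for fluorophore depletion at comparable fluorophore and quencher
  concentrations.

The bimolecular quenching constant k_q = K_SV / tau_q (tau_q the unquenched
fluorophore lifetime) discriminates static from dynamic (collisional)
quenching: values far above the diffusion-controlled limit (~1e10 M^-1 s^-1),
together with quencher-independent lifetimes, indicate ground-state complex
formation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "Mechanism",
    "FitFailureError",
    "correct_inner_filter",
    "sv_linear_predict",
    "fit_sv_linear",
    "sv_quadratic_predict",
    "fit_sv_quadratic",
    "classify_quenching",
    "read_titration_csv",
    "quench_fit_report",
]

#: Diffusion-controlled quenching rate in water, M^-1 s^-1 (order of magnitude).
DIFFUSION_LIMIT = 1e10

#: Factor by which k_q must exceed the diffusion limit to call quenching static.
STATIC_KQ_FACTOR = 10.0

#: Maximum relative lifetime change compatible with static quenching.
STATIC_TAU_TOLERANCE = 0.02


class Mechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


class FitFailureError(RuntimeError):
    """Raised when a quenching model cannot be fitted to the data."""


@dataclass
class TitrationSeries:
    """One quenching titration at a fixed fluorophore concentration.

    Parameters
    ----------
    fluorophore_conc : float
        Total fluorophore concentration in molar.
    quencher_concs : array-like
        Quencher concentrations in molar, strictly increasing, starting at 0.
    intensities : array-like
        Emission intensities (a.u.) at the analysis wavelength; the first
        entry (zero quencher) is F0.
    absorbance_ex, absorbance_em : array-like, optional
        Per-point absorbances at excitation/emission wavelengths for the
        inner-filter correction.
    emission_wavelength : float
        Analysis wavelength in nm (metadata only).
    """

    fluorophore_conc: float
    quencher_concs: np.ndarray
    intensities: np.ndarray
    absorbance_ex: np.ndarray | None = None
    absorbance_em: np.ndarray | None = None
    emission_wavelength: float = 346.0

    def __post_init__(self) -> None:
        self.quencher_concs = np.asarray(self.quencher_concs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        q, f = self.quencher_concs, self.intensities
        if q.ndim != 1 or f.shape != q.shape:
            raise ValueError("quencher_concs and intensities must be 1-D and equal length")
        if q[0] != 0.0:
            raise ValueError("first quencher concentration must be exactly 0 (defines F0)")
        if np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("intensities must be strictly positive")
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if a.shape != q.shape:
                    raise ValueError(f"{name} must match the titration length")
                if np.any(a < 0):
                    raise ValueError(f"{name} must be non-negative")
                setattr(self, name, a)

    @property
    def corrected_intensities(self) -> np.ndarray:
        """Intensities after inner-filter correction (identity if no absorbances)."""
        if self.absorbance_ex is None and self.absorbance_em is None:
            return self.intensities
        a_ex = self.absorbance_ex if self.absorbance_ex is not None else 0.0
        a_em = self.absorbance_em if self.absorbance_em is not None else 0.0
        return correct_inner_filter(self.intensities, a_ex, a_em)

    @property
    def f0(self) -> float:
        return float(self.corrected_intensities[0])

    @property
    def f0_over_f(self) -> np.ndarray:
        return self.f0 / self.corrected_intensities


@dataclass
class QuenchFit:
    """Result of a Stern-Volmer fit."""

    model: str  # "linear" | "quadratic"
    K_SV: float  # M^-1
    K_SV_stderr: float  # M^-1
    k_q: float | None = None  # M^-1 s^-1, only when a lifetime was supplied
    mechanism: Mechanism | None = None
    residual_norm: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.K_SV <= 0:
            raise FitFailureError(
                f"non-positive Stern-Volmer constant ({self.K_SV:.3g} M^-1): "
                "F0/F does not increase with quencher"
            )


def correct_inner_filter(intensity, a_ex, a_em):
    """Half-path inner-filter correction: F_corr = F * 10**((A_ex + A_em)/2).

    Identity when both absorbances are zero.  Accepts scalars or arrays.
    """
    intensity = np.asarray(intensity, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensity must be positive")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    out = intensity * 10.0 ** ((a_ex + a_em) / 2.0)
    return out if out.ndim else float(out)


def sv_linear_predict(K_SV: float, q) -> float | np.ndarray:
    """Linear Stern-Volmer ratio F0/F = 1 + K_SV [Q]."""
    if K_SV <= 0:
        raise ValueError("K_SV must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("quencher concentration must be non-negative")
    out = 1.0 + K_SV * q
    return out if out.ndim else float(out)


def sv_quadratic_predict(K_SV: float, hsa0: float, q0) -> float | np.ndarray:
    """Quenched fraction (F0-F)/F0 for 1:1 binding with fluorophore depletion.

    (1/(2 P0)) * [(1/K + P0 + Q0) - sqrt((1/K + P0 + Q0)^2 - 4 P0 Q0)]

    with P0 the total fluorophore and Q0 the total quencher concentration
    (the free-quencher approximation [Q]0 = [Q]free is retained).  The value
    is the bound fluorophore fraction, in [0, 1).
    """
    if K_SV <= 0 or hsa0 <= 0:
        raise ValueError("K_SV and fluorophore concentration must be positive")
    q0 = np.asarray(q0, dtype=float)
    if np.any(q0 < 0):
        raise ValueError("quencher concentration must be non-negative")
    s = 1.0 / K_SV + hsa0 + q0
    disc = s * s - 4.0 * hsa0 * q0
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in quadratic binding model")
    out = (s - np.sqrt(disc)) / (2.0 * hsa0)
    return out if out.ndim else float(out)


def fit_sv_linear(series: TitrationSeries, tau_q: float | None = None) -> QuenchFit:
    """Least-squares fit of F0/F = 1 + K_SV [Q].

    F0 is the measured zero-quencher intensity (a datum, not a parameter),
    so the intercept is fixed at 1 and only the slope is estimated
    (through-origin regression of F0/F - 1 on [Q]).

    Parameters
    ----------
    series : TitrationSeries
        Must contain at least 3 nonzero-quencher points.
    tau_q : float, optional
        Unquenched fluorophore lifetime in ns; when given, the bimolecular
        quenching constant k_q = K_SV / tau_q (s^-1 scale) is reported.
    """
    q = series.quencher_concs[1:]
    y = series.f0_over_f[1:] - 1.0
    if q.size < 3:
        raise ValueError("need at least 3 nonzero-quencher points")
    sxx = float(np.dot(q, q))
    k = float(np.dot(q, y)) / sxx
    resid = y - k * q
    dof = max(q.size - 1, 1)
    stderr = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    k_q = k / (tau_q * 1e-9) if tau_q is not None else None
    return QuenchFit(
        model="linear",
        K_SV=k,
        K_SV_stderr=stderr,
        k_q=k_q,
        residual_norm=float(np.linalg.norm(resid)),
        n_points=q.size,
    )


def fit_sv_quadratic(series: TitrationSeries) -> QuenchFit:
    """Nonlinear least-squares fit of the quadratic binding model to (F0-F)/F0."""
    from scipy.optimize import curve_fit

    q = series.quencher_concs[1:]
    if q.size < 4:
        raise ValueError("need at least 4 nonzero-quencher points")
    f = series.corrected_intensities[1:]
    y = (series.f0 - f) / series.f0
    hsa0 = series.fluorophore_conc

    def model(qq, ksv):
        return sv_quadratic_predict(ksv, hsa0, qq)

    # initial guess from the linear model; bounded restarts over decades
    try:
        p0 = fit_sv_linear(series).K_SV
    except FitFailureError:
        p0 = 1e4
    last_err: Exception | None = None
    for start in (p0, p0 * 10, p0 / 10, 1e3, 1e6):
        try:
            popt, pcov = curve_fit(
                model, q, y, p0=[start], bounds=(1e-12, np.inf), maxfev=10000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            resid = y - model(q, popt[0])
            return QuenchFit(
                model="quadratic",
                K_SV=float(popt[0]),
                K_SV_stderr=float(np.sqrt(pcov[0, 0])),
                residual_norm=float(np.linalg.norm(resid)),
                n_points=q.size,
            )
        except (RuntimeError, FitFailureError) as err:  # non-convergence
            last_err = err
    raise FitFailureError(f"quadratic Stern-Volmer fit did not converge: {last_err}")


def classify_quenching(
    K_SV: float,
    tau_free: float,
    tau_bound_series: Sequence[float],
    diffusion_limit: float = DIFFUSION_LIMIT,
) -> tuple[Mechanism, float]:
    """Classify the quenching mechanism from k_q and lifetime behaviour.

    Static quenching: apparent k_q = K_SV/tau_free far above the diffusion
    limit (>= 10x) while lifetimes stay constant (<= 2% deviation) — the
    ground-state complex is dark, so only the steady-state intensity drops.
    Dynamic quenching: k_q at or below the diffusion limit with lifetimes
    decreasing alongside F0/F.  Conflicting evidence -> indeterminate.

    Parameters
    ----------
    K_SV : float
        Stern-Volmer constant, M^-1.
    tau_free : float
        Lifetime without quencher, ns.
    tau_bound_series : sequence of float
        Lifetimes at increasing quencher concentrations, ns.

    Returns
    -------
    (mechanism, k_q) with k_q in M^-1 s^-1.
    """
    taus = np.asarray(tau_bound_series, dtype=float)
    if taus.size == 0:
        raise ValueError("lifetime series must be non-empty")
    if tau_free <= 0 or np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    k_q = K_SV / (tau_free * 1e-9)
    max_dev = float(np.max(np.abs(taus - tau_free)) / tau_free)
    if k_q >= STATIC_KQ_FACTOR * diffusion_limit and max_dev <= STATIC_TAU_TOLERANCE:
        return Mechanism.STATIC, k_q
    if k_q <= diffusion_limit and max_dev > STATIC_TAU_TOLERANCE:
        return Mechanism.DYNAMIC, k_q
    return Mechanism.INDETERMINATE, k_q


# ---------------------------------------------------------------------------
# I/O

def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read a titration table.

    Format: optional ``# key: value`` header lines (fluorophore_conc, unit,
    emission_wavelength), then CSV with columns ``quencher_conc, intensity``
    and optional ``A_ex, A_em``.  ``unit`` may be ``M`` (default) or ``uM``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    scale = {"M": 1.0, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}[meta.get("unit", "M")]
    return TitrationSeries(
        fluorophore_conc=float(meta.get("fluorophore_conc", "nan")) * scale,
        quencher_concs=df["quencher_conc"].to_numpy() * scale,
        intensities=df["intensity"].to_numpy(),
        absorbance_ex=df["A_ex"].to_numpy() if "A_ex" in df else None,
        absorbance_em=df["A_em"].to_numpy() if "A_em" in df else None,
        emission_wavelength=float(meta.get("emission_wavelength", 346.0)),
    )


def quench_fit_report(fit: QuenchFit) -> str:
    """JSON report of a quenching fit."""
    return json.dumps(
        {
            "model": fit.model,
            "K_SV_per_M": fit.K_SV,
            "K_SV_stderr_per_M": fit.K_SV_stderr,
            "k_q_per_M_per_s": fit.k_q,
            "mechanism": fit.mechanism.value if fit.mechanism else None,
            "residual_norm": fit.residual_norm,
            "n_points": fit.n_points,
        },
        indent=2,
    )
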