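"""Dynamic force spectroscopy: unbinding events, force histograms, Bell-Evans.

AFM force-distance retract curves are scanned for jump-off discontinuities;
the stretch preceding a jump is fitted with an extended freely-jointed-chain
(eFJC) tether model, and an event is called *specific* when the rupture
length falls inside the PEG-tether window and the tether fit is good.  Per
loading rate r the modal rupture force F* is read from a Gaussian fit to the
main mode of the force histogram.  The Bell-Evans model

    F* = (kB T / x_beta) * ln( r x_beta / (k_off kB T) )

is linear in ln r; its slope gives the barrier width x_beta and its zero-force
intercept the thermal dissociation rate k_off.  The association rate is
estimated with an effective-volume heuristic (half-sphere of radius r_eff
explored during the dwell time), giving K_A = k_on / k_off.

Unit conventions: forces pN, loading rates nN/s, lengths nm, rates s^-1,
temperatures K.  All conversions to SI happen inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

__all__ = [
    "KB",
    "ForceCurve",
    "UnbindingEvent",
    "LoadingRatePoint",
    "BellEvansFit",
    "TetherConfig",
    "BlockingResult",
    "InsufficientDataError",
    "FitFailureError",
    "detect_unbinding_events",
    "force_histogram",
    "bell_evans_predict",
    "bell_evans_density",
    "fit_bell_evans",
    "estimate_kon",
    "affinity",
    "blocking_specificity",
    "efjc_extension",
    "efjc_force",
    "read_force_curve",
    "read_manifest",
]

KB = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol


class InsufficientDataError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass
class ForceCurve:
    """One AFM retract curve (piezo position vs cantilever deflection)."""

    z: np.ndarray  # nm, strictly monotone retract positions
    deflection: np.ndarray  # nm (negative while the tether pulls the tip down)
    k_eff: float  # N/m, effective cantilever spring constant
    velocity: float  # nm/s pulling velocity
    k_syst: float | None = None  # N/m, system spring constant for loading rate

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.shape != self.deflection.shape or self.z.ndim != 1:
            raise ValueError("z and deflection must be 1-D and equal length")
        d = np.diff(self.z)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("z must be strictly monotone")
        if np.all(d < 0):  # store retraction as increasing tip-substrate distance
            self.z = self.z[::-1]
            self.deflection = self.deflection[::-1]
        if self.k_eff <= 0:
            raise ValueError("k_eff must be positive")

    @property
    def loading_rate(self) -> float:
        """r = k_syst * v in nN/s (k_eff used if k_syst not given)."""
        k = self.k_syst if self.k_syst is not None else self.k_eff
        return k * self.velocity  # N/m * nm/s = nN/s


@dataclass
class UnbindingEvent:
    force: float  # pN
    rupture_length: float  # nm
    loading_rate: float  # nN/s
    specific: bool
    tether_fit_r2: float

    def __post_init__(self) -> None:
        if self.force <= 0:
            raise ValueError("force must be positive")
        if self.rupture_length <= 0:
            raise ValueError("rupture length must be positive")


@dataclass
class LoadingRatePoint:
    r: float  # nN/s
    F_star: float  # pN, modal unbinding force
    F_star_stderr: float  # pN
    n_events: int

    def __post_init__(self) -> None:
        if self.r <= 0 or self.F_star <= 0:
            raise ValueError("loading rate and modal force must be positive")


@dataclass
class BellEvansFit:
    k_off: float  # s^-1
    x_beta: float  # nm
    k_off_stderr: float
    x_beta_stderr: float
    temperature: float  # K
    slope: float  # pN per ln(nN/s) unit-free log
    intercept: float  # pN at r = 1 N/s (internal SI log scale)


@dataclass
class TetherConfig:
    """Selection parameters for specific unbinding events.

    The default rupture-length window 10-40 nm brackets the contour length of
    a 3.4 kDa PEG linker (~27 nm) plus the protein contribution.
    """

    window: tuple[float, float] = (10.0, 40.0)  # nm
    r2_threshold: float = 0.9
    kuhn_length: float = 0.7  # nm, PEG Kuhn length
    segment_elasticity: float = 10.0  # nN, eFJC stretch modulus
    min_jump: float = 0.15  # nm, minimum deflection jump to call a rupture
    noise_floor: float | None = None  # nm; estimated from the curve tail if None


class BlockingResult(NamedTuple):
    fraction_before: float
    fraction_after: float
    reduction_factor: float  # nan when undefined (no events after blocking)


# ---------------------------------------------------------------------------
# Tether model (extended freely jointed chain)

def efjc_extension(force_pN, contour_nm: float, kuhn_nm: float,
                   elasticity_nN: float = 10.0, T: float = 298.0):
    """eFJC extension x(F) = Lc [coth(b F/kBT) - kBT/(b F)] (1 + F/Ks)."""
    f = np.asarray(force_pN, dtype=float)
    kbt = KB * T * 1e21  # pN*nm
    beta = np.clip(f * kuhn_nm / kbt, 1e-12, None)
    langevin = 1.0 / np.tanh(beta) - 1.0 / beta
    return contour_nm * langevin * (1.0 + f / (elasticity_nN * 1e3))


def efjc_force(extension_nm, contour_nm: float, kuhn_nm: float,
               elasticity_nN: float = 10.0, T: float = 298.0):
    """Numerical inverse of :func:`efjc_extension` (force in pN per point)."""
    x = np.atleast_1d(np.asarray(extension_nm, dtype=float))
    out = np.zeros_like(x)
    f_hi = 2e4  # pN upper bracket
    for i, xi in enumerate(x):
        if xi <= 0:
            out[i] = 0.0
            continue

        def g(f, xi=xi):
            return efjc_extension(f, contour_nm, kuhn_nm, elasticity_nN, T) - xi

        if g(f_hi) < 0:  # beyond the bracket: extension past hard stretch limit
            out[i] = f_hi
        else:
            out[i] = brentq(g, 1e-9, f_hi, xtol=1e-6)
    return out if np.ndim(extension_nm) else float(out[0])


# ---------------------------------------------------------------------------
# Event detection

def detect_unbinding_events(
    curve: ForceCurve, config: TetherConfig | None = None
) -> list[UnbindingEvent]:
    """Locate jump-off ruptures on a retract curve and classify specificity.

    A rupture is a sudden positive jump of the deflection back towards the
    baseline from a pulled (negative-deflection) state.  The stretch between
    tether engagement and the jump is fitted with the eFJC model; the event is
    specific iff its rupture length lies in ``config.window`` and the tether
    fit reaches ``config.r2_threshold``.  Unbinding force is the deflection
    magnitude at the jump times k_eff.
    """
    cfg = config or TetherConfig()
    z, d = curve.z, curve.deflection
    if z.size < 4:
        raise ValueError("curve too short: no retract segment")

    noise = cfg.noise_floor
    if noise is None:
        tail = d[-max(z.size // 10, 5):]
        noise = max(float(np.std(tail)), 1e-3)
    pulled = -3.0 * noise

    jumps = np.flatnonzero(
        (np.diff(d) >= max(cfg.min_jump, 5.0 * noise)) & (d[:-1] <= pulled)
    )
    events: list[UnbindingEvent] = []
    for i in jumps:
        # walk back to where the tether engaged (deflection left the baseline)
        j = i
        while j > 0 and d[j - 1] <= pulled:
            j -= 1
        rupture_len = float(z[i] - z[j])
        force_pN = float(-d[i] * curve.k_eff * 1e3)  # nm * N/m = nN -> pN
        if force_pN <= 0 or rupture_len <= 0:
            continue
        r2 = _tether_r2(z[j : i + 1] - z[j], -d[j : i + 1] * curve.k_eff * 1e3, cfg)
        specific = (
            cfg.window[0] <= rupture_len <= cfg.window[1] and r2 >= cfg.r2_threshold
        )
        events.append(
            UnbindingEvent(
                force=force_pN,
                rupture_length=rupture_len,
                loading_rate=curve.loading_rate,
                specific=specific,
                tether_fit_r2=r2,
            )
        )
    return events


def _tether_r2(ext: np.ndarray, force_pN: np.ndarray, cfg: TetherConfig) -> float:
    """R^2 of an eFJC fit (free contour length) to the pre-rupture stretch."""
    mask = force_pN > 0
    ext, force_pN = ext[mask], force_pN[mask]
    if ext.size < 5 or np.ptp(force_pN) <= 0:
        return 0.0

    def model(x, lc):
        return efjc_force(x, lc, cfg.kuhn_length, cfg.segment_elasticity)

    try:
        popt, _ = curve_fit(
            model, ext, force_pN, p0=[max(ext.max() * 1.1, 1.0)],
            bounds=(ext.max() * 1.001, 1e4), maxfev=200,
        )
    except (RuntimeError, ValueError):
        return 0.0
    resid = force_pN - model(ext, *popt)
    ss_tot = float(np.sum((force_pN - force_pN.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


# ---------------------------------------------------------------------------
# Force histograms and the Bell-Evans model

def force_histogram(
    events: Sequence[UnbindingEvent] | Sequence[float],
    loading_rate: float | None = None,
    specific_only: bool = True,
    peak_fraction_low: float = 0.8,
    peak_fraction_high: float = 0.5,
    extend_bins: int = 1,
) -> LoadingRatePoint:
    """Modal unbinding force from a Gaussian fit to the main histogram mode.

    Accepts either :class:`UnbindingEvent` objects or bare forces in pN.
    Bins are Freedman-Diaconis; the Gaussian is fitted to the tallest mode.
    The fit region runs from where counts drop below ``peak_fraction_low`` of
    the peak on the low-force side to below ``peak_fraction_high`` on the
    high-force side, extended by ``extend_bins`` bins each way.  The region
    is asymmetric by default because the rupture-force density carries its
    heavy tail on the low-force side: a symmetric half-maximum region drags
    the Gaussian centre below the true mode.
    """
    if len(events) > 0 and isinstance(events[0], UnbindingEvent):
        evs = [e for e in events if e.specific] if specific_only else list(events)
        forces = np.array([e.force for e in evs], dtype=float)
        if loading_rate is None and evs:
            loading_rate = evs[0].loading_rate
    else:
        forces = np.asarray(events, dtype=float)
    if forces.size < 5:
        raise InsufficientDataError(
            f"only {forces.size} events: need at least 5 to build a histogram"
        )
    if loading_rate is None:
        raise ValueError("loading_rate required when passing bare forces")

    counts, edges = np.histogram(forces, bins="fd")
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    lo = peak
    while lo > 0 and counts[lo - 1] >= counts[peak] * peak_fraction_low:
        lo -= 1
    hi = peak
    while hi < counts.size - 1 and counts[hi + 1] >= counts[peak] * peak_fraction_high:
        hi += 1
    lo = max(lo - extend_bins, 0)
    hi = min(hi + extend_bins, counts.size - 1)
    x, y = centers[lo : hi + 1], counts[lo : hi + 1]

    def gauss(f, amp, mu, sig):
        return amp * np.exp(-0.5 * ((f - mu) / sig) ** 2)

    width0 = max((x[-1] - x[0]) / 2.0, (edges[1] - edges[0]))
    try:
        popt, pcov = curve_fit(
            gauss, x, y, p0=[counts[peak], centers[peak], width0], maxfev=10000
        )
        f_star = float(popt[1])
        stderr = float(np.sqrt(pcov[1, 1]))
    except RuntimeError:  # degenerate narrow mode: fall back to the peak bin
        f_star, stderr = float(centers[peak]), float(edges[1] - edges[0])
    return LoadingRatePoint(
        r=float(loading_rate), F_star=f_star, F_star_stderr=stderr, n_events=forces.size
    )


def bell_evans_predict(k_off: float, x_beta: float, r: float, T: float = 298.0) -> float:
    """Most probable rupture force F* in pN.

    Parameters: k_off s^-1, x_beta nm, r nN/s, T K.  Returns 0 when the
    logarithm argument drops to/below 1 (near-equilibrium, low-force regime).
    """
    if min(k_off, x_beta, r, T) <= 0:
        raise ValueError("all arguments must be positive")
    kbt = KB * T  # J
    arg = (r * 1e-9) * (x_beta * 1e-9) / (k_off * kbt)
    if arg <= 1.0:
        return 0.0
    return float(kbt / (x_beta * 1e-9) * np.log(arg) * 1e12)  # N -> pN


def bell_evans_density(F_pN, k_off: float, x_beta: float, r: float, T: float = 298.0):
    """Analytic rupture-force pdf p(F) under a constant loading rate.

    p(F) = (k_off/r) e^{F x/kBT} exp(-(k_off kBT/(r x))(e^{F x/kBT} - 1)),
    with F in pN; returned density is per pN.
    """
    f = np.asarray(F_pN, dtype=float) * 1e-12  # N
    kbt = KB * T
    x = x_beta * 1e-9
    rr = r * 1e-9
    ex = np.exp(f * x / kbt)
    dens = (k_off / rr) * ex * np.exp(-(k_off * kbt / (rr * x)) * (ex - 1.0))
    return dens * 1e-12  # per N -> per pN


def bell_evans_cdf(F_pN, k_off: float, x_beta: float, r: float, T: float = 298.0):
    """Analytic rupture-force CDF (1 - survival probability)."""
    f = np.asarray(F_pN, dtype=float) * 1e-12
    kbt = KB * T
    x = x_beta * 1e-9
    rr = r * 1e-9
    return 1.0 - np.exp(-(k_off * kbt / (rr * x)) * (np.exp(f * x / kbt) - 1.0))


def fit_bell_evans(
    points: Iterable[LoadingRatePoint], T: float = 298.0, weighted: bool = False
) -> BellEvansFit:
    """Linear regression of F* on ln r; extracts x_beta and k_off.

    slope = kB T / x_beta;  the zero-force intercept gives the loading rate
    r0 = k_off kB T / x_beta, hence k_off = exp(-b/s)/s in SI.  Standard
    errors propagate from the regression covariance by the delta method.
    """
    pts = sorted(points, key=lambda p: p.r)
    if len(pts) < 3:
        raise ValueError("need at least 3 loading rates")
    r = np.array([p.r for p in pts]) * 1e-9  # N/s
    if np.log10(r.max() / r.min()) < 1.0:
        raise ValueError("loading rates must span at least one decade")
    x = np.log(r)
    y = np.array([p.F_star for p in pts]) * 1e-12  # N
    if weighted:
        w = 1.0 / np.maximum(np.array([p.F_star_stderr for p in pts]) * 1e-12, 1e-15) ** 2
        coeffs, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
    else:
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
    s, b = float(coeffs[0]), float(coeffs[1])
    if s <= 0:
        raise FitFailureError(
            "non-positive slope of F* vs ln(r): no single-barrier interpretation"
        )
    kbt = KB * T
    x_beta = kbt / s  # m
    k_off = np.exp(-b / s) / s  # s^-1  (= r0 * x_beta / kBT)

    # delta method on (s, b)
    dxb_ds = -kbt / s**2
    var_xb = dxb_ds**2 * cov[0, 0]
    dk_ds = k_off * (b / s**2 - 1.0 / s)
    dk_db = -k_off / s
    grad = np.array([dk_ds, dk_db])
    var_k = float(grad @ cov @ grad)
    return BellEvansFit(
        k_off=float(k_off),
        x_beta=float(x_beta * 1e9),
        k_off_stderr=float(np.sqrt(max(var_k, 0.0))),
        x_beta_stderr=float(np.sqrt(max(var_xb, 0.0)) * 1e9),
        temperature=T,
        slope=s * 1e12,
        intercept=b * 1e12,
    )


def estimate_kon(r_eff: float, t_interaction: float) -> float:
    """Order-of-magnitude association rate from an effective-volume argument.

    k_on ~ N_A V_eff / t_interaction with V_eff = (2/3) pi r_eff^3, the
    half-sphere the tethered partner explores during the dwell time
    t_interaction (s); r_eff in nm.  The result is a heuristic, reliable to
    order of magnitude only.
    """
    if r_eff <= 0 or t_interaction <= 0:
        raise ValueError("r_eff and t_interaction must be positive")
    v_eff_L = (2.0 / 3.0) * np.pi * (r_eff * 1e-9) ** 3 * 1e3  # m^3 -> L
    return AVOGADRO * v_eff_L / t_interaction


def affinity(k_on: float, k_off: float) -> float:
    """Equilibrium association constant K_A = k_on / k_off (M^-1)."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    return k_on / k_off


def blocking_specificity(
    n_spec_before: int, n_total_before: int, n_spec_after: int, n_total_after: int
) -> BlockingResult:
    """Specific-event fractions before/after a blocking control and their ratio."""
    if n_total_before <= 0 or n_total_after <= 0:
        raise ValueError("totals must be positive")
    if n_spec_before > n_total_before or n_spec_after > n_total_after:
        raise ValueError("specific counts cannot exceed totals")
    fb = n_spec_before / n_total_before
    fa = n_spec_after / n_total_after
    ratio = fb / fa if fa > 0 else float("nan")
    return BlockingResult(fb, fa, ratio)


# ---------------------------------------------------------------------------
# I/O

def read_force_curve(path: str | Path, k_eff: float, velocity: float,
                     k_syst: float | None = None) -> ForceCurve:
    """Read a two-column (z_nm, deflection_nm) retract curve."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     names=["z_nm", "deflection_nm"], header=None)
    return ForceCurve(
        z=df["z_nm"].to_numpy(), deflection=df["deflection_nm"].to_numpy(),
        k_eff=k_eff, velocity=velocity, k_syst=k_syst,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a curve manifest CSV: filename, k_eff, k_syst, velocity."""
    df = pd.read_csv(path)
    required = {"filename", "k_eff", "k_syst", "velocity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
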