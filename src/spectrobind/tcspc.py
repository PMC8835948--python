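"""TCSPC fluorescence-decay analysis by iterative reconvolution.

A time-correlated single-photon-counting histogram is modelled as a sum of
exponentials plus a constant background,

    I(t) = a0 + sum_i a_i exp(-t / tau_i),

convolved with the measured instrument response function (IRF, scattered
excitation light) on the same channel grid.  Fitting is weighted nonlinear
least squares with Poisson weights 1/max(counts, 1); goodness of fit is the
reduced chi-square on those weights.  The summary statistic is the
amplitude-weighted mean lifetime

    <tau> = sum_i a_i tau_i / sum_i a_i .
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayTrace",
    "MultiExpFit",
    "FitFailureError",
    "multiexp_model",
    "reconvolve",
    "fit_decay",
    "average_lifetime",
    "read_decay_table",
]

#: reduced chi-square above which a fit is flagged (not rejected)
CHI2_FLAG_THRESHOLD = 1.2


class FitFailureError(RuntimeError):
    """Raised when the decay fit fails to converge."""


@dataclass
class DecayTrace:
    """A TCSPC decay histogram with optional IRF on the same grid."""

    times: np.ndarray  # ns, uniform grid
    counts: np.ndarray  # photon counts
    irf_counts: np.ndarray | None = None
    channel_width: float | None = None  # ns

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1-D and equal length")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.irf_counts is not None:
            self.irf_counts = np.asarray(self.irf_counts, dtype=float)
            if self.irf_counts.shape != self.times.shape:
                raise ValueError("IRF must be on the same grid as the decay")
            if np.any(self.irf_counts < 0):
                raise ValueError("IRF counts must be non-negative")
        if self.channel_width is None and dt.size:
            self.channel_width = float(dt[0])


@dataclass
class MultiExpFit:
    """Multi-exponential fit result.

    ``components`` is a list of (amplitude, lifetime_ns) pairs sorted by
    lifetime ascending.  ``avg_lifetime`` is the amplitude-weighted mean.
    """

    a0: float
    components: list[tuple[float, float]]
    shift: int = 0  # IRF alignment, channels
    chi2_reduced: float = float("nan")
    avg_lifetime: float = float("nan")
    stderr_avg: float = float("nan")
    high_chi2_flag: bool = False

    def __post_init__(self) -> None:
        self.components = sorted(
            [(float(a), float(t)) for a, t in self.components], key=lambda c: c[1]
        )
        if any(t <= 0 for _, t in self.components):
            raise ValueError("all lifetimes must be positive")
        if any(a < 0 for a, _ in self.components):
            raise ValueError("all amplitudes must be non-negative")


def multiexp_model(a0: float, components: Sequence[tuple[float, float]], times) -> np.ndarray:
    """Evaluate a0 + sum_i a_i exp(-t/tau_i) on the grid."""
    times = np.asarray(times, dtype=float)
    out = np.full_like(times, float(a0))
    for a, tau in components:
        out = out + a * np.exp(-times / tau)
    return out


def reconvolve(model_curve, irf) -> np.ndarray:
    """Causal discrete convolution of a model decay with a unit-area IRF.

    The IRF is normalised to unit area so total signal is conserved; the
    output is truncated to the input grid length.
    """
    model_curve = np.asarray(model_curve, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if model_curve.shape != irf.shape:
        raise ValueError("model and IRF must share the grid")
    total = irf.sum()
    if total <= 0:
        raise ValueError("IRF must have positive total counts")
    return np.convolve(model_curve, irf / total)[: model_curve.size]


def average_lifetime(fit_or_components) -> float:
    """Amplitude-weighted mean lifetime sum(a_i tau_i)/sum(a_i)."""
    comps = (
        fit_or_components.components
        if isinstance(fit_or_components, MultiExpFit)
        else list(fit_or_components)
    )
    if not comps:
        raise ValueError("need at least one component")
    a = np.array([c[0] for c in comps], dtype=float)
    tau = np.array([c[1] for c in comps], dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("sum of amplitudes must be positive")
    return float(np.dot(a, tau) / total)


def _tau_guess(times: np.ndarray, counts: np.ndarray) -> float:
    """Crude decay-time estimate: first moment of counts past the peak."""
    peak = int(np.argmax(counts))
    t = times[peak:] - times[peak]
    c = counts[peak:]
    tot = c.sum()
    if tot <= 0:
        return max(times[-1] / 10.0, 1e-3)
    return max(float(np.dot(t, c) / tot), 1e-3)


def fit_decay(trace: DecayTrace, n_components: int = 2, shift: int = 0) -> MultiExpFit:
    """Fit an IRF-reconvolved multi-exponential to a TCSPC trace.

    Weighted nonlinear least squares with Poisson weights 1/max(counts, 1).
    With no IRF on the trace a delta IRF is assumed (tail fit from t=0).
    ``shift`` rolls the IRF by an integer number of channels before
    convolution, to absorb timing offsets between IRF and decay recording.

    Raises
    ------
    FitFailureError
        If the optimiser does not converge from any of the bounded restarts.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    times, counts = trace.times, trace.counts
    if counts.max() <= 100:
        raise ValueError("peak count too low for fitting (need > 100)")
    t_rel = times - times[0]

    if trace.irf_counts is not None:
        irf = np.roll(trace.irf_counts, shift)
    else:
        irf = np.zeros_like(counts)
        irf[0] = 1.0

    def model(_x, *params):
        a0 = params[0]
        amps = np.asarray(params[1 : 1 + n_components])
        taus = np.asarray(params[1 + n_components :])
        decay = np.zeros_like(t_rel)
        for a, tau in zip(amps, taus):
            decay = decay + a * np.exp(-t_rel / tau)
        return a0 + reconvolve(decay, irf)

    sigma = np.sqrt(np.maximum(counts, 1.0))
    tau0 = _tau_guess(times, counts)
    peak_amp = float(counts.max())
    a0_guess = float(np.median(counts[-max(counts.size // 20, 5):]))

    # lifetime starting points spread around the crude estimate
    spreads = {
        1: [(1.0,)],
        2: [(0.5, 1.3), (0.3, 1.0), (0.8, 2.0)],
        3: [(0.3, 1.0, 2.0), (0.2, 0.8, 1.5)],
    }[n_components]

    lower = [0.0] + [0.0] * n_components + [1e-4] * n_components
    upper = [np.inf] * (1 + n_components) + [1e4] * n_components

    last_err: Exception | None = None
    for spread in spreads:
        p0 = (
            [a0_guess]
            + [peak_amp / n_components] * n_components
            + [tau0 * s for s in spread]
        )
        try:
            popt, pcov = curve_fit(
                model,
                times,
                counts,
                p0=p0,
                sigma=sigma,
                absolute_sigma=True,
                bounds=(lower, upper),
                maxfev=20000,
            )
        except RuntimeError as err:
            last_err = err
            continue
        return _package_fit(popt, pcov, model, times, counts, n_components, shift)
    raise FitFailureError(f"decay fit did not converge: {last_err}")


def _package_fit(popt, pcov, model, times, counts, n_components, shift) -> MultiExpFit:
    resid = counts - model(times, *popt)
    dof = max(counts.size - popt.size, 1)
    chi2 = float(np.sum(resid**2 / np.maximum(counts, 1.0)) / dof)
    amps = popt[1 : 1 + n_components]
    taus = popt[1 + n_components :]
    comps = list(zip(amps, taus))
    avg = average_lifetime(comps)

    # delta-method stderr of <tau> from the (a_i, tau_i) covariance block
    s = amps.sum()
    grad = np.zeros(popt.size)
    for i in range(n_components):
        grad[1 + i] = (taus[i] - avg) / s  # d<tau>/da_i
        grad[1 + n_components + i] = amps[i] / s  # d<tau>/dtau_i
    var = float(grad @ pcov @ grad)
    stderr = float(np.sqrt(var)) if var > 0 else float("nan")

    return MultiExpFit(
        a0=float(popt[0]),
        components=comps,
        shift=shift,
        chi2_reduced=chi2,
        avg_lifetime=avg,
        stderr_avg=stderr,
        high_chi2_flag=chi2 > CHI2_FLAG_THRESHOLD,
    )


def read_decay_table(path: str | Path, irf_path: str | Path | None = None) -> DecayTrace:
    """Read a two-column (time_ns, counts) trace; CSV or whitespace-delimited.

    The IRF may be a third column named ``irf`` or a second file of the same
    two-column layout on an identical grid.
    """
    df = _read_two_col(path)
    irf = df["irf"].to_numpy() if "irf" in df else None
    if irf_path is not None:
        irf_df = _read_two_col(irf_path)
        if not np.allclose(irf_df.iloc[:, 0].to_numpy(), df.iloc[:, 0].to_numpy()):
            raise ValueError("IRF grid does not match decay grid")
        irf = irf_df.iloc[:, 1].to_numpy()
    return DecayTrace(
        times=df.iloc[:, 0].to_numpy(), counts=df.iloc[:, 1].to_numpy(), irf_counts=irf
    )


def _read_two_col(path: str | Path) -> pd.DataFrame:
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    sep = "," if "," in lines[0] else r"\s+"
    has_header = any(ch.isalpha() for ch in lines[0])
    names = None if has_header else ["time_ns", "counts", "irf"][: len(lines[0].split(sep if sep == "," else None))]
    return pd.read_csv(
        path, sep=sep, comment="#", header=0 if has_header else None, names=names
    )
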