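"""Growth-curve and dose-response analysis.

Growth rates are slopes of ordinary least squares on log-transformed OD600
readings (units 1/h, natural-log scale).  Relative fitness is a strain's
growth rate divided by the parental strain's rate under identical
conditions.  IC50 — the stressor concentration halving the unstressed
growth rate — is read off a dose-response series either by linear
interpolation between the bracketing concentrations or by fitting a Hill
inhibition curve  mu(c) = mu0 / (1 + (c / IC50)^h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GrowthCurve",
    "DoseResponse",
    "GrowthRateFit",
    "growth_rate",
    "relative_fitness",
    "estimate_ic50",
    "additive_expectation",
]


@dataclass
class GrowthCurve:
    """Hourly OD600 readings for one culture under one condition."""

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    stressor: str = ""
    concentration_mM: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DoseResponse:
    """Growth rate versus stressor concentration, with optional replicate SD."""

    concentrations: np.ndarray
    rates: np.ndarray
    sd: np.ndarray | None = None
    strain: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass(frozen=True)
class GrowthRateFit:
    rate: float  # 1/h
    intercept: float  # ln OD at t=0
    r_squared: float
    window: tuple  # (start index, stop index) into the curve


def _ols_log(times: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    y = np.log(od)
    slope, intercept = np.polyfit(times, y, 1)
    fitted = slope * times + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def growth_rate(curve: GrowthCurve, window: tuple | None = None) -> GrowthRateFit:
    """Exponential growth rate by linear fit to log-transformed OD.

    ``window`` is an (start, stop) index range; when omitted, the contiguous
    span of at least four points maximising R^2 is selected automatically
    (ties broken towards longer, then earlier, windows).
    """
    t, od = curve.times, curve.od
    if window is not None:
        i, j = window
        t, od = t[i:j], od[i:j]
        if len(t) < 3:
            raise ValueError("window must contain at least 3 points")
        if np.any(od <= 0):
            raise ValueError("nonpositive OD in fit window")
        slope, intercept, r2 = _ols_log(t, od)
        return GrowthRateFit(slope, intercept, r2, (i, j))
    if len(t) < 3:
        raise ValueError("growth curve needs at least 3 points")
    if np.any(od <= 0):
        raise ValueError("nonpositive OD reading; restrict the window")
    best: GrowthRateFit | None = None
    n = len(t)
    min_len = min(4, n)
    for i in range(n - min_len + 1):
        for j in range(i + min_len, n + 1):
            slope, intercept, r2 = _ols_log(t[i:j], od[i:j])
            if (
                best is None
                or r2 > best.r_squared + 1e-12
                or (
                    abs(r2 - best.r_squared) <= 1e-12
                    and (j - i) > (best.window[1] - best.window[0])
                )
            ):
                best = GrowthRateFit(slope, intercept, r2, (i, j))
    return best


def relative_fitness(rate: float, reference_rate: float) -> float:
    """Growth rate divided by the parental strain's rate."""
    if reference_rate <= 0:
        raise ValueError("reference growth rate must be > 0")
    return rate / reference_rate


def _hill(c, mu0, ic50, h):
    return mu0 / (1.0 + (c / ic50) ** h)


def estimate_ic50(dr: DoseResponse, method: str = "interpolation"):
    """Half-maximal inhibitory concentration from a dose-response series.

    ``interpolation`` (default): linear interpolation between the two
    concentrations bracketing half the unstressed rate — the dashed-line
    reading of a dose-response plot.  ``hill``: least-squares fit of the
    Hill inhibition curve; returns ``(ic50, h)``.
    """
    conc, rates = dr.concentrations, dr.rates
    if len(conc) < 2 or conc[0] != 0:
        raise ValueError("dose-response must include the unstressed (0 mM) rate")
    mu0 = rates[0]
    if mu0 <= 0:
        raise ValueError("unstressed growth rate must be > 0")
    half = mu0 / 2.0

    if method == "interpolation":
        for i in range(len(conc) - 1):
            r_hi, r_lo = rates[i], rates[i + 1]
            if r_hi >= half >= r_lo:
                if r_hi == r_lo:
                    return float(conc[i])
                frac = (r_hi - half) / (r_hi - r_lo)
                return float(conc[i] + frac * (conc[i + 1] - conc[i]))
        raise ValueError("IC50 outside tested range")
    if method == "hill":
        if np.all(rates[1:] >= half):
            raise ValueError("IC50 outside tested range")
        p0 = (mu0, _interp_guess(conc, rates, half), 2.0)
        popt, _ = optimize.curve_fit(
            _hill,
            conc,
            rates,
            p0=p0,
            bounds=([1e-9, 1e-9, 1e-3], [np.inf, np.inf, 50.0]),
            maxfev=20000,
        )
        return float(popt[1]), float(popt[2])
    raise ValueError(f"unknown method {method!r}")


def _interp_guess(conc, rates, half) -> float:
    for i in range(len(conc) - 1):
        if rates[i] >= half >= rates[i + 1] and rates[i] > rates[i + 1]:
            frac = (rates[i] - half) / (rates[i] - rates[i + 1])
            return float(conc[i] + frac * (conc[i + 1] - conc[i]))
    return float(conc[len(conc) // 2] or 1.0)


def additive_expectation(relative_fitnesses) -> float:
    """Expected combined relative fitness under additivity: 1 + sum (w_i - 1)."""
    ws = list(relative_fitnesses)
    if any(w <= 0 for w in ws):
        raise ValueError("relative fitnesses must be > 0")
    return 1.0 + sum(w - 1.0 for w in ws)
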