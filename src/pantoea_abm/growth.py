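"""Logistic summaries of population curves.

Each simulated population curve is reduced to three numbers by fitting its
growth portion to the modified logistic

    y(t) = A / (1 + exp( 4·μ/A · (τ − t) + 2 ))

whose parameters are directly interpretable: ``A`` is the asymptotic
maximum, ``μ`` the maximum slope (attained at the inflection) and ``τ`` the
lag time (where the tangent at the inflection crosses the baseline).

Two fit spaces are supported.  ``counts`` fits the raw viable-cell count, so
A is a cell number and μ has units of cells/h.  ``log_ratio`` fits
ln(N(t)/N(0)), in which μ is a specific growth rate in h⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PopulationCurve",
    "GrowthOutputs",
    "logistic_model",
    "extract_growth_window",
    "fit_growth",
    "average_outputs",
]


@dataclass
class PopulationCurve:
    """Viable-cell count over simulated time (hours)."""

    time_h: np.ndarray
    population: np.ndarray
    seed: int = 0
    parameter_set_id: int | None = None

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.population = np.asarray(self.population)
        if self.time_h.ndim != 1 or self.time_h.shape != self.population.shape:
            raise ValueError("time_h and population must be 1-D and equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.population < 0):
            raise ValueError("population counts must be non-negative")


@dataclass
class GrowthOutputs:
    """Logistic-fit summaries of one curve, with fit diagnostics."""

    A: float
    mu: float
    tau: float
    r2_fit: float
    converged: bool
    fit_space: str = "counts"


def logistic_model(t, A, mu, tau):
    """Modified logistic with explicit maximum A, slope mu and lag tau."""
    if np.any(np.asarray(A) <= 0):
        raise ValueError("A must be positive")
    z = (4.0 * mu / A) * (tau - np.asarray(t, dtype=float)) + 2.0
    # clip to avoid overflow in exp; exp(700) already ~1e304
    return A / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))


def _logistic_unchecked(t, A, mu, tau):
    z = (4.0 * mu / max(A, 1e-300)) * (tau - t) + 2.0
    return A / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))


def extract_growth_window(
    y: np.ndarray,
    rise_frac: float = 0.02,
    plateau_frac: float = 0.02,
) -> tuple[int, int]:
    """Indices [start, stop) of the growth portion of a response.

    ``start`` is the first sustained increase: the first index whose value
    exceeds the initial level by ``rise_frac`` of the dynamic range (stepped
    back by one so the fit anchors the pre-rise level).  ``stop`` is plateau
    onset: one past the first index at which the response has come within
    ``plateau_frac`` of its maximum, extended by a few samples so the
    asymptote is anchored.
    """
    n = y.size
    y0, ymax = y[0], y.max()
    rng_ = ymax - y0
    if rng_ <= 0:
        return 0, n
    above = np.flatnonzero(y > y0 + rise_frac * rng_)
    start = max(int(above[0]) - 1, 0) if above.size else 0
    onset = int(np.flatnonzero(y >= ymax - plateau_frac * rng_)[0])
    stop = min(max(onset + 1, start + 2), n)
    # keep a few plateau samples so the asymptote is anchored
    stop = min(stop + max(3, n // 50), n)
    return start, stop


def fit_growth(
    curve: PopulationCurve,
    fit_space: str = "counts",
    r2_gate: float = 0.9,
    rise_frac: float = 0.02,
    plateau_frac: float = 0.02,
) -> GrowthOutputs:
    """Fit the growth portion of a curve and return (A, mu, tau).

    Degenerate inputs (flat, all-zero or monotone-decreasing curves, or an
    optimizer failure, or a fit with R² below ``r2_gate``) yield
    ``converged=False`` rather than an exception; such curves are excluded
    from downstream datasets.
    """
    t = curve.time_h
    N = np.asarray(curve.population, dtype=float)
    bad = GrowthOutputs(np.nan, np.nan, np.nan, np.nan, False, fit_space)

    if fit_space == "counts":
        y = N
    elif fit_space == "log_ratio":
        if N[0] <= 0:
            return bad
        pos = N > 0
        # trailing die-off (zeros) is not part of the growth portion
        t, N = t[pos], N[pos]
        y = np.log(N / N[0])
    else:
        raise ValueError(f"unknown fit_space {fit_space!r}")

    if t.size < 10 or y.max() - y[0] <= 0:
        return bad

    start, stop = extract_growth_window(y, rise_frac, plateau_frac)
    tw, yw = t[start:stop], y[start:stop]
    if tw.size < 5 or yw.max() <= 0:
        return bad

    A0 = float(yw.max())
    slopes = np.diff(yw) / np.diff(tw)
    mu0 = float(max(slopes.max(), 1e-6))
    t_steep = float(tw[np.argmax(slopes)])
    tau0 = max(t_steep - A0 / (2.0 * mu0), 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic_unchecked,
                tw,
                yw,
                p0=[A0, mu0, tau0],
                bounds=([1e-12, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        return bad
    A, mu, tau = (float(v) for v in popt)
    pred = _logistic_unchecked(tw, A, mu, tau)
    ss_res = float(np.sum((yw - pred) ** 2))
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    converged = bool(np.isfinite(r2) and r2 >= r2_gate and A > 0)
    return GrowthOutputs(A, mu, tau, r2, converged, fit_space)


@dataclass
class AveragedOutputs:
    A_mean: float
    mu_mean: float
    tau_mean: float
    A_sd: float
    mu_sd: float
    tau_sd: float
    n_converged: int


def average_outputs(replicates: list[GrowthOutputs]) -> AveragedOutputs:
    """Mean and SD of (A, mu, tau) over the converged replicates only."""
    conv = [r for r in replicates if r.converged]
    if not conv:
        raise ValueError("no converged replicates to average")
    arr = np.array([[r.A, r.mu, r.tau] for r in conv])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    return AveragedOutputs(*mean, *sd, len(conv))
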