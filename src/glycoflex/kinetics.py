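"""Steady-state kinetics and macromolecular rate theory (MMRT).

Absorbance slopes from the OPD→DAP chromogenic assay are converted to
per-enzyme turnover rates, fitted to the Michaelis–Menten equation, and the
temperature dependence of kcat is fitted to the MMRT expression

    ln k = ln(kB·T/h) − [ΔH‡(T0) + ΔCp‡(T − T0)]/(R·T)
                      + [ΔS‡(T0) + ΔCp‡·ln(T/T0)]/R,

whose negative activation heat capacity ΔCp‡ produces curvature and an
apparent temperature optimum at the stationary point of ln k,

    T_opt = (ΔCp‡·T0 − ΔH‡(T0)) / (ΔCp‡ + R).

ΔH‡ is in kJ mol^-1 and ΔS‡, ΔCp‡ in kJ mol^-1 K^-1; R enters in kJ units
in the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import H_PLANCK, KB, R_J, R_KJ

__all__ = [
    "RateTable",
    "MichaelisMentenFit",
    "TempRateSeries",
    "MMRTFit",
    "rate_from_absorbance",
    "fit_michaelis_menten",
    "eval_mmrt",
    "fit_mmrt",
    "compute_topt",
]


def rate_from_absorbance(
    slope_per_min: float,
    enzyme_M: float,
    epsilon: float = 10600.0,
    path_cm: float = 1.0,
) -> float:
    """Turnover rate (s^-1) from an absorbance slope (A450 per minute).

    rate = slope / (ε · l · [E] · 60) using the DAP extinction coefficient
    ε450 = 10 600 M^-1 cm^-1 by default.
    """
    if enzyme_M <= 0:
        raise ValueError("enzyme concentration must be positive")
    return slope_per_min / (epsilon * path_cm * enzyme_M * 60.0)


@dataclass
class RateTable:
    """Substrate concentrations (mM) vs per-enzyme turnover rates (s^-1)."""

    substrate_mM: np.ndarray
    rate_s: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.substrate_mM = np.asarray(self.substrate_mM, float)
        self.rate_s = np.asarray(self.rate_s, float)
        if self.substrate_mM.shape != self.rate_s.shape:
            raise ValueError("substrate and rate arrays differ in length")
        if np.any(self.substrate_mM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rate_s < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class MichaelisMentenFit:
    kcat: float  # s^-1
    km: float  # mM
    kcat_se: float = np.nan
    km_se: float = np.nan
    converged: bool = True

    @property
    def vmax(self) -> float:
        return self.kcat

    @property
    def efficiency(self) -> float:
        """kcat/KM in s^-1 M^-1 (KM converted mM → M)."""
        return self.kcat / (self.km * 1e-3)

    def model(self, s) -> np.ndarray:
        s = np.asarray(s, float)
        return self.kcat * s / (self.km + s)

    def to_dict(self) -> dict:
        return {
            "kcat": self.kcat,
            "km": self.km,
            "kcat_se": self.kcat_se,
            "km_se": self.km_se,
            "efficiency": self.efficiency,
            "converged": self.converged,
        }


def fit_michaelis_menten(table: RateTable) -> MichaelisMentenFit:
    """Nonlinear fit of v = kcat·[S]/(KM + [S]).

    Needs rates already normalised per enzyme (see rate_from_absorbance) and
    at least 5 distinct substrate concentrations. Negative or non-converged
    estimates are flagged rather than silently returned.
    """
    s, v = table.substrate_mM, table.rate_s
    if np.unique(s).size < 5:
        raise ValueError("need at least 5 distinct substrate concentrations")

    def mm(s_, kcat, km):
        return kcat * s_ / (km + s_)

    p0 = [float(np.max(v)) or 1.0, float(np.median(s))]
    try:
        popt, pcov = curve_fit(mm, s, v, p0=p0, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        ok = bool(popt[0] > 0 and popt[1] > 0)
    except RuntimeError:
        popt, perr, ok = p0, [np.nan, np.nan], False
    return MichaelisMentenFit(
        kcat=float(popt[0]),
        km=float(popt[1]),
        kcat_se=float(perr[0]),
        km_se=float(perr[1]),
        converged=ok,
    )


@dataclass
class TempRateSeries:
    """Assay temperature (K) vs kcat (s^-1)."""

    temperature: np.ndarray
    kcat: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.kcat = np.asarray(self.kcat, float)
        if self.temperature.shape != self.kcat.shape:
            raise ValueError("arrays differ in length")
        if np.any(self.kcat <= 0):
            raise ValueError("kcat must be positive (rates below detection excluded)")
        if np.any(self.temperature <= 0):
            raise ValueError("temperatures must be in Kelvin")


@dataclass
class MMRTFit:
    """MMRT parameters at reference temperature t0 (K).

    dh_t0 in kJ mol^-1; ds_t0, dcp in kJ mol^-1 K^-1.
    """

    dh_t0: float
    ds_t0: float
    dcp: float
    t0: float = 298.0
    dh_se: float = np.nan
    ds_se: float = np.nan
    dcp_se: float = np.nan
    converged: bool = True

    @property
    def t_opt(self) -> float:
        return compute_topt(self)

    def lnk(self, T) -> np.ndarray:
        return eval_mmrt(self, T)

    def to_dict(self) -> dict:
        d = {
            "dh_t0": self.dh_t0,
            "ds_t0": self.ds_t0,
            "dcp": self.dcp,
            "t0": self.t0,
            "dh_se": self.dh_se,
            "ds_se": self.ds_se,
            "dcp_se": self.dcp_se,
            "converged": self.converged,
        }
        try:
            d["t_opt"] = self.t_opt
        except ValueError:
            d["t_opt"] = None
        return d


def eval_mmrt(fit: MMRTFit, T) -> np.ndarray:
    """ln k at temperature(s) T for the given MMRT parameters.

    kB = 1.380649e-23 J/K, h = 6.62607015e-34 J s, R = 8.314 J mol^-1 K^-1;
    the kJ-based enthalpy/entropy/heat-capacity inputs are converted to J.
    """
    T = np.asarray(T, float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    dh = fit.dh_t0 * 1000.0
    ds = fit.ds_t0 * 1000.0
    dcp = fit.dcp * 1000.0
    return (
        np.log(KB * T / H_PLANCK)
        - (dh + dcp * (T - fit.t0)) / (R_J * T)
        + (ds + dcp * np.log(T / fit.t0)) / R_J
    )


def fit_mmrt(series: TempRateSeries, t0: float = 298.0) -> MMRTFit:
    """Fit ln kcat vs T to the MMRT expression with fixed T0.

    Fitting on ln k stabilises the variance. T0 is arbitrary and fixed
    (default 298 K); ΔH‡ and ΔS‡ are reported at that reference. A monotone
    series yields a T_opt outside the assay range, surfaced by compute_topt.
    """
    T, k = series.temperature, series.kcat
    if np.unique(T).size < 5:
        raise ValueError("need at least 5 distinct temperatures")
    y = np.log(k)

    def f(T_, dh, ds, dcp):
        return eval_mmrt(MMRTFit(dh, ds, dcp, t0), T_)

    # Eyring-line start: slope of ln k - ln(kB T/h) vs 1/T gives ΔH‡
    z = y - np.log(KB * T / H_PLANCK)
    slope, intercept = np.polyfit(1.0 / T, z, 1)
    p0 = [-slope * R_J / 1000.0, intercept * R_J / 1000.0, -1.0]
    try:
        popt, pcov = curve_fit(f, T, y, p0=p0, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        ok = True
    except RuntimeError:
        popt, perr, ok = p0, [np.nan] * 3, False
    return MMRTFit(
        dh_t0=float(popt[0]),
        ds_t0=float(popt[1]),
        dcp=float(popt[2]),
        t0=t0,
        dh_se=float(perr[0]),
        ds_se=float(perr[1]),
        dcp_se=float(perr[2]),
        converged=ok,
    )


def compute_topt(fit: MMRTFit, valid_range: tuple[float, float] = (250.0, 400.0)) -> float:
    """Apparent temperature optimum from d ln k/dT = 0 in closed form.

    d ln k/dT = 1/T + [ΔH‡(T0) + ΔCp‡(T − T0)]/(R T²) vanishes at
    T_opt = (ΔCp‡·T0 − ΔH‡(T0)) / (ΔCp‡ + R), R in kJ mol^-1 K^-1.
    Raises if the stationary point does not exist or falls outside
    ``valid_range`` (e.g. for an effectively linear Eyring series).
    """
    denom = fit.dcp + R_KJ
    if denom == 0:
        raise ValueError("no stationary point: ΔCp‡ + R = 0")
    if denom > 0:
        # rate of change of d ln k/dT is positive: stationary point is a minimum
        raise ValueError("stationary point is a minimum, not an optimum (ΔCp‡ > −R)")
    topt = (fit.dcp * fit.t0 - fit.dh_t0) / denom
    if not (valid_range[0] < topt < valid_range[1]):
        raise ValueError(f"stationary point {topt:.1f} K outside {valid_range}")
    return float(topt)
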