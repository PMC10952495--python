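"""Two-state analysis of CD thermal melts.

The ellipticity at 222 nm along a temperature ramp is modelled as a
population-weighted average of sloping folded and unfolded baselines,

    θ(T) = [bf + mf·T + (bu + mu·T)·Ku] / (1 + Ku),
    Ku(T) = exp[ΔH·(1 − T/Tm) / (R·T)],

where Tm is the melt midpoint (Ku(Tm) = 1) and ΔH the Van't Hoff enthalpy
of unfolding at Tm. Curves may be normalised to pass through 0 and 1 at two
anchor temperatures before plotting; normalisation is affine and commutes
with the fit (Tm and ΔH are unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import R_J

__all__ = [
    "MeltCurve",
    "TwoStateFit",
    "normalise_melt",
    "unfolding_constant",
    "two_state_model",
    "fit_two_state",
]


@dataclass
class MeltCurve:
    """Temperature (K, strictly increasing) vs CD signal at 222 nm (a.u.)."""

    temperature: np.ndarray
    signal: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal differ in length")
        if self.temperature.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")


def normalise_melt(curve: MeltCurve, t_zero: float, t_one: float) -> MeltCurve:
    """Affine rescale so the signal is 0 at ``t_zero`` and 1 at ``t_one``.

    Anchor signals are linearly interpolated when the anchors fall between
    samples (e.g. 0 at 300 K and 1 at 353 or 363 K).
    """
    t, s = curve.temperature, curve.signal
    if not (t[0] <= t_zero <= t[-1]) or not (t[0] <= t_one <= t[-1]):
        raise ValueError("anchor temperatures outside the measured range")
    s0 = float(np.interp(t_zero, t, s))
    s1 = float(np.interp(t_one, t, s))
    if s0 == s1:
        raise ValueError("degenerate anchors: equal signal values")
    return MeltCurve(t.copy(), (s - s0) / (s1 - s0), normalised=True)


def unfolding_constant(T, tm: float, dh_vh: float):
    """Equilibrium constant of unfolding, Ku = exp[−ΔH(1 − T/Tm)/(R·T)].

    This is the van't Hoff form with ΔG(T) = ΔH(1 − T/Tm): Ku(Tm) = 1
    identically and, for ΔH > 0, unfolding is favoured above Tm.
    ``dh_vh`` in kJ mol^-1; R = 8.314 J mol^-1 K^-1 (the denominator uses
    R·T, not R·Tm).
    """
    T = np.asarray(T, float)
    if np.any(T <= 0) or tm <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    return np.exp(-dh_vh * 1000.0 * (1.0 - T / tm) / (R_J * T))


def two_state_model(T, tm, dh_vh, bf, mf, bu, mu):
    ku = unfolding_constant(T, tm, dh_vh)
    T = np.asarray(T, float)
    return (bf + mf * T + (bu + mu * T) * ku) / (1.0 + ku)


@dataclass
class TwoStateFit:
    """Fitted two-state melt: Tm (K), Van't Hoff ΔH (kJ/mol) and baselines."""

    tm: float
    dh_vh: float
    bf: float
    mf: float
    bu: float
    mu: float
    tm_se: float = np.nan
    dh_se: float = np.nan
    converged: bool = True
    no_transition: bool = False

    def fraction_unfolded(self, T) -> np.ndarray:
        ku = unfolding_constant(T, self.tm, self.dh_vh)
        return ku / (1.0 + ku)

    def model(self, T) -> np.ndarray:
        return two_state_model(T, self.tm, self.dh_vh, self.bf, self.mf, self.bu, self.mu)

    def to_dict(self) -> dict:
        return {
            "tm": self.tm,
            "dh_vh": self.dh_vh,
            "bf": self.bf,
            "mf": self.mf,
            "bu": self.bu,
            "mu": self.mu,
            "tm_se": self.tm_se,
            "dh_se": self.dh_se,
            "converged": self.converged,
            "no_transition": self.no_transition,
        }


def _initial_guess(t: np.ndarray, s: np.ndarray) -> list[float]:
    k = max(2, int(0.15 * t.size))
    mf, bf = np.polyfit(t[:k], s[:k], 1)
    mu, bu = np.polyfit(t[-k:], s[-k:], 1)
    # smoothed derivative locates the transition
    ds = np.gradient(np.convolve(s, np.ones(5) / 5, mode="same"), t)
    tm0 = float(t[np.argmax(np.abs(ds[2:-2])) + 2])
    return [tm0, 300.0, bf, mf, bu, mu]


def fit_two_state(curve: MeltCurve, init: list[float] | None = None) -> TwoStateFit:
    """Least-squares fit of the two-state model with sloping baselines.

    A flat curve (no resolvable transition, as for apo-rHRP which is
    unfolded before the ramp) sets ``no_transition`` instead of reporting a
    spurious Tm: the rule is a fitted transition amplitude at Tm below 5% of
    the total signal range, or a Tm estimate pinned to a range bound.
    """
    t, s = curve.temperature, curve.signal
    p0 = init if init is not None else _initial_guess(t, s)

    lo = [t[0], -5000.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 5000.0, np.inf, np.inf, np.inf, np.inf]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return two_state_model(t, *p) - s

    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    tm, dh, bf, mf, bu, mu = sol.x

    # standard errors from the Jacobian at the solution
    try:
        dof = max(t.size - 6, 1)
        s2 = np.sum(sol.fun**2) / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        tm_se, dh_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        tm_se = dh_se = np.nan

    amplitude = abs((bu + mu * tm) - (bf + mf * tm))
    sig_range = float(np.ptp(s))
    at_bound = tm <= t[0] + 1e-9 or tm >= t[-1] - 1e-9
    no_transition = sig_range == 0 or amplitude < 0.05 * sig_range or at_bound

    return TwoStateFit(
        tm=float(tm),
        dh_vh=float(dh),
        bf=float(bf),
        mf=float(mf),
        bu=float(bu),
        mu=float(mu),
        tm_se=tm_se,
        dh_se=dh_se,
        converged=bool(sol.success),
        no_transition=bool(no_transition),
    )
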