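"""Red-edge excitation shift (REES) analysis of tryptophan fluorescence.

An emission spectrum measured at each of a series of excitation wavelengths
is deconvolved into a sum of two skewed Gaussians; the component attributable
to tryptophan emission is summarised by its centre of spectral mass (CSM,
the intensity-weighted mean emission wavelength). Plotting CSM against the
red-shift of the excitation wavelength, Δλ_Ex, and fitting

    CSM(Δλ_Ex) = CSM0 + A · exp(R · Δλ_Ex)

quantifies the REES effect. The A/R ratio is used as an empirical flexibility
metric: a larger A/R reflects a wider distribution of solvent–fluorophore
environments and hence a more flexible protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "SkewedGaussian",
    "EmissionSpectrum",
    "SpectralFit",
    "REESCurve",
    "REESFit",
    "eval_skewed_gaussian",
    "fit_spectrum",
    "compute_csm",
    "build_rees_curve",
    "fit_rees_curve",
    "flexibility_ratio",
    "average_replicates",
]

#: below this |b| the skewed Gaussian is evaluated in its symmetric limit;
#: with log1p the exact form is stable down to here, and at the threshold the
#: two branches agree to < 1e-6 of f_max
B_SYMMETRIC_LIMIT = 1e-6

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class SkewedGaussian:
    """One skewed-Gaussian spectral component.

    ``f_max`` is the peak intensity reached exactly at ``lambda_max`` (nm);
    ``width`` is the full width at half maximum in the symmetric limit (nm);
    ``skew`` controls the asymmetry (dimensionless; 0 means symmetric).
    """

    f_max: float
    lambda_max: float
    width: float
    skew: float

    def __post_init__(self) -> None:
        if not (self.f_max > 0):
            raise ValueError("f_max must be positive")
        if not (self.width > 0):
            raise ValueError("width must be positive")

    def __call__(self, lambda_em):
        return eval_skewed_gaussian(self, lambda_em)

    def integrated_area(self, grid: np.ndarray) -> float:
        return float(np.trapezoid(self(grid), grid))


def eval_skewed_gaussian(g: SkewedGaussian, lambda_em) -> np.ndarray | float:
    """Evaluate a skewed Gaussian at emission wavelength(s) ``lambda_em`` (nm).

    f(λ) = f_max · exp(−ln2 · [ln(1 + 2b(λ−λmax)/w) / b]²)

    The function is defined to be 0 wherever 1 + 2b(λ−λmax)/w ≤ 0. For
    |b| < ``B_SYMMETRIC_LIMIT`` the symmetric limit
    f_max · exp(−4 ln2 (λ−λmax)²/w²) is returned, in which case ``width`` is
    exactly the FWHM.
    """
    lam = np.asarray(lambda_em, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("emission wavelength must be finite")
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    u = 2.0 * (lam - g.lambda_max) / g.width
    if abs(g.skew) < B_SYMMETRIC_LIMIT:
        out = g.f_max * np.exp(-_LN2 * u * u)
    else:
        arg = g.skew * u
        out = np.zeros_like(lam)
        ok = arg > -1.0
        z = np.log1p(arg[ok]) / g.skew
        out[ok] = g.f_max * np.exp(-_LN2 * z * z)
    return float(out[0]) if scalar else out


@dataclass
class EmissionSpectrum:
    """A fluorescence emission spectrum recorded at one excitation wavelength.

    Emission is nominally scanned 315–500 nm; intensities are in arbitrary
    fluorescence units.
    """

    excitation_wavelength: float
    emission_wavelengths: np.ndarray
    intensities: np.ndarray
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.emission_wavelengths = np.asarray(self.emission_wavelengths, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.emission_wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity arrays differ in length")
        if self.emission_wavelengths.size < 10:
            raise ValueError("spectrum needs at least 10 points")
        if not np.all(np.diff(self.emission_wavelengths) > 0):
            raise ValueError("emission wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")


def average_replicates(spectra: list[EmissionSpectrum]) -> EmissionSpectrum:
    """Point-wise average of replicate spectra sharing one excitation
    wavelength and emission grid (up to 12 independent readings are typical)."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.excitation_wavelength != first.excitation_wavelength:
            raise ValueError("replicates must share the excitation wavelength")
        if not np.array_equal(s.emission_wavelengths, first.emission_wavelengths):
            raise ValueError("replicates must share the emission grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return EmissionSpectrum(
        excitation_wavelength=first.excitation_wavelength,
        emission_wavelengths=first.emission_wavelengths.copy(),
        intensities=mean,
        replicate_id="mean",
    )


@dataclass
class SpectralFit:
    """Result of deconvolving one spectrum into two skewed Gaussians."""

    component_1: SkewedGaussian
    component_2: SkewedGaussian
    trp_component: int  # 1 or 2
    residual_norm: float
    converged: bool

    @property
    def trp(self) -> SkewedGaussian:
        return self.component_1 if self.trp_component == 1 else self.component_2

    def model(self, grid: np.ndarray) -> np.ndarray:
        return self.component_1(grid) + self.component_2(grid)


def _assign_trp(c1: SkewedGaussian, c2: SkewedGaussian, grid: np.ndarray) -> int:
    """Label the tryptophan component: λmax within 320–400 nm and the larger
    integrated area; ties (both or neither in-window) fall back to area, then
    to the smaller λmax."""
    in_win = [320.0 <= c.lambda_max <= 400.0 for c in (c1, c2)]
    areas = [c.integrated_area(grid) for c in (c1, c2)]
    if in_win[0] != in_win[1]:
        return 1 if in_win[0] else 2
    if not np.isclose(areas[0], areas[1]):
        return 1 if areas[0] > areas[1] else 2
    return 1 if c1.lambda_max <= c2.lambda_max else 2


def _smooth(y: np.ndarray, half_window: int = 3) -> np.ndarray:
    k = 2 * half_window + 1
    return np.convolve(y, np.ones(k) / k, mode="same")


def _initial_component(grid: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    ys = _smooth(y)
    i_max = int(np.argmax(ys))
    f0 = max(y[i_max], 1e-12)
    lam0 = grid[i_max]
    half = ys >= 0.5 * ys[i_max]
    if half.sum() >= 2:
        w0 = float(grid[half][-1] - grid[half][0])
    else:
        w0 = 60.0
    w0 = min(max(w0, 5.0), 200.0)
    return f0, lam0, w0, 0.1


def fit_spectrum(
    spectrum: EmissionSpectrum, init: SpectralFit | None = None
) -> SpectralFit:
    """Nonlinear least-squares fit of a sum of two skewed Gaussians.

    Eight free parameters; requires at least 64 data points (8× the parameter
    count). The tryptophan component is labelled by the documented
    λmax-window / integrated-area rule. Non-convergence is flagged on the
    result, never silent.
    """
    grid = spectrum.emission_wavelengths
    y = spectrum.intensities
    n_par = 8
    if grid.size < 8 * n_par:
        raise ValueError(
            f"need at least {8 * n_par} points for an 8-parameter fit, got {grid.size}"
        )

    if init is not None:
        p0 = []
        for c in (init.component_1, init.component_2):
            p0 += [c.f_max, c.lambda_max, c.width, c.skew]
    else:
        f0, lam0, w0, b0 = _initial_component(grid, y)
        # second component: red-shifted shoulder at ~40% amplitude
        p0 = [f0, lam0, w0, b0, 0.4 * f0, min(lam0 + 70.0, grid[-1]), w0, b0]

    scale = max(np.max(y), 1e-12)
    lo = [1e-10 * scale, grid[0] - 50, 5.0, -2.0] * 2
    hi = [10.0 * scale, grid[-1] + 50, 200.0, 2.0] * 2
    p0 = np.clip(p0, lo, hi)

    def unpack(p):
        c1 = SkewedGaussian(p[0], p[1], p[2], p[3])
        c2 = SkewedGaussian(p[4], p[5], p[6], p[7])
        return c1, c2

    def resid(p):
        c1, c2 = unpack(p)
        return c1(grid) + c2(grid) - y

    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    c1, c2 = unpack(sol.x)
    rn = float(np.sum(sol.fun**2))
    return SpectralFit(
        component_1=c1,
        component_2=c2,
        trp_component=_assign_trp(c1, c2, grid),
        residual_norm=rn,
        converged=bool(sol.success),
    )


def compute_csm(
    g_or_wavelengths: SkewedGaussian | np.ndarray,
    intensities_or_grid: np.ndarray | None = None,
) -> float:
    """Centre of spectral mass: CSM = Σ fᵢ λᵢ / Σ fᵢ over the emission grid.

    Call either as ``compute_csm(wavelengths, intensities)`` for raw points,
    or as ``compute_csm(component, grid)`` to evaluate a fitted component on
    an emission grid first.
    """
    if isinstance(g_or_wavelengths, SkewedGaussian):
        grid = np.asarray(intensities_or_grid, float)
        f = g_or_wavelengths(grid)
    else:
        grid = np.asarray(g_or_wavelengths, float)
        f = np.asarray(intensities_or_grid, float)
    if np.any(f < 0) or not np.any(f > 0):
        raise ValueError("CSM needs non-negative intensities with at least one positive")
    return float(np.sum(f * grid) / np.sum(f))


@dataclass
class REESCurve:
    """CSM of the tryptophan component versus excitation red-shift Δλ_Ex."""

    delta_lambda_ex: np.ndarray
    csm: np.ndarray
    excitation_wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_lambda_ex = np.asarray(self.delta_lambda_ex, float)
        self.csm = np.asarray(self.csm, float)
        if self.delta_lambda_ex.shape != self.csm.shape:
            raise ValueError("arrays differ in length")
        if self.delta_lambda_ex[0] != 0 or np.any(np.diff(self.delta_lambda_ex) <= 0):
            raise ValueError("delta_lambda_ex must start at 0 and strictly increase")


def build_rees_curve(
    spectra: list[EmissionSpectrum], fits: list[SpectralFit]
) -> REESCurve:
    """Assemble the per-excitation tryptophan-component CSMs into a REES curve.

    Spectra must be sorted by excitation wavelength with one fit each;
    Δλ_Ex is measured from the lowest excitation wavelength.
    """
    if len(spectra) != len(fits):
        raise ValueError("one fit per spectrum required")
    ex = np.array([s.excitation_wavelength for s in spectra], float)
    if np.unique(ex).size != ex.size:
        raise ValueError("duplicate excitation wavelengths")
    if np.any(np.diff(ex) <= 0):
        raise ValueError("spectra must be sorted by excitation wavelength")
    csm = np.array(
        [compute_csm(f.trp, s.emission_wavelengths) for s, f in zip(spectra, fits)]
    )
    return REESCurve(delta_lambda_ex=ex - ex[0], csm=csm, excitation_wavelengths=ex)


@dataclass
class REESFit:
    """Exponential fit CSM = CSM0 + A·exp(R·Δλ_Ex) with standard errors."""

    csm0: float
    a: float
    r: float
    csm0_se: float = np.nan
    a_se: float = np.nan
    r_se: float = np.nan
    flat: bool = False  # no resolvable amplitude (A consistent with 0)
    converged: bool = True

    @property
    def a_over_r(self) -> float:
        return flexibility_ratio(self)

    def model(self, dlx) -> np.ndarray:
        return self.csm0 + self.a * np.exp(self.r * np.asarray(dlx, float))

    def to_dict(self) -> dict:
        return {
            "csm0": self.csm0,
            "a": self.a,
            "r": self.r,
            "csm0_se": self.csm0_se,
            "a_se": self.a_se,
            "r_se": self.r_se,
            "a_over_r": self.a_over_r if not self.flat else 0.0,
            "flat": bool(self.flat),
            "converged": bool(self.converged),
        }


def fit_rees_curve(curve: REESCurve, weights: np.ndarray | None = None) -> REESFit:
    """Least-squares estimate of (CSM0, A, R) from a REES curve.

    Needs ≥ 6 points. A degenerate flat curve is reported with ``flat=True``
    (amplitude statistically indistinguishable from 0) rather than raising.
    Fits are unweighted by default; optional per-point standard deviations may
    be supplied as ``weights``.
    """
    x, y = curve.delta_lambda_ex, curve.csm
    if x.size < 6:
        raise ValueError("need at least 6 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("CSM values must be finite")

    rng_y = float(np.ptp(y))
    if rng_y < 1e-12:
        return REESFit(csm0=float(np.mean(y)), a=0.0, r=0.0, flat=True)

    def f(x_, csm0, a, r):
        return csm0 + a * np.exp(r * x_)

    p0 = [float(np.min(y)), rng_y, 0.1]
    try:
        popt, pcov = curve_fit(
            f,
            x,
            y,
            p0=p0,
            sigma=weights,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        converged = True
    except RuntimeError:
        popt, perr, converged = p0, [np.nan] * 3, False

    # amplitude indistinguishable from zero at ~2 sigma -> flag, don't crash
    flat = bool(np.isfinite(perr[1]) and abs(popt[1]) < 2.0 * perr[1])
    return REESFit(
        csm0=float(popt[0]),
        a=float(popt[1]),
        r=float(popt[2]),
        csm0_se=float(perr[0]),
        a_se=float(perr[1]),
        r_se=float(perr[2]),
        flat=flat,
        converged=converged,
    )


def flexibility_ratio(fit: REESFit) -> float:
    """A/R in nm²; larger values are read as a more flexible protein.

    The interpretation (wider distribution of equilibrium conformational
    states) is documented, not enforced.
    """
    if fit.r == 0:
        if fit.a == 0:
            return 0.0
        raise ZeroDivisionError("A/R undefined for R = 0")
    return fit.a / fit.r


def warn_if_unconverged(fit: SpectralFit | REESFit) -> None:
    if not fit.converged:
        warnings.warn("fit did not converge", RuntimeWarning, stacklevel=2)
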