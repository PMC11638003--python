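"""Diffusion-side computations: viscosity, Stokes-Einstein, Smoluchowski
encounter rates, and FCS correlogram modelling.

The FCS model is the standard 3-D diffusion autocorrelation
G(tau) = G0 (1 + tau/tau_D)^-1 (1 + tau/(gamma^2 tau_D))^-1/2 with the
calibrated axial ratio gamma and lateral focal radius omega_r; the
diffusion coefficient follows from D = omega_r^2 / (4 tau_D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.optimize import curve_fit

__all__ = [
    "water_viscosity",
    "diffusion_coefficient",
    "hydrodynamic_radius",
    "HydroRecord",
    "EncounterRate",
    "encounter_rate",
    "FCSCurve",
    "FCSFit",
    "fcs_model",
    "correct_afterpulsing",
    "fit_fcs",
]

K_B = _const.k
N_A = _const.N_A

# Vogel-equation constants for pure water: eta = A exp(B / (T - C)),
# accurate to well under 1% across the 15-40 C range used here.
_VOGEL_A = 0.02939e-3  # Pa s
_VOGEL_B = 507.88      # K
_VOGEL_C = 149.3       # K


class HydroError(ValueError):
    pass


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of pure water (Pa s) at temperature T (K)."""
    T = float(T)
    if not 273.0 < T < 373.0:
        raise HydroError(f"temperature {T} K outside liquid-water range")
    return _VOGEL_A * math.exp(_VOGEL_B / (T - _VOGEL_C))


def diffusion_coefficient(T: float, eta: float, R_h: float) -> float:
    """Stokes-Einstein: D = k_B T / (6 pi eta R_h), all SI."""
    if min(T, eta, R_h) <= 0:
        raise HydroError("T, eta and R_h must all be > 0")
    return K_B * T / (6.0 * math.pi * eta * R_h)


def hydrodynamic_radius(T: float, eta: float, D: float) -> float:
    """Exact inversion of Stokes-Einstein for the particle radius."""
    if min(T, eta, D) <= 0:
        raise HydroError("T, eta and D must all be > 0")
    return K_B * T / (6.0 * math.pi * eta * D)


@dataclass(frozen=True)
class HydroRecord:
    """A mutually consistent (D, T, eta, R_h) quadruple."""

    D: float
    T: float
    eta: float
    R_h: float

    def __post_init__(self) -> None:
        expected = diffusion_coefficient(self.T, self.eta, self.R_h)
        if abs(self.D - expected) > 1e-6 * expected:
            raise HydroError("record violates the Stokes-Einstein relation")

    @classmethod
    def from_radius(cls, T: float, eta: float, R_h: float) -> "HydroRecord":
        return cls(D=diffusion_coefficient(T, eta, R_h),
                   T=T, eta=eta, R_h=R_h)

    @classmethod
    def from_diffusion(cls, T: float, eta: float, D: float) -> "HydroRecord":
        return cls(D=D, T=T, eta=eta, R_h=hydrodynamic_radius(T, eta, D))


@dataclass(frozen=True)
class EncounterRate:
    """Smoluchowski diffusional encounter rate in both unit conventions.

    ``molar`` is the standard diffusion-limited rate constant
    4 pi N_A (R1+R2)(D1+D2) x 1000 in L mol^-1 s^-1.  ``as_printed`` omits
    the factor-1000 volume conversion, the convention under which the
    literature magnitude of a few 10^6 for proteins of this size is
    quoted; the ratio of encounter to measured association rate is
    meaningful in this mode.
    """

    as_printed: float
    molar: float

    def value(self, mode: str = "as_printed") -> float:
        if mode == "as_printed":
            return self.as_printed
        if mode == "molar":
            return self.molar
        raise HydroError(f"unknown unit mode {mode!r}")


def encounter_rate(R_h1: float, R_h2: float,
                   D1: float, D2: float) -> EncounterRate:
    """Diffusional encounter rate of two spherical particles.

    Radii in metres, diffusion coefficients in m^2 s^-1.  Symmetric in the
    two particles.
    """
    if min(R_h1, R_h2) <= 0 or min(D1, D2) < 0:
        raise HydroError("radii must be > 0 and diffusivities >= 0")
    base = 4.0 * math.pi * N_A * (R_h1 + R_h2) * (D1 + D2)
    return EncounterRate(as_printed=base, molar=base * 1000.0)


@dataclass
class FCSCurve:
    """An autocorrelation curve on a log-spaced lag grid.

    ``baseline`` records the long-lag convention of the data: the pure
    diffusion model decays to 0; hardware correlators often report curves
    decaying to 1.
    """

    lag: np.ndarray  # s
    G: np.ndarray
    count_rate: float | None = None  # Hz
    baseline: str = "zero"  # 'zero' | 'one'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(np.diff(self.lag) <= 0) or np.any(self.lag <= 0):
            raise HydroError("lag grid must be positive, strictly increasing")
        if self.lag.shape != self.G.shape:
            raise HydroError("lag and G must have matching shapes")
        if self.baseline not in ("zero", "one"):
            raise HydroError(f"unknown baseline convention {self.baseline!r}")

    def zero_based(self) -> "FCSCurve":
        if self.baseline == "zero":
            return self
        return FCSCurve(self.lag.copy(), self.G - 1.0, self.count_rate,
                        "zero", dict(self.meta))


def fcs_model(tau, G0: float, tau_D: float, gamma: float):
    """3-D diffusion autocorrelation (zero-baseline convention)."""
    tau = np.asarray(tau, dtype=float)
    return (G0 / (1.0 + tau / tau_D)
            / np.sqrt(1.0 + tau / (gamma ** 2 * tau_D)))


def correct_afterpulsing(raw: FCSCurve, reference: FCSCurve,
                         i_ap: float | None = None) -> FCSCurve:
    """Remove detector after-pulsing using an uncorrelated reference.

    G(tau) = G'(tau) - (<i_ap>/<i>) (G_ap(tau) - 1), where the reference
    curve G_ap was recorded with uncorrelated light and both curves carry
    their mean count rates.  Both curves use the one-baseline convention of
    the raw correlator output; the reference is interpolated log-linearly
    in lag onto the data grid when the grids differ.
    """
    if raw.count_rate is None:
        raise HydroError("raw curve lacks its mean count rate")
    i_ap = reference.count_rate if i_ap is None else i_ap
    if i_ap is None:
        raise HydroError("after-pulsing reference lacks its count rate")
    if reference.lag.shape == raw.lag.shape and np.allclose(
            reference.lag, raw.lag):
        g_ap = reference.G
    else:
        g_ap = np.interp(np.log(raw.lag), np.log(reference.lag), reference.G)
    g = raw.G - (i_ap / raw.count_rate) * (g_ap - 1.0)
    return FCSCurve(raw.lag.copy(), g, raw.count_rate, raw.baseline,
                    dict(raw.meta))


@dataclass
class FCSFit:
    """Amplitude and diffusion time of the 3-D diffusion model."""

    G0: float
    tau_D: float  # s
    gamma: float
    omega_r: float  # m
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def D(self) -> float:
        """Diffusion coefficient from the focal geometry (m^2 s^-1)."""
        return self.omega_r ** 2 / (4.0 * self.tau_D)


#: Calibrated focal-volume parameters per excitation channel: the 510-nm
#: channel (reporter fluorophore) and the 640-nm channel (receptor Pr
#: fluorescence).
FOCAL_CALIBRATIONS = {
    "510nm": {"gamma": 9.0, "omega_r": 250e-9},
    "640nm": {"gamma": 6.0, "omega_r": 304e-9},
}


def fit_fcs(curve: FCSCurve, gamma: float = 9.0, omega_r: float = 250e-9,
            fit_gamma: bool = False) -> FCSFit:
    """Fit G0 and tau_D of the 3-D diffusion model to a correlogram.

    ``gamma`` (axial ratio) and ``omega_r`` (lateral focal radius) come
    from the instrument calibration; with ``fit_gamma`` the axial ratio is
    floated instead, mirroring the calibration procedure itself.
    """
    if gamma <= 0 or omega_r <= 0:
        raise HydroError("gamma and omega_r must be > 0")
    data = curve.zero_based()
    tau, g = data.lag, data.G
    flags = []
    if g[-1] > 0.5 * g[0]:
        flags.append("non-decaying")
    g0_guess = float(g[0])
    half = np.nonzero(g <= 0.5 * g0_guess)[0]
    tau_d0 = float(tau[half[0]]) if half.size else float(np.median(tau))

    if fit_gamma:
        def model(tt, g0, td, gm):
            return fcs_model(tt, g0, td, gm)
        p0 = [g0_guess, tau_d0, gamma]
        bounds = ([0.0, 0.0, 0.5], [np.inf, np.inf, 100.0])
    else:
        def model(tt, g0, td):
            return fcs_model(tt, g0, td, gamma)
        p0 = [g0_guess, tau_d0]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    try:
        popt, pcov = curve_fit(model, tau, g, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as err:
        raise HydroError(f"FCS fit failed: {err}") from err
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    resid = g - model(tau, *popt)
    fitted_gamma = float(popt[2]) if fit_gamma else gamma
    stderr = {"G0": se[0], "tau_D": se[1]}
    if fit_gamma:
        stderr["gamma"] = se[2]
    return FCSFit(G0=float(popt[0]), tau_D=float(popt[1]),
                  gamma=fitted_gamma, omega_r=omega_r,
                  stderr=stderr, rss=float(resid @ resid), flags=flags)
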