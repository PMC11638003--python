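"""Fitting procedures for time-resolved and equilibrium measurements.

Covers single/double exponential decays, the consecutive two-step
(photoreversion-then-dissociation) model, pseudo-first-order analysis of
observable rates versus binder concentration, single-site binding
isotherms with Pfr-fraction correction, Arrhenius temperature dependence,
two-state thermal unfolding, and the global multi-intensity fit of the
full photoconversion/binding ODE model.  Reported uncertainties are
asymptotic standard errors from the local quadratic approximation of the
least-squares objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy.optimize import curve_fit, least_squares, lsq_linear, minimize

from .model import (
    IlluminationProtocol,
    ModelError,
    ObservableMap,
    PFR_PHOTOEQUILIBRIUM_658,
    RateConstants,
    SystemComposition,
    TimeTrace,
    observe,
    simulate,
)

__all__ = [
    "FitError",
    "ExpFit",
    "ConsecutiveFit",
    "LinearKineticsFit",
    "IsothermFit",
    "ArrheniusFit",
    "MeltFit",
    "GlobalFitResult",
    "fit_monoexponential",
    "fit_biexponential",
    "fit_consecutive",
    "fit_pseudo_first_order",
    "fit_isotherm",
    "fit_arrhenius",
    "fit_two_state_melt",
    "consecutive_signal",
    "global_fit_interaction",
]

R_GAS = _const.R  # J mol^-1 K^-1


class FitError(RuntimeError):
    """Raised when a fit cannot be carried out at all."""


def _sigma(trace: TimeTrace):
    if trace.sd is not None and np.all(trace.sd > 0):
        return trace.sd
    return None


def _stderr(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov))


@dataclass
class ExpFit:
    """Result of a single- or double-exponential fit."""

    F0: float
    F1: float
    k1: float
    F2: float | None = None
    k2: float | None = None
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    flags: list = field(default_factory=list)
    slower_phase_dominant: bool | None = None

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.F0 + self.F1 * np.exp(-self.k1 * t)
        if self.F2 is not None:
            y = y + self.F2 * np.exp(-self.k2 * t)
        return y


def fit_monoexponential(trace: TimeTrace) -> ExpFit:
    """Fit F(t) = F0 + F1 exp(-k t) by nonlinear least squares."""
    t, y = trace.time, trace.signal
    if t.size < 5:
        raise FitError("monoexponential fit requires >= 5 points")
    span = float(np.ptp(y))
    if span == 0 or span < 1e-12 * max(1.0, abs(y[0])):
        return ExpFit(F0=float(y.mean()), F1=0.0, k1=np.nan,
                      flags=["constant-signal", "rate-unidentifiable"])

    t0 = t - t[0]
    f0_guess = float(y[-1])
    f1_guess = float(y[0] - y[-1])
    # crude rate guess: time to cover (1 - 1/e) of the total change
    target = y[0] - (1 - 1 / math.e) * (y[0] - y[-1])
    crossing = np.nonzero((y - target) * np.sign(y[0] - y[-1]) <= 0)[0]
    tau = t0[crossing[0]] if crossing.size and t0[crossing[0]] > 0 \
        else max(t0[-1] / 3.0, 1e-9)
    k_guess = 1.0 / tau

    def model(tt, f0, f1, k):
        return f0 + f1 * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model, t0, y, p0=[f0_guess, f1_guess, k_guess],
            sigma=_sigma(trace), absolute_sigma=trace.sd is not None,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"monoexponential fit failed: {err}") from err
    resid = y - model(t0, *popt)
    se = _stderr(pcov)
    flags = []
    if not np.all(np.isfinite(se)):
        flags.append("covariance-singular")
    if popt[2] <= 1e-12:
        flags.append("rate-at-bound")
    return ExpFit(F0=float(popt[0]), F1=float(popt[1]), k1=float(popt[2]),
                  stderr={"F0": se[0], "F1": se[1], "k1": se[2]},
                  rss=float(resid @ resid), flags=flags)


def fit_biexponential(trace: TimeTrace,
                      collapse_ratio: float = 1.5) -> ExpFit:
    """Fit F(t) = F0 + F1 exp(-k1 t) + F2 exp(-k2 t), with k1 > k2.

    Emits a ``rate-collapse`` flag when the two rates differ by less than
    ``collapse_ratio`` (the data are then effectively monoexponential) and
    records whether the slower phase carries the larger amplitude, the
    signature of dark-recovery data.
    """
    t, y = trace.time, trace.signal
    if t.size < 8:
        raise FitError("biexponential fit requires >= 8 points")
    mono = fit_monoexponential(trace)
    if "constant-signal" in mono.flags:
        return ExpFit(F0=mono.F0, F1=0.0, k1=np.nan, F2=0.0, k2=np.nan,
                      flags=list(mono.flags))
    k0 = mono.k1 if np.isfinite(mono.k1) else 1.0 / max(t[-1] - t[0], 1e-9)
    t0 = t - t[0]

    def model(tt, f0, f1, k1, f2, k2):
        return f0 + f1 * np.exp(-k1 * tt) + f2 * np.exp(-k2 * tt)

    p0 = [mono.F0, 0.5 * mono.F1, 3.0 * k0, 0.5 * mono.F1, k0 / 3.0]
    try:
        popt, pcov = curve_fit(
            model, t0, y, p0=p0,
            sigma=_sigma(trace), absolute_sigma=trace.sd is not None,
            bounds=([-np.inf, -np.inf, 0.0, -np.inf, 0.0],
                    [np.inf, np.inf, np.inf, np.inf, np.inf]),
            maxfev=40000)
    except RuntimeError as err:
        raise FitError(f"biexponential fit failed: {err}") from err
    f0, f1, k1, f2, k2 = popt
    se = _stderr(pcov)
    if k1 < k2:  # enforce k1 > k2 convention
        k1, k2 = k2, k1
        f1, f2 = f2, f1
        se = se[[0, 3, 4, 1, 2]]
    resid = y - model(t0, f0, f1, k1, f2, k2)
    flags = []
    if k2 > 0 and k1 / k2 < collapse_ratio:
        flags.append("rate-collapse")
    return ExpFit(F0=float(f0), F1=float(f1), k1=float(k1),
                  F2=float(f2), k2=float(k2),
                  stderr={"F0": se[0], "F1": se[1], "k1": se[2],
                          "F2": se[3], "k2": se[4]},
                  rss=float(resid @ resid), flags=flags,
                  slower_phase_dominant=bool(abs(f2) > abs(f1)))


def consecutive_signal(t, F0: float, F1: float, k_q: float, k_o: float):
    """Signal of the consecutive two-step scheme.

    F(t) = F0 + (F1-F0) * k_q k_o/(k_q-k_o) * [-exp(-k_q t)/k_q
    + exp(-k_o t)/k_o]; the removable singularity at k_o = k_q is
    evaluated by its analytic limit (1 + k_q t) exp(-k_q t).
    """
    t = np.asarray(t, dtype=float)
    if abs(k_q - k_o) < 1e-9 * max(k_q, k_o, 1e-30):
        h = (1.0 + k_q * t) * np.exp(-k_q * t)
    else:
        h = (k_q * k_o / (k_q - k_o)
             * (-np.exp(-k_q * t) / k_q + np.exp(-k_o * t) / k_o))
    return F0 + (F1 - F0) * h


@dataclass
class ConsecutiveFit:
    """Downstream rate from the photoreversion-then-dissociation model."""

    F0: float
    F1: float
    k_q_fixed: float
    k_o: float
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    flags: list = field(default_factory=list)

    def predict(self, t) -> np.ndarray:
        return consecutive_signal(t, self.F0, self.F1,
                                  self.k_q_fixed, self.k_o)


def fit_consecutive(trace: TimeTrace, k_q_fixed: float,
                    identifiability_band: float = 0.05) -> ConsecutiveFit:
    """Fit the consecutive model with the photoreversion rate held fixed.

    When the fitted downstream rate lands within ``identifiability_band``
    of ``k_q_fixed`` the two steps are kinetically indistinguishable and
    the estimate is only a lower bound on the true speed; the result then
    carries an ``identifiability`` flag.
    """
    if k_q_fixed <= 0:
        raise FitError("k_q_fixed must be > 0")
    t, y = trace.time, trace.signal
    if t.size < 5:
        raise FitError("consecutive fit requires >= 5 points")
    t0 = t - t[0]

    def model(tt, f0, f1, ko):
        return consecutive_signal(tt, f0, f1, k_q_fixed, ko)

    p0 = [float(y[-1]), float(y[0]), max(3.0 / max(t0[-1], 1e-9), 1e-3)]
    try:
        popt, pcov = curve_fit(
            model, t0, y, p0=p0,
            sigma=_sigma(trace), absolute_sigma=trace.sd is not None,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"consecutive fit failed: {err}") from err
    resid = y - model(t0, *popt)
    se = _stderr(pcov)
    flags = []
    if abs(popt[2] - k_q_fixed) < identifiability_band * k_q_fixed:
        flags.append("identifiability")
    return ConsecutiveFit(F0=float(popt[0]), F1=float(popt[1]),
                          k_q_fixed=float(k_q_fixed), k_o=float(popt[2]),
                          stderr={"F0": se[0], "F1": se[1], "k_o": se[2]},
                          rss=float(resid @ resid), flags=flags)


def _wls_line(x: np.ndarray, y: np.ndarray, sd: np.ndarray | None):
    """Weighted straight-line fit returning (slope, intercept, covariance)."""
    w = np.ones_like(x) if sd is None else 1.0 / np.asarray(sd) ** 2
    X = np.column_stack([x, np.ones_like(x)])
    xtw = X.T * w
    cov = np.linalg.inv(xtw @ X)
    beta = cov @ (xtw @ y)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    if sd is None:
        cov = cov * float(resid @ resid) / dof
    return float(beta[0]), float(beta[1]), cov


@dataclass
class LinearKineticsFit:
    """Pseudo-first-order analysis: k_obs = k_a [receptor] + k_d.

    ``k_a_corrected`` divides the raw slope by the Pfr fraction present
    under red light, referring the bimolecular rate constant to the
    actually-binding Pfr population; K_d = k_d / k_a_corrected.
    """

    k_a: float
    k_d: float
    pfr_fraction_used: float
    k_a_corrected: float
    K_d: float
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def fit_pseudo_first_order(table: pd.DataFrame,
                           pfr_fraction: float = PFR_PHOTOEQUILIBRIUM_658
                           ) -> LinearKineticsFit:
    """Weighted linear regression of observable rate on concentration.

    ``table`` needs columns ``concentration_M`` and ``k_obs_s``; an
    optional ``sd`` column supplies per-point weights.  A slope that is
    non-positive or statistically indistinguishable from zero marks the
    association as unresolvable; the dissociation rate is then the
    (weighted) mean of the observed rates, mirroring the Pr-state analysis
    where the observable rate does not vary with concentration.
    """
    if not 0 < pfr_fraction <= 1:
        raise FitError("pfr_fraction must lie in (0, 1]")
    for col in ("concentration_M", "k_obs_s"):
        if col not in table.columns:
            raise FitError(f"table lacks required column {col!r}")
    if len(table) < 3:
        raise FitError("pseudo-first-order analysis requires >= 3 points")
    x = table["concentration_M"].to_numpy(dtype=float)
    y = table["k_obs_s"].to_numpy(dtype=float)
    sd = table["sd"].to_numpy(dtype=float) if "sd" in table.columns else None
    slope, intercept, cov = _wls_line(x, y, sd)
    se_slope, se_int = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    flags = []
    if intercept < 0:
        flags.append("negative-intercept")
    k_a, k_d = slope, intercept
    if slope <= 0 or slope < 2 * se_slope:
        flags.append("association-unresolved")
        w = np.ones_like(y) if sd is None else 1.0 / np.asarray(sd) ** 2
        k_d = float(np.average(y, weights=w))
    k_a_corr = k_a / pfr_fraction
    K_d = k_d / k_a_corr if k_a_corr > 0 else np.nan
    return LinearKineticsFit(
        k_a=k_a, k_d=k_d, pfr_fraction_used=pfr_fraction,
        k_a_corrected=k_a_corr, K_d=K_d,
        stderr={"k_a": se_slope, "k_d": se_int,
                "k_a_corrected": se_slope / pfr_fraction},
        flags=flags)


@dataclass
class IsothermFit:
    """Single-site binding isotherm result."""

    F0: float
    F1: float
    K_d: float
    pfr_fraction_used: float
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    flags: list = field(default_factory=list)


def fit_isotherm(table: pd.DataFrame,
                 pfr_fraction: float = PFR_PHOTOEQUILIBRIUM_658,
                 correct: bool = True) -> IsothermFit:
    """Fit F = F0 + (F1-F0) c/(c + K_d) to a titration table.

    When ``correct`` is true, total receptor concentrations are multiplied
    by the Pfr fraction before fitting, so that K_d refers to the binding-
    competent Pfr population (K_d_corrected ~ pfr_fraction * K_d_apparent).
    ``table`` needs columns ``concentration_M`` and ``signal``.
    """
    for col in ("concentration_M", "signal"):
        if col not in table.columns:
            raise FitError(f"table lacks required column {col!r}")
    if len(table) < 5:
        raise FitError("isotherm fit requires >= 5 concentrations")
    c = table["concentration_M"].to_numpy(dtype=float)
    y = table["signal"].to_numpy(dtype=float)
    sd = table["sd"].to_numpy(dtype=float) if "sd" in table.columns else None
    used = pfr_fraction if correct else 1.0
    if not 0 < used <= 1:
        raise FitError("pfr_fraction must lie in (0, 1]")
    ceff = c * used

    def model(cc, f0, f1, kd):
        return f0 + (f1 - f0) * cc / (cc + kd)

    nz = ceff[ceff > 0]
    p0 = [float(y[np.argmin(ceff)]), float(y[np.argmax(ceff)]),
          float(np.median(nz)) if nz.size else 1e-7]
    try:
        popt, pcov = curve_fit(
            model, ceff, y, p0=p0, sigma=sd,
            absolute_sigma=sd is not None,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"isotherm fit failed: {err}") from err
    resid = y - model(ceff, *popt)
    se = _stderr(pcov)
    flags = []
    if nz.size and not nz.min() <= popt[2] <= nz.max():
        flags.append("extrapolation")
    return IsothermFit(F0=float(popt[0]), F1=float(popt[1]),
                       K_d=float(popt[2]), pfr_fraction_used=used,
                       stderr={"F0": se[0], "F1": se[1], "K_d": se[2]},
                       rss=float(resid @ resid), flags=flags)


@dataclass
class ArrheniusFit:
    """Arrhenius parameters k = A exp(-E_A / R T)."""

    A: float
    E_A: float  # J mol^-1
    stderr: dict = field(default_factory=dict)
    method: str = "log-linear"


def fit_arrhenius(table: pd.DataFrame,
                  method: str = "log-linear") -> ArrheniusFit:
    """Fit rate constants versus absolute temperature to Arrhenius form.

    ``table`` needs columns ``T_K`` and ``k_s``.  The default works in log
    space (variance stabilising; ln k linear in 1/T); ``method='nonlinear'``
    fits k directly.
    """
    for col in ("T_K", "k_s"):
        if col not in table.columns:
            raise FitError(f"table lacks required column {col!r}")
    if len(table) < 3:
        raise FitError("Arrhenius fit requires >= 3 temperatures")
    T = table["T_K"].to_numpy(dtype=float)
    k = table["k_s"].to_numpy(dtype=float)
    if np.any(k <= 0) or np.any(T <= 0):
        raise FitError("rates and temperatures must be > 0")
    x = 1.0 / T
    slope, intercept, cov = _wls_line(x, np.log(k), None)
    E_A = -slope * R_GAS
    A = math.exp(intercept)
    se = {"E_A": math.sqrt(cov[0, 0]) * R_GAS,
          "A": A * math.sqrt(cov[1, 1])}
    if method == "log-linear":
        return ArrheniusFit(A=A, E_A=E_A, stderr=se, method=method)
    if method != "nonlinear":
        raise FitError(f"unknown Arrhenius method {method!r}")

    def model(TT, a, ea):
        return a * np.exp(-ea / (R_GAS * TT))

    popt, pcov = curve_fit(model, T, k, p0=[A, E_A], maxfev=20000)
    sevec = _stderr(pcov)
    return ArrheniusFit(A=float(popt[0]), E_A=float(popt[1]),
                        stderr={"A": sevec[0], "E_A": sevec[1]},
                        method=method)


@dataclass
class MeltFit:
    """Two-state thermal-unfolding parameters with linear baselines."""

    dH: float  # J mol^-1
    T_m: float  # K
    baseline_folded: tuple
    baseline_unfolded: tuple
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def T_m_celsius(self) -> float:
        return self.T_m - 273.15


def melt_signal(T, dH, T_m, a_f, b_f, a_u, b_u):
    """Boltzmann-weighted two-state CD signal with linear baselines.

    dG(T) = dH (1 - T/T_m); fraction unfolded = 1/(1 + exp(dG/RT)).
    """
    T = np.asarray(T, dtype=float)
    dG = dH * (1.0 - T / T_m)
    x = 1.0 / (1.0 + np.exp(np.clip(dG / (R_GAS * T), -500, 500)))
    return (a_f + b_f * T) * (1.0 - x) + (a_u + b_u * T) * x


def fit_two_state_melt(table: pd.DataFrame) -> MeltFit:
    """Fit a thermal melting curve to the two-state unfolding model.

    ``table`` needs ``signal`` and either ``T_K`` or ``T_C``.  The curve
    must span both the folded and unfolded baselines; a curve without a
    detectable transition is returned flagged rather than trusted.
    """
    if "signal" not in table.columns:
        raise FitError("table lacks required column 'signal'")
    if "T_K" in table.columns:
        T = table["T_K"].to_numpy(dtype=float)
    elif "T_C" in table.columns:
        T = table["T_C"].to_numpy(dtype=float) + 273.15
    else:
        raise FitError("table needs a T_K or T_C column")
    y = table["signal"].to_numpy(dtype=float)
    if T.size < 10:
        raise FitError("melt fit requires >= 10 temperatures")
    order = np.argsort(T)
    T, y = T[order], y[order]

    n_edge = max(3, T.size // 10)
    bf = np.polyfit(T[:n_edge], y[:n_edge], 1)
    bu = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
    lo = np.polyval(bf, T)
    hi = np.polyval(bu, T)
    denom = hi - lo
    span = float(np.median(np.abs(denom)))
    if span < 1e-9 * max(1.0, float(np.abs(y).max())):
        return MeltFit(dH=np.nan, T_m=np.nan,
                       baseline_folded=tuple(bf[::-1]),
                       baseline_unfolded=tuple(bu[::-1]),
                       flags=["no-transition"])
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.clip((y - lo) / denom, 0.0, 1.0)
    cross = np.nonzero(frac >= 0.5)[0]
    tm0 = float(T[cross[0]]) if cross.size else float(np.median(T))

    p0 = [3e5, tm0, bf[1], bf[0], bu[1], bu[0]]
    try:
        popt, pcov = curve_fit(
            melt_signal, T, y, p0=p0,
            bounds=([0.0, T.min(), -np.inf, -np.inf, -np.inf, -np.inf],
                    [np.inf, T.max(), np.inf, np.inf, np.inf, np.inf]),
            maxfev=40000)
    except RuntimeError as err:
        raise FitError(f"melt fit failed: {err}") from err
    resid = y - melt_signal(T, *popt)
    se = _stderr(pcov)
    return MeltFit(dH=float(popt[0]), T_m=float(popt[1]),
                   baseline_folded=(float(popt[2]), float(popt[3])),
                   baseline_unfolded=(float(popt[4]), float(popt[5])),
                   stderr={"dH": se[0], "T_m": se[1]},
                   rss=float(resid @ resid))


@dataclass
class GlobalFitResult:
    """Shared-parameter fit of the ODE model across light intensities.

    The free parameters are exactly the photoconversion coefficient (via
    the Pr->Pfr rate at the reference intensity), the three binding rate
    constants k_aFR, k_dFR, k_dR, and the two signal amplitudes; k_aR is
    pinned to zero and k_p:k_q to the spectroscopic photoequilibrium.
    """

    rates: RateConstants
    F0: float
    F1: float
    k_p_ref: float  # Pr->Pfr rate at the reference intensity (s^-1)
    ref_intensity: float
    rss: float
    rss_by_intensity: dict
    n_points: int
    success: bool
    model: str = "full"
    message: str = ""

    @property
    def k_aFR(self) -> float:
        return self.rates.k_aFR

    @property
    def k_dFR(self) -> float:
        return self.rates.k_dFR

    @property
    def k_dR(self) -> float:
        return self.rates.k_dR


# log-space box for the four rate parameters; generous physical range
# that also guards the integrator against overflow during line searches
_GLOBAL_BOUNDS_LOG = (
    (math.log(1e-4), math.log(1e3)),   # k_p at the reference intensity
    (math.log(1e1), math.log(1e9)),    # k_aFR
    (math.log(1e-6), math.log(1e3)),   # k_dFR
    (math.log(1e-6), math.log(1e3)),   # k_dR
)


def _global_rates(theta, ref_intensity, pfr_eq):
    th = np.clip(theta, [b[0] for b in _GLOBAL_BOUNDS_LOG],
                 [b[1] for b in _GLOBAL_BOUNDS_LOG])
    kp_coeff = math.exp(th[0]) / ref_intensity
    return RateConstants(k_p_coeff=kp_coeff,
                         k_q_coeff=kp_coeff * (1 - pfr_eq) / pfr_eq,
                         k_aR=0.0, k_aFR=math.exp(th[1]),
                         k_dFR=math.exp(th[2]), k_dR=math.exp(th[3]))


def _global_residuals(theta, traces, composition, light_duration,
                      ref_intensity, pfr_eq, complex_photoconverts,
                      ode_rtol):
    """Residuals over all traces with the two amplitudes profiled out.

    The FRET signal F0*[P]/P0 + F1*([RP]+[FRP])/P0 is linear in (F0, F1),
    so for any rate-parameter vector the optimal amplitudes follow from a
    2-column linear least-squares solve (variable projection); only the
    four rate parameters need nonlinear optimisation.
    """
    rates = _global_rates(theta, ref_intensity, pfr_eq)
    p0 = composition.P0_total
    basis_rows = []
    data = []
    for intensity, trace in traces.items():
        protocol = IlluminationProtocol.red_pulse(intensity, light_duration)
        traj = simulate(rates, protocol, composition, trace.time,
                        rtol=ode_rtol, atol=1e-16,
                        complex_photoconverts=complex_photoconverts,
                        check_conservation=False)
        basis_rows.append(np.column_stack([
            traj.P / p0, (traj.RP + traj.FRP) / p0]))
        data.append(trace.signal)
    A = np.vstack(basis_rows)
    y = np.concatenate(data)
    # amplitudes are physical signal levels: non-negative and of the same
    # order as the data, which excludes degenerate compensating solutions
    cap = 10.0 * float(np.max(np.abs(y)))
    sol = lsq_linear(A, y, bounds=(0.0, cap))
    amps = sol.x
    return A @ amps - y, rates, (float(amps[0]), float(amps[1]))


def global_fit_interaction(
    traces_by_intensity: dict,
    rates_init: RateConstants,
    composition: SystemComposition,
    light_duration: float = 20.0,
    ref_intensity: float = 69.0,
    pfr_photoequilibrium: float = PFR_PHOTOEQUILIBRIUM_658,
    model: str = "full",
    ode_rtol: float = 1e-7,
    nm_maxiter: int = 400,
) -> GlobalFitResult:
    """Simultaneous ODE fit of fluorescence traces at several intensities.

    Each trace records the PIF-reporter FRET signal during a constant-red
    pulse of ``light_duration`` seconds followed by darkness.  Photoconversion
    rates scale linearly with intensity, so a single Pr->Pfr rate at
    ``ref_intensity`` fixes all four light schedules.  Optimisation runs a
    Nelder-Mead warm start on the summed squares, then polishes with
    derivative-based least squares.  ``model='conventional'`` disables
    photoconversion of the bound complex (the reduced scheme that cannot
    reproduce the fluence-dependent attenuation).
    """
    if len(traces_by_intensity) < 2:
        raise FitError("global fit requires traces at >= 2 intensities")
    if model not in ("full", "conventional"):
        raise FitError(f"unknown model {model!r}")
    complex_photo = model == "full"

    kp0 = max(rates_init.k_p_coeff * ref_intensity, 1e-3)
    theta0 = np.array([
        math.log(kp0),
        math.log(max(rates_init.k_aFR, 1e2)),
        math.log(max(rates_init.k_dFR, 1e-4)),
        math.log(max(rates_init.k_dR, 1e-4)),
    ])

    def resid(theta):
        r, _, _ = _global_residuals(theta, traces_by_intensity, composition,
                                    light_duration, ref_intensity,
                                    pfr_photoequilibrium, complex_photo,
                                    ode_rtol)
        return r

    def ssr(theta):
        r = resid(theta)
        return float(r @ r)

    warm = minimize(ssr, theta0, method="Nelder-Mead",
                    options={"maxiter": nm_maxiter, "xatol": 1e-6,
                             "fatol": 1e-14, "adaptive": True})
    lo = [b[0] for b in _GLOBAL_BOUNDS_LOG]
    hi = [b[1] for b in _GLOBAL_BOUNDS_LOG]
    polish = least_squares(resid, np.clip(warm.x, lo, hi),
                           bounds=(lo, hi), method="trf",
                           xtol=1e-12, ftol=1e-12, max_nfev=400)
    theta = polish.x
    residuals, rates, amps = _global_residuals(
        theta, traces_by_intensity, composition, light_duration,
        ref_intensity, pfr_photoequilibrium, complex_photo, ode_rtol)
    rss_by = {}
    start = 0
    for intensity, trace in traces_by_intensity.items():
        n = len(trace)
        part = residuals[start:start + n]
        rss_by[intensity] = float(part @ part)
        start += n
    success = bool(polish.success or warm.success)
    return GlobalFitResult(
        rates=rates, F0=amps[0], F1=amps[1],
        k_p_ref=rates.k_p_coeff * ref_intensity,
        ref_intensity=ref_intensity,
        rss=float(residuals @ residuals), rss_by_intensity=rss_by,
        n_points=residuals.size, success=success, model=model,
        message="" if success else "optimizer did not converge; "
                                  "best-so-far parameters returned")


def fit_association_series(
    traces_by_concentration: dict,
    pfr_fraction: float = PFR_PHOTOEQUILIBRIUM_658,
    light_off_s: float = 0.5,
    settle_s: float = 1.0,
) -> LinearKineticsFit:
    """Pseudo-first-order analysis of shutter-pulse association traces.

    Each trace records the reporter signal around a brief red pulse ending
    at ``light_off_s``; the post-pulse decay is fitted monoexponentially
    and the observable rates are regressed on receptor concentration.
    The first ``settle_s`` seconds after light-off are discarded so the
    fast transient from Pr-state complexes formed during the pulse (which
    dissociate at k_dR, lifetime well under a second) does not bias the
    slow association phase.
    """
    rows = []
    for conc, trace in sorted(traces_by_concentration.items()):
        window = trace.window(t_min=light_off_s + settle_s)
        fit = fit_monoexponential(window)
        rows.append({"concentration_M": conc, "k_obs_s": fit.k1,
                     "sd": fit.stderr.get("k1", np.nan)})
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table["sd"])) or np.any(table["sd"] <= 0):
        table = table.drop(columns="sd")
    return fit_pseudo_first_order(table, pfr_fraction)
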