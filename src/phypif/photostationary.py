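"""Closed-form photostationary state and dose-response scan engine.

Under constant light the network relaxes to a unique steady state.  Setting
the time derivatives to zero and imposing receptor and PIF mass
conservation reduces the problem to a single scalar unknown, the free PIF
concentration [P]: for fixed [P] the four receptor species obey a *linear*
balance, and the PIF conservation residual f([P]) = [P] + [RP] + [FRP] - P0
is strictly increasing on [0, P0].  The root of f (equivalent to the real
admissible root of the cubic obtained by eliminating the receptor species
algebraically) is bracketed and found to machine precision.  This exact
reduction is derived directly from the rate equations rather than from a
transcribed polynomial, and the numerical ODE terminal state serves as the
independent correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    IlluminationProtocol,
    ModelError,
    RateConstants,
    SpeciesState,
    SystemComposition,
    intensity_to_rates,
    photostationary_pfr_fraction,
)

__all__ = ["solve_photostationary", "DoseResponseCurve", "dose_response",
           "ScanSpec", "scan_panel"]


def _receptor_steady(k_p: float, kq_tot: float, rates: RateConstants,
                     R0: float, P: float) -> np.ndarray:
    """Steady receptor partition [R, FR, RP, FRP] at fixed free PIF P.

    The four balance equations are linearly dependent (receptor mass is
    conserved), so one is replaced by the conservation constraint.
    """
    kaR, kdR = rates.k_aR, rates.k_dR
    kaFR, kdFR = rates.k_aFR, rates.k_dFR
    a = np.array([
        [-(k_p + kaR * P), kq_tot, kdR, 0.0],
        [k_p, -(kq_tot + kaFR * P), 0.0, kdFR],
        [kaR * P, 0.0, -(k_p + kdR), kq_tot],
        [1.0, 1.0, 1.0, 1.0],
    ])
    b = np.array([0.0, 0.0, 0.0, R0])
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(a, b, rcond=None)[0]
    return x


def solve_photostationary(
    rates: RateConstants,
    composition: SystemComposition,
    intensity: float,
    channel: str = "red658",
) -> SpeciesState:
    """Species concentrations at photostationary state under constant light.

    Requires a driving flux: ``intensity > 0`` or ``k_rec > 0``; otherwise
    the network has no unique steady state.
    """
    k_p, k_q = intensity_to_rates((channel, intensity), rates)
    kq_tot = k_q + rates.k_rec
    if k_p + kq_tot <= 0:
        raise ModelError(
            "no unique photostationary state: need light or k_rec > 0")
    R0, P0 = composition.R0_total, composition.P0_total

    if P0 == 0 or R0 == 0:
        frac = photostationary_pfr_fraction(k_p, k_q, rates.k_rec)
        return SpeciesState(R=(1 - frac) * R0, FR=frac * R0,
                            RP=0.0, FRP=0.0, P=P0)

    def residual(P: float) -> float:
        r, fr, rp, frp = _receptor_steady(k_p, kq_tot, rates, R0, P)
        return P + rp + frp - P0

    lo, hi = 0.0, P0
    f_lo = residual(lo)
    if f_lo >= 0:  # no binding capacity engaged; free PIF is everything
        P_star = P0 if abs(f_lo) < 1e-12 * P0 else lo
    else:
        P_star = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16)
    r, fr, rp, frp = _receptor_steady(k_p, kq_tot, rates, R0, P_star)
    y = np.clip([r, fr, rp, frp, P_star], 0.0, None)
    state = SpeciesState.from_array(y)
    # internal-consistency guard: a coefficient bug would break conservation
    state.validate(composition, rtol=1e-8)
    return state


@dataclass
class DoseResponseCurve:
    """Bound PIF fraction versus light intensity on a log-spaced grid.

    ``attenuation_onset`` is the lowest intensity above the peak at which
    the bound fraction has fallen ``attenuation_threshold`` below the peak
    (None when no such attenuation occurs on the grid).
    """

    intensities: np.ndarray  # mW cm^-2, strictly increasing
    bound_fraction: np.ndarray
    scan_label: str = ""
    scan_value: float = 1.0
    attenuation_threshold: float = 0.10
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        if np.any(np.diff(self.intensities) <= 0):
            raise ModelError("intensity grid must be strictly increasing")
        if np.any((self.bound_fraction < -1e-9)
                  | (self.bound_fraction > 1 + 1e-9)):
            raise ModelError("bound fraction must lie in [0, 1]")

    @property
    def low_intensity_plateau(self) -> float:
        return float(self.bound_fraction[0])

    @property
    def peak_intensity(self) -> float:
        return float(self.intensities[int(np.argmax(self.bound_fraction))])

    @property
    def peak_height(self) -> float:
        return float(np.max(self.bound_fraction))

    @property
    def attenuation_onset(self) -> float | None:
        i_peak = int(np.argmax(self.bound_fraction))
        cutoff = (1.0 - self.attenuation_threshold) * self.peak_height
        after = np.nonzero(self.bound_fraction[i_peak:] < cutoff)[0]
        if after.size == 0:
            return None
        return float(self.intensities[i_peak + after[0]])

    @property
    def attenuation_magnitude(self) -> float:
        """Relative drop from the peak to the highest-intensity point."""
        peak = self.peak_height
        if peak <= 0:
            return 0.0
        return float((peak - self.bound_fraction[-1]) / peak)


def dose_response(
    rates: RateConstants,
    composition: SystemComposition,
    intensity_grid,
    channel: str = "red658",
    attenuation_threshold: float = 0.10,
) -> DoseResponseCurve:
    """Photostationary bound fraction across a light-intensity grid."""
    grid = np.asarray(intensity_grid, dtype=float)
    if grid.size < 3 or np.any(grid <= 0):
        raise ModelError("intensity grid must be positive with >= 3 points")
    bound = np.empty_like(grid)
    for i, inten in enumerate(grid):
        try:
            state = solve_photostationary(rates, composition, inten, channel)
        except ModelError as err:
            raise ModelError(
                f"steady-state solve failed at {inten:g} mW cm^-2: {err}"
            ) from err
        bound[i] = state.bound_fraction()
    return DoseResponseCurve(grid, bound,
                             attenuation_threshold=attenuation_threshold)


#: Scan dimensions and how a multiplier maps onto the parameters.
SCAN_DIMENSIONS = ("k_rec", "kinetics_fr", "k_dFR", "k_dR",
                   "kp_kq_ratio", "R0_total")


@dataclass(frozen=True)
class ScanSpec:
    """One-dimensional parameter scan for a dose-response panel family.

    ``dimension`` names the scanned quantity; ``values`` are multipliers
    applied to the reference parameters, except for ``kp_kq_ratio`` where
    each value *is* the k_p:k_q ratio itself (``inf`` means k_q = 0, i.e.
    light that drives only the forward photoconversion).
    """

    dimension: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dimension not in SCAN_DIMENSIONS:
            raise ModelError(
                f"unknown scan dimension {self.dimension!r}; "
                f"choose one of {SCAN_DIMENSIONS}")
        if len(self.values) == 0:
            raise ModelError("scan requires at least one value")


def _apply_scan(rates: RateConstants, composition: SystemComposition,
                dimension: str, value: float):
    if dimension == "k_rec":
        return rates.with_(k_rec=rates.k_rec * value), composition
    if dimension == "kinetics_fr":
        return rates.with_(k_aFR=rates.k_aFR * value,
                           k_dFR=rates.k_dFR * value), composition
    if dimension == "k_dFR":
        return rates.with_(k_dFR=rates.k_dFR * value), composition
    if dimension == "k_dR":
        return rates.with_(k_dR=rates.k_dR * value), composition
    if dimension == "R0_total":
        comp = SystemComposition(
            R0_total=composition.R0_total * value,
            P0_total=composition.P0_total,
            pfr_fraction_0=composition.pfr_fraction_0,
            bound_rp_fraction_0=composition.bound_rp_fraction_0,
            bound_frp_fraction_0=composition.bound_frp_fraction_0,
        )
        return rates, comp
    # kp_kq_ratio: redistribute the total photoconversion coefficient
    total = rates.k_p_coeff + rates.k_q_coeff
    if np.isinf(value):
        kp_c, kq_c = total, 0.0
    else:
        if value < 0:
            raise ModelError("k_p/k_q ratio must be >= 0")
        kp_c = total * value / (1.0 + value)
        kq_c = total / (1.0 + value)
    return rates.with_(k_p_coeff=kp_c, k_q_coeff=kq_c), composition


def scan_panel(
    rates: RateConstants,
    composition: SystemComposition,
    scan: ScanSpec,
    intensity_grid,
    channel: str = "red658",
    attenuation_threshold: float = 0.10,
) -> list[DoseResponseCurve]:
    """One dose-response curve per scan value (a Fig.-panel family)."""
    curves = []
    for value in scan.values:
        r, c = _apply_scan(rates, composition, scan.dimension, value)
        curve = dose_response(r, c, intensity_grid, channel,
                              attenuation_threshold)
        curve.scan_label = scan.dimension
        curve.scan_value = float(value)
        curves.append(curve)
    return curves
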