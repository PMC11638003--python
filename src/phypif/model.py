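"""Reaction network of phytochrome photoconversion coupled to PIF binding.

The model tracks five species: free phytochrome in its red-absorbing (Pr)
and far-red-absorbing (Pfr) states, the corresponding complexes with a
phytochrome-interacting factor (PIF), and free PIF::

    Pr  <--k_p/k_q-->  Pfr          (light-driven, first order)
    Pfr + P  <--k_aFR/k_dFR-->  Pfr:P
    Pr  + P  <--k_aR/k_dR  -->  Pr:P
    Pr:P <--k_p/k_q--> Pfr:P        (complex photoconverts at the same rates)

Photoconversion rates scale linearly with the applied light intensity; the
thermal Pfr->Pr dark reversion ``k_rec`` adds to the Pfr->Pr flux
independently of light.  Concentrations are molar, time is in seconds,
light intensity in mW cm^-2, temperature in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants as _const
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "LightSegment",
    "IlluminationProtocol",
    "SystemComposition",
    "SpeciesState",
    "Trajectory",
    "ObservableMap",
    "TimeTrace",
    "intensity_to_rates",
    "photon_flux_to_irradiance",
    "irradiance_to_photon_flux",
    "photostationary_pfr_fraction",
    "simulate",
    "terminal_state",
    "observe",
]

#: Pfr fraction of the photosensory core module at photostationary state
#: under 658-nm light (spectroscopically determined, intensity independent).
PFR_PHOTOEQUILIBRIUM_658 = 0.73

#: Reference intensity of the 658-nm LED at maximum power (mW cm^-2).
RED_REFERENCE_INTENSITY = 69.0

#: Total Pr<->Pfr equilibration rate k_p + k_q at the reference red
#: intensity, from the shutter-controlled fluorescence calibration (s^-1).
RED_TOTAL_RATE_FLUORESCENCE = 10.0

#: Alternative calibration from absorbance photoconversion kinetics (s^-1 at
#: 69 mW cm^-2); differs from the fluorescence value because of the
#: different illumination geometry of the spectrophotometer.
RED_TOTAL_RATE_ABSORBANCE = 5.2

#: Far-red (733 nm) Pfr->Pr photoreversion rate at the maximum LED
#: intensity of 42 mW cm^-2 (s^-1).
FARRED_RATE = 2.4
FARRED_REFERENCE_INTENSITY = 42.0


class ModelError(ValueError):
    """Raised on invalid model input or a failed integration."""


def _check_nonneg(name: str, value: float) -> None:
    if value < 0 or not math.isfinite(value):
        raise ModelError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the reaction network.

    ``k_p_coeff`` and ``k_q_coeff`` are per-intensity photoconversion
    coefficients for 658-nm light (s^-1 per mW cm^-2); ``k_q733_coeff``
    plays the same role for the 733-nm channel, which drives only the
    Pfr->Pr direction.  Binding rate constants are bimolecular
    (``k_aR``, ``k_aFR``; M^-1 s^-1) or unimolecular (``k_dR``, ``k_dFR``;
    s^-1).  ``k_rec`` is the thermal dark reversion rate (s^-1); it is
    negligible on experiment timescales (time constant > 200 h at 15 C)
    and defaults to 0.  ``k_aR`` defaults to 0 because the Pr state binds
    PIF only weakly.
    """

    k_p_coeff: float = PFR_PHOTOEQUILIBRIUM_658 * RED_TOTAL_RATE_FLUORESCENCE / RED_REFERENCE_INTENSITY
    k_q_coeff: float = (1 - PFR_PHOTOEQUILIBRIUM_658) * RED_TOTAL_RATE_FLUORESCENCE / RED_REFERENCE_INTENSITY
    k_aR: float = 0.0
    k_dR: float = 0.0
    k_aFR: float = 0.0
    k_dFR: float = 0.0
    k_q733_coeff: float = FARRED_RATE / FARRED_REFERENCE_INTENSITY
    k_rec: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_p_coeff", "k_q_coeff", "k_aR", "k_dR", "k_aFR",
                     "k_dFR", "k_q733_coeff", "k_rec"):
            _check_nonneg(name, getattr(self, name))

    @classmethod
    def from_calibration(
        cls,
        total_rate: float = RED_TOTAL_RATE_FLUORESCENCE,
        at_intensity: float = RED_REFERENCE_INTENSITY,
        pfr_photoequilibrium: float = PFR_PHOTOEQUILIBRIUM_658,
        **kinetics: float,
    ) -> "RateConstants":
        """Build rate constants from a red-light calibration.

        ``total_rate`` is the observed single-exponential equilibration
        rate k_p + k_q at ``at_intensity``; the split between k_p and k_q
        is fixed by the photostationary Pfr fraction.  Remaining binding
        rate constants are passed through as keyword arguments.
        """
        if total_rate <= 0 or at_intensity <= 0:
            raise ModelError("calibration rate and intensity must be > 0")
        if not 0 < pfr_photoequilibrium < 1:
            raise ModelError("pfr_photoequilibrium must lie in (0, 1)")
        coeff = total_rate / at_intensity
        return cls(
            k_p_coeff=pfr_photoequilibrium * coeff,
            k_q_coeff=(1 - pfr_photoequilibrium) * coeff,
            **kinetics,
        )

    def with_(self, **changes: float) -> "RateConstants":
        return replace(self, **changes)


@dataclass(frozen=True)
class LightSegment:
    """One piecewise-constant illumination interval."""

    t_start: float
    duration: float
    channel: str  # 'red658' | 'farred733' | 'dark'
    intensity: float  # mW cm^-2

    def __post_init__(self) -> None:
        if self.channel not in ("red658", "farred733", "dark"):
            raise ModelError(f"unknown light channel {self.channel!r}")
        if self.duration <= 0:
            raise ModelError("segment duration must be > 0")
        if self.intensity < 0:
            raise ModelError("segment intensity must be >= 0")
        if self.channel == "dark" and self.intensity != 0:
            raise ModelError("dark segments must have intensity 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class IlluminationProtocol:
    """Ordered, non-overlapping light segments; gaps count as darkness."""

    segments: tuple[LightSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ModelError(
                    f"overlapping segments at t={b.t_start:g} s")

    @classmethod
    def constant(cls, channel: str, intensity: float, duration: float,
                 t_start: float = 0.0) -> "IlluminationProtocol":
        return cls((LightSegment(t_start, duration, channel, intensity),))

    @classmethod
    def red_pulse(cls, intensity: float, duration: float,
                  t_start: float = 0.0) -> "IlluminationProtocol":
        """A single red pulse; everything after is darkness."""
        return cls.constant("red658", intensity, duration, t_start)

    def breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for s in self.segments:
            pts.add(s.t_start)
            pts.add(s.t_end)
        return sorted(pts)

    def segment_at(self, t: float) -> LightSegment | None:
        for s in self.segments:
            if s.t_start <= t < s.t_end:
                return s
        return None


def intensity_to_rates(segment, rates: RateConstants) -> tuple[float, float]:
    """Photochemical (k_p, k_q) in s^-1 for one protocol segment.

    The thermal reversion ``k_rec`` is *not* included here; the ODE adds
    it to the Pfr->Pr flux regardless of illumination.  ``segment`` may be
    a :class:`LightSegment` or a ``(channel, intensity)`` pair.
    """
    if segment is None:
        return 0.0, 0.0
    if isinstance(segment, LightSegment):
        channel, intensity = segment.channel, segment.intensity
    else:
        channel, intensity = segment
    if intensity < 0:
        raise ModelError("intensity must be >= 0")
    if channel == "dark":
        return 0.0, 0.0
    if channel == "red658":
        return rates.k_p_coeff * intensity, rates.k_q_coeff * intensity
    if channel == "farred733":
        return 0.0, rates.k_q733_coeff * intensity
    raise ModelError(f"unknown light channel {channel!r}")


def photon_flux_to_irradiance(flux_uE: float, wavelength_nm: float) -> float:
    """Convert a photon flux density (uE s^-1 m^-2) to mW cm^-2.

    One microeinstein is one micromole of photons; the energy per mole is
    N_A h c / lambda.
    """
    if wavelength_nm <= 0:
        raise ModelError("wavelength must be > 0")
    if flux_uE < 0:
        raise ModelError("photon flux must be >= 0")
    joule_per_mol = _const.N_A * _const.h * _const.c / (wavelength_nm * 1e-9)
    w_per_m2 = flux_uE * 1e-6 * joule_per_mol
    return w_per_m2 * 0.1  # W m^-2 -> mW cm^-2


def irradiance_to_photon_flux(irradiance_mW_cm2: float,
                              wavelength_nm: float) -> float:
    """Inverse of :func:`photon_flux_to_irradiance`."""
    if wavelength_nm <= 0:
        raise ModelError("wavelength must be > 0")
    if irradiance_mW_cm2 < 0:
        raise ModelError("irradiance must be >= 0")
    joule_per_mol = _const.N_A * _const.h * _const.c / (wavelength_nm * 1e-9)
    return irradiance_mW_cm2 / 0.1 / (1e-6 * joule_per_mol)


def photostationary_pfr_fraction(k_p: float, k_q: float,
                                 k_rec: float = 0.0) -> float:
    """Pfr fraction of free receptor at photostationary state.

    The two-state photoequilibrium balance gives k_p / (k_p + k_q + k_rec);
    with ``k_rec = 0`` the fraction depends only on the k_p:k_q ratio and
    is therefore independent of light intensity.
    """
    total = k_p + k_q + k_rec
    if total <= 0:
        raise ModelError("k_p + k_q + k_rec must be > 0")
    return k_p / total


@dataclass(frozen=True)
class SystemComposition:
    """Total concentrations and the initial partitioning of the system.

    ``pfr_fraction_0`` applies to the receptor not initially in complex;
    ``bound_rp_fraction_0``/``bound_frp_fraction_0`` are fractions of the
    total PIF initially bound as Pr:P and Pfr:P, respectively.
    """

    R0_total: float  # M
    P0_total: float  # M
    pfr_fraction_0: float = 0.0
    bound_rp_fraction_0: float = 0.0
    bound_frp_fraction_0: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg("R0_total", self.R0_total)
        _check_nonneg("P0_total", self.P0_total)
        for name in ("pfr_fraction_0", "bound_rp_fraction_0",
                     "bound_frp_fraction_0"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ModelError(f"{name} must lie in [0, 1]")
        if self.bound_rp_fraction_0 + self.bound_frp_fraction_0 > 1:
            raise ModelError("initial bound fractions exceed total PIF")
        rp = self.bound_rp_fraction_0 * self.P0_total
        frp = self.bound_frp_fraction_0 * self.P0_total
        if rp + frp > self.R0_total * (1 + 1e-12):
            raise ModelError("initial complexes exceed total receptor")

    def initial_state(self) -> "SpeciesState":
        rp = self.bound_rp_fraction_0 * self.P0_total
        frp = self.bound_frp_fraction_0 * self.P0_total
        free_r = self.R0_total - rp - frp
        return SpeciesState(
            R=(1 - self.pfr_fraction_0) * free_r,
            FR=self.pfr_fraction_0 * free_r,
            RP=rp,
            FRP=frp,
            P=self.P0_total - rp - frp,
        )


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (M) of the five species at one instant."""

    R: float
    FR: float
    RP: float
    FRP: float
    P: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.FR, self.RP, self.FRP, self.P])

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(*(float(v) for v in y))

    @property
    def receptor_total(self) -> float:
        return self.R + self.FR + self.RP + self.FRP

    @property
    def pif_total(self) -> float:
        return self.P + self.RP + self.FRP

    @property
    def pfr_fraction(self) -> float:
        """Pfr fraction over all receptor (free + complexed)."""
        return (self.FR + self.FRP) / self.receptor_total

    def bound_fraction(self) -> float:
        """Fraction of total PIF in complex."""
        total = self.pif_total
        if total == 0:
            raise ModelError("bound fraction undefined for P0_total = 0")
        return (self.RP + self.FRP) / total

    def validate(self, composition: SystemComposition,
                 rtol: float = 1e-6) -> None:
        scale = max(composition.R0_total, composition.P0_total, 1e-300)
        if min(self.R, self.FR, self.RP, self.FRP, self.P) < -rtol * scale:
            raise ModelError("negative concentration in species state")
        if abs(self.receptor_total - composition.R0_total) > rtol * max(
                composition.R0_total, 1e-300):
            raise ModelError("receptor mass conservation violated")
        if abs(self.pif_total - composition.P0_total) > rtol * max(
                composition.P0_total, 1e-300):
            raise ModelError("PIF mass conservation violated")


@dataclass
class Trajectory:
    """Species concentrations over a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 5): columns R, FR, RP, FRP, P
    composition: SystemComposition
    protocol: IlluminationProtocol

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ModelError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, 5):
            raise ModelError("state array shape mismatch")

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def FR(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def RP(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def FRP(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 4]

    def bound_fraction(self) -> np.ndarray:
        if self.composition.P0_total == 0:
            raise ModelError("bound fraction undefined for P0_total = 0")
        return (self.RP + self.FRP) / self.composition.P0_total

    def state_at(self, index: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[index])

    def final_state(self) -> SpeciesState:
        return self.state_at(-1)


def _rhs_factory(k_p: float, k_q: float, rates: RateConstants,
                 complex_photoconverts: bool = True):
    kq_tot = k_q + rates.k_rec
    kaR, kdR = rates.k_aR, rates.k_dR
    kaFR, kdFR = rates.k_aFR, rates.k_dFR
    # optionally freeze photoconversion inside the complex ("conventional"
    # reduced model used as a foil in global fitting)
    kp_c = k_p if complex_photoconverts else 0.0
    kq_c = kq_tot if complex_photoconverts else rates.k_rec

    def rhs(t, y):
        r, fr, rp, frp, p = y
        assoc_r = kaR * r * p
        assoc_fr = kaFR * fr * p
        return (
            -k_p * r - assoc_r + kq_tot * fr + kdR * rp,
            -kq_tot * fr - assoc_fr + k_p * r + kdFR * frp,
            -kp_c * rp - kdR * rp + kq_c * frp + assoc_r,
            -kq_c * frp - kdFR * frp + kp_c * rp + assoc_fr,
            -assoc_r - assoc_fr + kdR * rp + kdFR * frp,
        )

    return rhs


def simulate(
    rates: RateConstants,
    protocol: IlluminationProtocol,
    composition: SystemComposition,
    time_grid,
    rtol: float = 1e-8,
    atol: float = 1e-16,
    complex_photoconverts: bool = True,
    check_conservation: bool = True,
) -> Trajectory:
    """Integrate the reaction network over ``time_grid``.

    The integration is carried out piecewise so that every change of the
    photoconversion rates falls on an integrator restart; within each
    piece a stiff-capable solver (LSODA) is used.  Mass conservation is
    verified at every output point.
    """
    times = np.asarray(time_grid, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ModelError("time grid must be 1-D and strictly increasing")

    pieces = sorted({times[0], times[-1]}
                    | {t for t in protocol.breakpoints()
                       if times[0] < t < times[-1]})
    y = composition.initial_state().as_array()
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    for a, b in zip(pieces, pieces[1:]):
        mid = 0.5 * (a + b)
        k_p, k_q = intensity_to_rates(protocol.segment_at(mid), rates)
        rhs = _rhs_factory(k_p, k_q, rates, complex_photoconverts)
        mask = (times >= a) & (times <= b)
        t_eval = np.unique(np.concatenate(([a], times[mask], [b])))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise ModelError(
                f"ODE integration failed on segment [{a:g}, {b:g}] s: "
                f"{sol.message}")
        keep = np.isin(sol.t, times[mask])
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep].T)
        y = sol.y[:, -1]

    t_all = np.concatenate(out_t)
    y_all = np.concatenate(out_y)
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = np.clip(y_all[idx], 0.0, None)
    traj = Trajectory(t_all, y_all, composition, protocol)
    if check_conservation:
        for i in (0, y_all.shape[0] // 2, -1):
            traj.state_at(i).validate(composition)
    return traj


def terminal_state(
    rates: RateConstants,
    composition: SystemComposition,
    intensity: float,
    channel: str = "red658",
    rtol: float = 1e-10,
    steady_rtol: float = 1e-9,
    max_chunks: int = 48,
) -> SpeciesState:
    """Long-time limit of the network under constant light.

    Integrates in chunks of doubling duration until the state stops
    changing; serves as the numerical oracle for the closed-form
    photostationary solution.
    """
    k_p, k_q = intensity_to_rates((channel, intensity), rates)
    if k_p + k_q + rates.k_rec <= 0:
        raise ModelError("no photostationary state without light or k_rec")
    scale = max(composition.R0_total, composition.P0_total)
    if scale == 0:
        return composition.initial_state()
    rhs = _rhs_factory(k_p, k_q, rates)
    y = composition.initial_state().as_array()
    fast = max(k_p + k_q + rates.k_rec,
               rates.k_aFR * scale + rates.k_dFR, rates.k_dR, 1e-6)
    t_chunk = 1.0 / fast
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, t_chunk), y, method="LSODA",
                        rtol=rtol, atol=1e-20)
        if not sol.success:
            raise ModelError(f"steady-state integration failed: {sol.message}")
        y_new = sol.y[:, -1]
        if np.max(np.abs(y_new - y)) < steady_rtol * scale:
            return SpeciesState.from_array(np.clip(y_new, 0.0, None))
        y = y_new
        t_chunk *= 2.0
    raise ModelError("steady state not reached within chunk budget")


@dataclass(frozen=True)
class ObservableMap:
    """Affine map from species concentrations to a measured signal.

    Channels:

    * ``fret`` -- PIF-borne reporter fluorescence, quenched on binding:
      signal = F0*[P]/P0 + F1*([RP]+[FRP])/P0 with F1 < F0.
    * ``pr_fluorescence`` -- weak Pr-state receptor fluorescence:
      amplitude*([R]+[RP])/R0 + offset.
    * ``a715`` -- Pfr absorbance band: amplitude*([FR]+[FRP])/R0 + offset.
    """

    channel: str = "fret"
    F0: float = 1.0
    F1: float = 0.86
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in ("fret", "pr_fluorescence", "a715"):
            raise ModelError(f"unknown observable channel {self.channel!r}")
        if self.channel == "fret" and not self.F1 < self.F0:
            raise ModelError("FRET channel requires F1 < F0 (quenching)")


@dataclass
class TimeTrace:
    """A (time, signal) series, the universal measurement record."""

    time: np.ndarray
    signal: np.ndarray
    sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ModelError("time and signal must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ModelError("trace times must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.time.shape:
                raise ModelError("sd must match time shape")

    def __len__(self) -> int:
        return self.time.size

    def window(self, t_min: float = -np.inf,
               t_max: float = np.inf) -> "TimeTrace":
        m = (self.time >= t_min) & (self.time <= t_max)
        return TimeTrace(self.time[m], self.signal[m],
                         None if self.sd is None else self.sd[m],
                         dict(self.meta))


def observe(trajectory: Trajectory, omap: ObservableMap) -> TimeTrace:
    """Project a species trajectory onto a measurement channel."""
    comp = trajectory.composition
    if omap.channel == "fret":
        if comp.P0_total == 0:
            raise ModelError("FRET signal undefined for P0_total = 0")
        bound = (trajectory.RP + trajectory.FRP) / comp.P0_total
        sig = omap.F0 * trajectory.P / comp.P0_total + omap.F1 * bound
    elif omap.channel == "pr_fluorescence":
        if comp.R0_total == 0:
            raise ModelError("Pr fluorescence undefined for R0_total = 0")
        frac = (trajectory.R + trajectory.RP) / comp.R0_total
        sig = omap.amplitude * frac + omap.offset
    else:  # a715
        if comp.R0_total == 0:
            raise ModelError("absorbance signal undefined for R0_total = 0")
        frac = (trajectory.FR + trajectory.FRP) / comp.R0_total
        sig = omap.amplitude * frac + omap.offset
    return TimeTrace(trajectory.times.copy(), sig,
                     meta={"channel": omap.channel})
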