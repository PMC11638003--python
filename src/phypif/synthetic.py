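"""Seeded generators for every measurement type the estimators consume.

Each generator produces data from the same forward model its estimator
assumes (or, for association traces, from the full ODE model), with
additive Gaussian noise scaled to the signal span.  Truth parameters
travel in a separate metadata dictionary (and sidecar file on disk), never
inside the data table itself, so estimators cannot cheat.  Presets carry
the measured interaction parameters of the phytochrome B photosensory
core module (PCM) with the PIF3/PIF6 variants at 15 C, their Arrhenius
activation energies, and the extended receptor construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import consecutive_signal, melt_signal, R_GAS
from .hydrodynamics import fcs_model
from .model import (
    FARRED_RATE,
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

__all__ = ["InteractionPreset", "PRESETS", "PHOTOCONVERSION_RATES_ABS",
           "PHOTOCONVERSION_RATES_FLUOR", "GeneratorSpec", "SyntheticDataset",
           "generate", "make_benchmark_suite"]


@dataclass(frozen=True)
class InteractionPreset:
    """Measured interaction parameters for one receptor:PIF pair at 15 C."""

    name: str
    k_aFR: float        # M^-1 s^-1, corrected for the Pfr fraction
    k_dFR: float        # s^-1
    k_dR: float         # s^-1
    E_A_assoc: float    # J mol^-1
    E_A_dissoc: float   # J mol^-1
    pfr_fraction: float  # photostationary Pfr fraction under 658-nm light

    @property
    def K_d(self) -> float:
        """Dissociation constant k_dFR / k_aFR (M)."""
        return self.k_dFR / self.k_aFR

    def rate_constants(self, **overrides) -> RateConstants:
        kwargs = dict(k_aFR=self.k_aFR, k_dFR=self.k_dFR, k_dR=self.k_dR,
                      k_aR=0.0)
        kwargs.update(overrides)
        return RateConstants.from_calibration(
            pfr_photoequilibrium=self.pfr_fraction, **kwargs)


#: Interaction parameters of the PCM with the PIF variants at 15 C, plus
#: the extended receptor construct (residues 1-982; lower Pfr fraction and
#: markedly slower association).
PRESETS: dict[str, InteractionPreset] = {
    "P6A": InteractionPreset("P6A", 6.1e5, 0.11, 2.5, 1.2e4, 7.1e4,
                             PFR_PHOTOEQUILIBRIUM_658),
    "PIF6": InteractionPreset("PIF6", 5.2e5, 0.07, 0.26, 1.1e4, 7.2e4,
                              PFR_PHOTOEQUILIBRIUM_658),
    "P3A": InteractionPreset("P3A", 3.1e5, 0.10, 1.9, 2.5e4, 4.7e4,
                             PFR_PHOTOEQUILIBRIUM_658),
    "PIF3": InteractionPreset("PIF3", 4.3e5, 0.13, 1.6, 3.1e4, 5.3e4,
                              PFR_PHOTOEQUILIBRIUM_658),
    "PhyB-982": InteractionPreset("PhyB-982", 9.0e4, 0.095, 2.2,
                                  2.3e4, 7.5e4, 0.55),
}

#: Single-exponential Pr->Pfr photoconversion rates (s^-1) versus red
#: intensity (mW cm^-2): absorbance-monitored and fluorescence-monitored
#: calibrations (the instruments differ in illumination geometry).
PHOTOCONVERSION_RATES_ABS = {1.0: 0.19, 10.0: 1.3, 30.0: 2.5, 69.0: 5.2}
PHOTOCONVERSION_RATES_FLUOR = {1.0: 0.25, 10.0: 1.6, 30.0: 4.2, 69.0: 6.2}

#: Photoreversion rates (s^-1) held fixed in consecutive-model fits, from
#: far-red fluorescence measurements of the PCM and the extended construct.
KQ_FIXED_PCM = 1.94
KQ_FIXED_EXTENDED = 2.75

GENERATOR_KINDS = ("association_trace", "dissociation_trace",
                   "photoconversion_trace", "titration", "k_vs_T",
                   "melt_curve", "fcs_curve")


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic data set.

    ``noise_sd`` is the Gaussian noise standard deviation as a fraction of
    the noiseless signal span; ``params`` override the kind-specific
    defaults (time grids, concentrations, truth values).  The seed fully
    determines the output.
    """

    kind: str
    preset: str = "P6A"
    noise_sd: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ModelError(f"unknown generator kind {self.kind!r}; "
                             f"choose from {GENERATOR_KINDS}")
        if self.preset not in PRESETS:
            raise ModelError(f"unknown preset {self.preset!r}")
        if self.noise_sd < 0:
            raise ModelError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated data plus the truth parameters that produced it."""

    data: object  # TimeTrace or pandas.DataFrame
    truth: dict


def _add_noise(rng: np.random.Generator, y: np.ndarray,
               noise_sd: float) -> tuple[np.ndarray, float]:
    span = float(np.ptp(y))
    sd = noise_sd * (span if span > 0 else 1.0)
    if sd == 0:
        return y.copy(), 0.0
    return y + rng.normal(0.0, sd, size=y.shape), sd


def _gen_association(spec: GeneratorSpec,
                     rng: np.random.Generator) -> SyntheticDataset:
    preset = PRESETS[spec.preset]
    p = spec.params
    receptor = p.get("receptor_M", 1e-6)
    partner = p.get("partner_M", 20e-9)
    intensity = p.get("intensity_mW_cm2", 69.0)
    pulse = p.get("pulse_s", 0.5)
    t_max = p.get("t_max_s", 20.0)
    dt = p.get("dt_s", 0.1)  # instrument cadence of the fluorescence setup
    f0 = p.get("F0", 1.0)
    f1 = p.get("F1", 0.86)

    overrides = {k: p[k] for k in ("k_aR", "k_dR", "k_aFR", "k_dFR",
                                   "k_rec") if k in p}
    rates = preset.rate_constants(**overrides)
    comp = SystemComposition(R0_total=receptor, P0_total=partner)
    protocol = IlluminationProtocol.red_pulse(intensity, pulse)
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    traj = simulate(rates, protocol, comp, times)
    trace = observe(traj, ObservableMap(channel="fret", F0=f0, F1=f1))
    noisy, sd_abs = _add_noise(rng, trace.signal, spec.noise_sd)
    trace = TimeTrace(trace.time, noisy,
                      sd=None if sd_abs == 0 else np.full_like(noisy, sd_abs),
                      meta={"kind": spec.kind})
    truth = {
        "preset": preset.name, "k_aFR": rates.k_aFR,
        "k_dFR": rates.k_dFR, "k_dR": rates.k_dR,
        "pfr_fraction": preset.pfr_fraction,
        "receptor_M": receptor, "partner_M": partner,
        "intensity_mW_cm2": intensity, "pulse_s": pulse,
        "F0": f0, "F1": f1, "noise_sd_abs": sd_abs,
        # pseudo-first-order prediction for the post-pulse decay
        "k_obs_expected":
            rates.k_aFR * preset.pfr_fraction * receptor + rates.k_dFR,
    }
    return SyntheticDataset(trace, truth)


def _gen_dissociation(spec: GeneratorSpec,
                      rng: np.random.Generator) -> SyntheticDataset:
    preset = PRESETS[spec.preset]
    p = spec.params
    k_q = p.get("k_q_s", FARRED_RATE)
    k_o = p.get("k_o_s", preset.k_dR)
    t_max = p.get("t_max_s", 10.0)
    dt = p.get("dt_s", 0.1)
    f0 = p.get("F0", 1.0)   # final, unbound
    f1 = p.get("F1", 0.86)  # initial, bound (quenched)
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    clean = consecutive_signal(times, f0, f1, k_q, k_o)
    noisy, sd_abs = _add_noise(rng, clean, spec.noise_sd)
    trace = TimeTrace(times, noisy,
                      sd=None if sd_abs == 0 else np.full_like(noisy, sd_abs),
                      meta={"kind": spec.kind})
    truth = {"preset": preset.name, "k_q": k_q, "k_o": k_o,
             "F0": f0, "F1": f1, "noise_sd_abs": sd_abs}
    return SyntheticDataset(trace, truth)


def _gen_photoconversion(spec: GeneratorSpec,
                         rng: np.random.Generator) -> SyntheticDataset:
    p = spec.params
    k = p.get("k_s", FARRED_RATE)
    f0 = p.get("F0", 1.0)
    f1 = p.get("F1", -0.5)  # Pr fluorescence recovers under far-red light
    t_max = p.get("t_max_s", 4.0)
    dt = p.get("dt_s", 0.1)
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    clean = f0 + f1 * np.exp(-k * times)
    noisy, sd_abs = _add_noise(rng, clean, spec.noise_sd)
    trace = TimeTrace(times, noisy,
                      sd=None if sd_abs == 0 else np.full_like(noisy, sd_abs),
                      meta={"kind": spec.kind})
    return SyntheticDataset(trace, {"k": k, "F0": f0, "F1": f1,
                                    "noise_sd_abs": sd_abs})


def _gen_titration(spec: GeneratorSpec,
                   rng: np.random.Generator) -> SyntheticDataset:
    p = spec.params
    kd_apparent = p.get("K_d_apparent_M", 180e-9)
    f0 = p.get("F0", 1.0)
    f1 = p.get("F1", 0.86)
    conc = np.asarray(p.get(
        "concentrations_M",
        np.concatenate(([0.0], np.geomspace(10e-9, 2000e-9, 12)))),
        dtype=float)
    clean = f0 + (f1 - f0) * conc / (conc + kd_apparent)
    noisy, sd_abs = _add_noise(rng, clean, spec.noise_sd)
    table = pd.DataFrame({"concentration_M": conc, "signal": noisy})
    if sd_abs > 0:
        table["sd"] = sd_abs
    truth = {"K_d_apparent": kd_apparent, "F0": f0, "F1": f1,
             "pfr_fraction": PRESETS[spec.preset].pfr_fraction,
             "noise_sd_abs": sd_abs}
    return SyntheticDataset(table, truth)


def _gen_k_vs_T(spec: GeneratorSpec,
                rng: np.random.Generator) -> SyntheticDataset:
    preset = PRESETS[spec.preset]
    p = spec.params
    which = p.get("which", "dissociation")
    if which == "dissociation":
        e_a, k_ref = preset.E_A_dissoc, preset.k_dFR
    elif which == "association":
        e_a, k_ref = preset.E_A_assoc, preset.k_aFR
    else:
        raise ModelError("which must be 'association' or 'dissociation'")
    T = np.asarray(p.get("temperatures_K",
                         [288.15, 295.15, 303.15]), dtype=float)
    T_ref = p.get("T_ref_K", 288.15)  # presets are the 15 C values
    A = k_ref / np.exp(-e_a / (R_GAS * T_ref))
    clean = A * np.exp(-e_a / (R_GAS * T))
    if spec.noise_sd > 0:  # multiplicative noise: rates span decades
        noisy = clean * np.exp(rng.normal(0.0, spec.noise_sd, size=T.shape))
    else:
        noisy = clean.copy()
    table = pd.DataFrame({"T_K": T, "k_s": noisy})
    truth = {"preset": preset.name, "which": which, "E_A": e_a, "A": A,
             "noise_sd": spec.noise_sd}
    return SyntheticDataset(table, truth)


def _gen_melt(spec: GeneratorSpec,
              rng: np.random.Generator) -> SyntheticDataset:
    p = spec.params
    tm_C = p.get("T_m_C", 49.9)
    dH = p.get("dH_J_mol", 3e5)
    T_C = np.asarray(p.get("temperatures_C",
                           np.arange(15.0, 90.0 + 0.5, 1.0)), dtype=float)
    T = T_C + 273.15
    # CD at 222 nm: folded strongly negative, unfolded weaker, both with
    # shallow linear drifts
    a_f = p.get("baseline_folded_intercept", -20.0)
    b_f = p.get("baseline_folded_slope", 0.01)
    a_u = p.get("baseline_unfolded_intercept", -5.0)
    b_u = p.get("baseline_unfolded_slope", 0.0)
    clean = melt_signal(T, dH, tm_C + 273.15, a_f, b_f, a_u, b_u)
    noisy, sd_abs = _add_noise(rng, clean, spec.noise_sd)
    table = pd.DataFrame({"T_K": T, "signal": noisy})
    truth = {"T_m_C": tm_C, "dH": dH, "noise_sd_abs": sd_abs}
    return SyntheticDataset(table, truth)


def _gen_fcs(spec: GeneratorSpec,
             rng: np.random.Generator) -> SyntheticDataset:
    p = spec.params
    D = p.get("D_m2_s", 80e-12)
    omega_r = p.get("omega_r_m", 250e-9)
    gamma = p.get("gamma", 9.0)
    g0 = p.get("G0", 0.05)
    tau_d = omega_r ** 2 / (4.0 * D)
    lag = np.asarray(p.get("lag_s", np.geomspace(1e-6, 1.0, 200)),
                     dtype=float)
    clean = fcs_model(lag, g0, tau_d, gamma)
    if spec.noise_sd > 0:
        if p.get("occupancy_scaled", True):
            # log-spaced correlator bins average over ~lag-proportional
            # photon pairs, so statistical noise falls like 1/sqrt(lag)
            rel = np.sqrt(lag[0] / lag)
            sd = spec.noise_sd * g0 * rel
        else:
            sd = np.full_like(lag, spec.noise_sd * g0)
        noisy = clean + rng.normal(0.0, 1.0, size=lag.shape) * sd
    else:
        noisy = clean.copy()
    from .hydrodynamics import FCSCurve
    curve = FCSCurve(lag, noisy, count_rate=p.get("count_rate_Hz", 2e4))
    truth = {"D": D, "tau_D": tau_d, "G0": g0, "gamma": gamma,
             "omega_r": omega_r, "noise_sd": spec.noise_sd}
    return SyntheticDataset(curve, truth)


_GENERATORS = {
    "association_trace": _gen_association,
    "dissociation_trace": _gen_dissociation,
    "photoconversion_trace": _gen_photoconversion,
    "titration": _gen_titration,
    "k_vs_T": _gen_k_vs_T,
    "melt_curve": _gen_melt,
    "fcs_curve": _gen_fcs,
}


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Deterministically generate one data set from its spec."""
    rng = np.random.default_rng(spec.seed)
    return _GENERATORS[spec.kind](spec, rng)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2 ** 31))


def _write_trace_csv(trace: TimeTrace, path: Path) -> None:
    cols = {"time_s": trace.time, "signal": trace.signal}
    if trace.sd is not None:
        cols["sd"] = trace.sd
    pd.DataFrame(cols).to_csv(path, index=False)


def make_benchmark_suite(seed: int, outdir) -> dict:
    """Write one fixture per estimator (CSV + truth sidecar JSON).

    Includes a four-intensity association set (1/10/30/69 mW cm^-2 under
    20-s continuous red light) for the global fit, shutter-pulse
    association traces across a concentration series for the
    pseudo-first-order analysis, and one fixture each for the remaining
    estimators.  Returns a manifest mapping fixture names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    idx = 0

    def record(name: str, dataset: SyntheticDataset, stem: Path) -> None:
        truth_path = stem.with_suffix(".truth.json")
        with open(truth_path, "w") as fh:
            json.dump(dataset.truth, fh, indent=1, default=float)
        manifest[name] = {"data": str(stem.with_suffix(".csv")),
                          "truth": str(truth_path)}

    # four-intensity continuous-light interaction set (global fit input)
    for intensity in (1.0, 10.0, 30.0, 69.0):
        idx += 1
        ds = generate(GeneratorSpec(
            "association_trace", noise_sd=0.01, seed=_child_seed(seed, idx),
            params={"intensity_mW_cm2": intensity, "pulse_s": 20.0,
                    "t_max_s": 40.0}))
        stem = outdir / f"interaction_{intensity:g}mW"
        _write_trace_csv(ds.data, stem.with_suffix(".csv"))
        record(f"interaction_{intensity:g}mW", ds, stem)

    # shutter-pulse concentration series (pseudo-first-order input)
    for conc_nM in (500, 1000, 1500, 2000):
        idx += 1
        ds = generate(GeneratorSpec(
            "association_trace", noise_sd=0.01, seed=_child_seed(seed, idx),
            params={"receptor_M": conc_nM * 1e-9, "pulse_s": 0.5,
                    "t_max_s": 20.0}))
        stem = outdir / f"association_{conc_nM}nM"
        _write_trace_csv(ds.data, stem.with_suffix(".csv"))
        record(f"association_{conc_nM}nM", ds, stem)

    simple = {
        "dissociation": GeneratorSpec("dissociation_trace", noise_sd=0.01,
                                      seed=_child_seed(seed, 101)),
        "photoconversion": GeneratorSpec("photoconversion_trace",
                                         noise_sd=0.01,
                                         seed=_child_seed(seed, 102)),
        "titration": GeneratorSpec("titration", noise_sd=0.03,
                                   seed=_child_seed(seed, 103)),
        "arrhenius": GeneratorSpec("k_vs_T", noise_sd=0.0,
                                   seed=_child_seed(seed, 104)),
        "melt": GeneratorSpec("melt_curve", noise_sd=0.01,
                              seed=_child_seed(seed, 105)),
        "fcs": GeneratorSpec("fcs_curve", noise_sd=0.02,
                             seed=_child_seed(seed, 106)),
    }
    for name, gspec in simple.items():
        ds = generate(gspec)
        stem = outdir / name
        if isinstance(ds.data, TimeTrace):
            _write_trace_csv(ds.data, stem.with_suffix(".csv"))
        elif isinstance(ds.data, pd.DataFrame):
            ds.data.to_csv(stem.with_suffix(".csv"), index=False)
        else:  # FCS curve
            pd.DataFrame({"lag_s": ds.data.lag, "G": ds.data.G}).to_csv(
                stem.with_suffix(".csv"), index=False)
        record(name, ds, stem)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
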