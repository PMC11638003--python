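"""Tabular readers/writers, run configuration, and the pipeline driver.

All tables are comma-separated UTF-8 CSV with a mandatory header and '.'
decimal separator.  Units are embedded in column and config key names
(``time_s``, ``intensity_mW_cm2``) so files are unambiguous on their own.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    IlluminationProtocol,
    LightSegment,
    ModelError,
    RateConstants,
    SystemComposition,
    TimeTrace,
    Trajectory,
    simulate,
)
from .photostationary import (
    ScanSpec,
    DoseResponseCurve,
    dose_response,
    scan_panel,
    solve_photostationary,
)
from . import estimators as est
from .synthetic import GeneratorSpec, generate, make_benchmark_suite

__all__ = ["read_trace", "write_trace", "write_trajectory",
           "write_dose_response", "RunConfig", "read_config", "run_pipeline"]


class ConfigError(ValueError):
    pass


def read_trace(path) -> TimeTrace:
    """Read a (time_s, signal[, sd]) CSV into a TimeTrace.

    Times must be strictly increasing; a violation is reported with the
    offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ModelError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ModelError(
            f"{path}: times not strictly increasing at data row "
            f"{int(bad[0]) + 2}")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return TimeTrace(t, df["signal"].to_numpy(dtype=float), sd,
                     meta={"source": str(path)})


def write_trace(trace: TimeTrace, path) -> None:
    cols = {"time_s": trace.time, "signal": trace.signal}
    if trace.sd is not None:
        cols["sd"] = trace.sd
    pd.DataFrame(cols).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({
        "time_s": traj.times, "R_M": traj.R, "FR_M": traj.FR,
        "RP_M": traj.RP, "FRP_M": traj.FRP, "P_M": traj.P,
    }).to_csv(path, index=False)


def write_dose_response(curve: DoseResponseCurve, path) -> None:
    """CSV of the curve plus a JSON sidecar with the scan metadata."""
    path = Path(path)
    pd.DataFrame({"intensity_mW_cm2": curve.intensities,
                  "bound_fraction": curve.bound_fraction}).to_csv(
        path, index=False)
    sidecar = {
        "scan_label": curve.scan_label,
        "scan_value": curve.scan_value,
        "low_intensity_plateau": curve.low_intensity_plateau,
        "peak_intensity_mW_cm2": curve.peak_intensity,
        "peak_height": curve.peak_height,
        "attenuation_threshold": curve.attenuation_threshold,
        "attenuation_onset_mW_cm2": curve.attenuation_onset,
    }
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


# --- configuration -----------------------------------------------------

_RATE_KEYS = {"k_p_coeff", "k_q_coeff", "k_aR", "k_dR", "k_aFR", "k_dFR",
              "k_q733_coeff", "k_rec"}
_COMP_KEYS = {"R0_total_M", "P0_total_M", "pfr_fraction_0",
              "bound_rp_fraction_0", "bound_frp_fraction_0"}
_SEGMENT_KEYS = {"t_start_s", "duration_s", "channel", "intensity_mW_cm2"}

_SCHEMAS = {
    "simulate": {"rates", "composition", "protocol", "time", "output"},
    "steady_state": {"rates", "composition", "intensity_mW_cm2",
                     "channel", "output"},
    "dose_response": {"rates", "composition", "intensity_grid",
                      "scan", "output"},
    "fit": {"model", "input", "options", "output"},
    "synth": {"generator", "output"},
    "suite": {"output"},
}


@dataclass
class RunConfig:
    """Schema-validated description of one pipeline run."""

    kind: str
    seed: int = 0
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        kind = doc.get("kind")
        if kind not in _SCHEMAS:
            raise ConfigError(
                f"config 'kind' must be one of {sorted(_SCHEMAS)}, "
                f"got {kind!r}")
        allowed = _SCHEMAS[kind] | {"kind", "seed"}
        unknown = set(doc) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        blocks = {k: v for k, v in doc.items() if k not in ("kind", "seed")}
        return cls(kind=kind, seed=int(doc.get("seed", 0)), blocks=blocks)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.from_dict(doc)


def _rates_from_block(block: dict | None) -> RateConstants:
    block = block or {}
    unknown = set(block) - _RATE_KEYS
    if unknown:
        raise ConfigError(f"unknown rate keys: {sorted(unknown)}")
    # YAML readers may deliver scientific-notation scalars as strings
    return RateConstants(**{k: float(v) for k, v in block.items()})


def _composition_from_block(block: dict) -> SystemComposition:
    unknown = set(block) - _COMP_KEYS
    if unknown:
        raise ConfigError(f"unknown composition keys: {sorted(unknown)}")
    rename = {"R0_total_M": "R0_total", "P0_total_M": "P0_total"}
    return SystemComposition(**{rename.get(k, k): float(v)
                                for k, v in block.items()})


def _protocol_from_block(block: list) -> IlluminationProtocol:
    segs = []
    for seg in block:
        unknown = set(seg) - _SEGMENT_KEYS
        if unknown:
            raise ConfigError(f"unknown segment keys: {sorted(unknown)}")
        segs.append(LightSegment(
            t_start=seg.get("t_start_s", 0.0),
            duration=seg["duration_s"],
            channel=seg.get("channel", "red658"),
            intensity=seg.get("intensity_mW_cm2", 0.0)))
    return IlluminationProtocol(tuple(segs))


_FIT_DISPATCH = {
    "monoexp": lambda trace, opt: est.fit_monoexponential(trace),
    "biexp": lambda trace, opt: est.fit_biexponential(trace),
    "consecutive": lambda trace, opt: est.fit_consecutive(
        trace, opt["k_q_fixed"]),
}
_TABLE_FITS = {
    "pseudo_first_order": lambda df, opt: est.fit_pseudo_first_order(
        df, opt.get("pfr_fraction", 0.73)),
    "isotherm": lambda df, opt: est.fit_isotherm(
        df, opt.get("pfr_fraction", 0.73), opt.get("correct", True)),
    "arrhenius": lambda df, opt: est.fit_arrhenius(
        df, opt.get("method", "log-linear")),
    "melt": lambda df, opt: est.fit_two_state_melt(df),
}


def fit_file(model: str, path, options: dict | None = None):
    """Run one named estimator on a CSV input file."""
    options = options or {}
    if model in _FIT_DISPATCH:
        return _FIT_DISPATCH[model](read_trace(path), options)
    if model in _TABLE_FITS:
        return _TABLE_FITS[model](pd.read_csv(path), options)
    if model == "fcs":
        from .hydrodynamics import FCSCurve, fit_fcs
        df = pd.read_csv(path)
        curve = FCSCurve(df["lag_s"].to_numpy(), df["G"].to_numpy())
        return fit_fcs(curve, options.get("gamma", 9.0),
                       options.get("omega_r", 250e-9))
    raise ConfigError(f"unknown fit model {model!r}")


def fit_result_record(result) -> list[dict]:
    """Flatten any fit result into (parameter, estimate, stderr, fixed)."""
    rows = []
    fixed_names = {"k_q_fixed", "pfr_fraction_used", "gamma", "omega_r",
                   "ref_intensity"}
    skip = {"stderr", "flags", "rss", "rss_by_intensity", "meta",
            "baseline_folded", "baseline_unfolded", "rates", "message",
            "success", "model", "n_points", "method",
            "slower_phase_dominant"}
    stderr = getattr(result, "stderr", {})
    for name, value in vars(result).items():
        if name in skip or value is None:
            continue
        rows.append({
            "parameter": name,
            "estimate": float(value),
            "stderr": float(stderr.get(name, np.nan)),
            "fixed": name in fixed_names,
        })
    return rows


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute one configured run and write results plus a manifest.

    The manifest records the config digest, the seed and the package
    version, which together fully determine the outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {}
    t0 = _time.perf_counter()

    def stage(name: str, **extra):
        log.append({"stage": name, "wall_s": _time.perf_counter() - t0,
                    **extra})

    b = config.blocks
    try:
        if config.kind == "simulate":
            rates = _rates_from_block(b.get("rates"))
            comp = _composition_from_block(b["composition"])
            protocol = _protocol_from_block(b["protocol"])
            tblock = b["time"]
            grid = np.arange(tblock["t_start_s"],
                             tblock["t_end_s"] + 0.5 * tblock["dt_s"],
                             tblock["dt_s"])
            traj = simulate(rates, protocol, comp, grid)
            out = outdir / b.get("output", "trajectory.csv")
            write_trajectory(traj, out)
            results["trajectory"] = str(out)
            stage("simulate", points=len(grid))
        elif config.kind == "steady_state":
            rates = _rates_from_block(b.get("rates"))
            comp = _composition_from_block(b["composition"])
            state = solve_photostationary(
                rates, comp, b["intensity_mW_cm2"],
                b.get("channel", "red658"))
            results["steady_state"] = {
                "R_M": state.R, "FR_M": state.FR, "RP_M": state.RP,
                "FRP_M": state.FRP, "P_M": state.P,
            }
            stage("steady_state")
        elif config.kind == "dose_response":
            rates = _rates_from_block(b.get("rates"))
            comp = _composition_from_block(b["composition"])
            gblock = b["intensity_grid"]
            grid = np.geomspace(gblock["min_mW_cm2"], gblock["max_mW_cm2"],
                                int(gblock["n"]))
            if "scan" in b:
                spec = ScanSpec(b["scan"]["dimension"],
                                tuple(b["scan"]["values"]))
                curves = scan_panel(rates, comp, spec, grid)
            else:
                curves = [dose_response(rates, comp, grid)]
            paths = []
            for i, curve in enumerate(curves):
                out = outdir / f"dose_response_{i}.csv"
                write_dose_response(curve, out)
                paths.append(str(out))
            results["curves"] = paths
            stage("dose_response", n_curves=len(curves))
        elif config.kind == "fit":
            result = fit_file(b["model"], b["input"], b.get("options"))
            rows = fit_result_record(result)
            out = outdir / b.get("output", "fit_result.csv")
            pd.DataFrame(rows).to_csv(out, index=False)
            results["fit"] = str(out)
            results["flags"] = list(getattr(result, "flags", []))
            stage("fit", model=b["model"])
        elif config.kind == "synth":
            g = dict(b["generator"])
            g.setdefault("seed", config.seed)
            ds = generate(GeneratorSpec(**g))
            out = outdir / b.get("output", "synthetic.csv")
            if isinstance(ds.data, TimeTrace):
                write_trace(ds.data, out)
            else:
                ds.data.to_csv(out, index=False)
            with open(out.with_suffix(".truth.json"), "w") as fh:
                json.dump(ds.truth, fh, indent=1, default=float)
            results["synthetic"] = str(out)
            stage("synth", kind=g["kind"])
        elif config.kind == "suite":
            manifest = make_benchmark_suite(config.seed,
                                            outdir / b.get("output", "suite"))
            results["suite"] = {k: v["data"] for k, v in manifest.items()}
            stage("suite", n_fixtures=len(manifest))
    except Exception as err:
        stage("error", error=str(err))
        _write_manifest(config, outdir, results, log)
        raise

    _write_manifest(config, outdir, results, log)
    return results


def _write_manifest(config: RunConfig, outdir: Path, results: dict,
                    log: list) -> None:
    digest = hashlib.sha256(
        json.dumps({"kind": config.kind, "seed": config.seed,
                    "blocks": config.blocks},
                   sort_keys=True, default=str).encode()).hexdigest()
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump({"config_sha256": digest, "seed": config.seed,
                   "version": __version__, "results": results,
                   "log": log}, fh, indent=1, default=str)
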