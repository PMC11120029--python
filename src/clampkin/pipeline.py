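"""End-to-end orchestration: generate -> fit/select -> melt -> titrate -> cleave.

The pipeline reproduces the study's full analysis on synthetic data: a
per-condition overall-binding-constant table with pairwise ratios, a melting
temperature/delta-Tm table, a quench-titration summary and cleavage fits,
written as plain CSV tables plus one structured text report.  Configuration
is a nested mapping (YAML on disk) validated strictly: unknown keys are
rejected with their location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .cleavage import fit_cleavage
from .globalfit import FitProblem, compare_conditions, staged_global_fit
from .hybridization import fit_quench_titration
from .melting import baseline_correct, delta_tm, differential_melting, write_melting_csv
from .synth import (
    InstrumentModel,
    ResponseModel,
    default_design,
    protocol_design,
    simulate_cleavage_timecourse,
    simulate_melting_curve,
    simulate_titration,
    simulate_trace_set,
    write_traceset_csv,
)

log = logging.getLogger("clampkin")

#: stage -> key -> default.  This mapping is also the validation schema.
DEFAULT_CONFIG = {
    "seed": 0,
    "binding": {
        "conditions": list(fixtures.STOPPED_FLOW),
        "design": "protocol",  # "protocol" (enzyme varied) or "figure"
        "noise_sd": 0.01,
        "n_samples": 400,
        "multistart": 2,
        "windows": [0.02, 0.2, 1.0],
    },
    "melting": {
        "duplexes": list(fixtures.MELTING),
        "noise_sd": 0.002,
        "smoothing_window": 25,
        "smoothing_order": 2,
    },
    "titration": {
        "noise_sd": 0.01,
        "points": 9,
        "max_excess": 3.0,
    },
    "cleavage": {
        "conditions": list(fixtures.CLEAVAGE),
        "noise_sd": 0.02,
        "n_times": 12,
        "t_max": 7200.0,
    },
}


class ConfigError(ValueError):
    """Configuration key unknown or malformed; message carries the location."""


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user and isinstance(default, dict):
            if not isinstance(user[key], dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge_validate(user[key], default, here)
        else:
            out[key] = user.get(key, default)
    for key in user:
        if key not in defaults:
            here = f"{path}.{key}" if path else key
            raise ConfigError(f"unknown configuration key: {here}")
    return out


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "RunConfig":
        return cls(_merge_validate(mapping or {}, DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        return cls.from_mapping(loaded)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)

    def __getitem__(self, key):
        return self.raw[key]


def run_binding_stage(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cfg = config["binding"]
    seed = int(config["seed"])
    design = protocol_design() if cfg["design"] == "protocol" else default_design()
    results = {}
    for i, cond in enumerate(cfg["conditions"]):
        scheme = fixtures.binding_scheme(cond)
        response = ResponseModel(fixtures.RESPONSE_BACKGROUND,
                                 dict(fixtures.RESPONSE_COEFFICIENTS))
        instrument = InstrumentModel(noise_sd=cfg["noise_sd"],
                                     n_samples=cfg["n_samples"], seed=seed + i)
        ts = simulate_trace_set(scheme, response, instrument, design, condition=cond)
        write_traceset_csv(ts, outdir / f"traces_{_slug(cond)}.csv")
        log.info("binding %s: %d traces, noise_sd=%.3g, seed=%d",
                 cond, len(ts.traces), cfg["noise_sd"], instrument.seed)
        problem = FitProblem(ts, scheme, multistart=cfg["multistart"], seed=seed + i)
        results[cond] = staged_global_fit(problem, windows=tuple(cfg["windows"]))
        log.info("binding %s: Ka=%.3g /M (SSR %.3g)", cond,
                 results[cond].derived.Ka, results[cond].ssr)
    table = compare_conditions(results)
    table.constants.to_csv(outdir / "ka_table.csv", index_label="condition")
    table.ka_ratios.to_csv(outdir / "ka_ratios.csv", index_label="condition")
    return table.constants


def run_melting_stage(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cfg = config["melting"]
    seed = int(config["seed"])
    estimates = {}
    for i, duplex in enumerate(cfg["duplexes"]):
        p = fixtures.MELTING[duplex]
        curve = simulate_melting_curve(p["tm"], p["dH"], noise_sd=cfg["noise_sd"],
                                       seed=seed + 10 * i, label=duplex)
        write_melting_csv(curve, outdir / f"melting_{_slug(duplex)}.csv")
        est = differential_melting(baseline_correct(curve),
                                   window=cfg["smoothing_window"],
                                   polyorder=cfg["smoothing_order"])
        estimates[duplex] = est
        log.info("melting %s: Tm=%.2f degC (generator %.1f)", duplex, est.consensus, p["tm"])
    rows = [{"duplex": d,
             "tm_260_C": est.per_wavelength.get(260, np.nan),
             "tm_270_C": est.per_wavelength.get(270, np.nan),
             "tm_consensus_C": est.consensus} for d, est in estimates.items()]
    df = pd.DataFrame(rows).set_index("duplex")
    deltas = []
    for pair, (a, b) in fixtures.MELTING_PAIRS.items():
        if a in estimates and b in estimates:
            deltas.append({"pair": pair, "delta_tm_C": delta_tm(estimates[a], estimates[b])})
    df.to_csv(outdir / "tm_table.csv")
    pd.DataFrame(deltas).to_csv(outdir / "delta_tm.csv", index=False)
    return df


def run_titration_stage(config: RunConfig, outdir: Path) -> dict:
    cfg = config["titration"]
    seed = int(config["seed"])
    fx = fixtures.TITRATION
    added = np.linspace(0.0, cfg["max_excess"] * fx["clamp_conc"], cfg["points"])
    series = simulate_titration(fx["clamp_conc"], added, fx["Kd"], fx["quench_eff"],
                                noise_sd=cfg["noise_sd"], seed=seed + 100)
    control = simulate_titration(fx["clamp_conc"], added, fx["Kd"], fx["quench_eff"],
                                 noise_sd=cfg["noise_sd"], seed=seed + 101,
                                 partner_is_oxoG=False)
    series.to_csv(outdir / "titration_oxoG.csv", index=False)
    control.to_csv(outdir / "titration_G_control.csv", index=False)
    model = fit_quench_titration(series["partner_total_M"].to_numpy(),
                                 series["relative_fluorescence"].to_numpy(),
                                 fx["clamp_conc"])
    summary = {
        "Kd_M": model.Kd,
        "quench_eff": model.quench_eff,
        "quench_eff_stderr": model.quench_eff_stderr,
        "equimolar_decrease_pct": 100.0 * (1.0 - float(np.interp(
            fx["clamp_conc"], series["partner_total_M"], series["relative_fluorescence"]))),
        "control_mean_signal": float(control["relative_fluorescence"].mean()),
    }
    log.info("titration: quench_eff=%.3f, Kd=%.3g M", model.quench_eff, model.Kd)
    return summary


def run_cleavage_stage(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cfg = config["cleavage"]
    seed = int(config["seed"])
    times = np.geomspace(30.0, cfg["t_max"], cfg["n_times"])  # log-spaced gel sampling
    rows = []
    frames = []
    for i, cond in enumerate(cfg["conditions"]):
        p = fixtures.CLEAVAGE[cond]
        alkali = simulate_cleavage_timecourse(p["kg"], p["kl"], p["active_fraction"],
                                              times, alkali=True,
                                              noise_sd=cfg["noise_sd"],
                                              seed=seed + 200 + i, condition=cond)
        untreated = simulate_cleavage_timecourse(p["kg"], p["kl"], p["active_fraction"],
                                                 times, alkali=False,
                                                 noise_sd=cfg["noise_sd"],
                                                 seed=seed + 250 + i, condition=cond)
        for tc in (alkali, untreated):
            frames.append(pd.DataFrame({"time_s": tc.times, "fraction_cleaved": tc.readout,
                                        "alkali": int(tc.alkali_treated), "condition": cond}))
        fit = fit_cleavage(alkali, untreated)
        rows.append({"condition": cond, "kg_per_s": fit.kg, "kl_per_s": fit.kl,
                     "active_fraction": fit.active_fraction,
                     "flags": ";".join(fit.flags)})
        log.info("cleavage %s: kg=%.3g /s kl=%.3g /s a=%.2f %s",
                 cond, fit.kg, fit.kl, fit.active_fraction, fit.flags)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "cleavage_timecourses.csv", index=False)
    df = pd.DataFrame(rows).set_index("condition")
    df.to_csv(outdir / "cleavage_fits.csv")
    return df


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the combined report; returns the tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_used.yaml").write_text(config.to_yaml())
    log.info("pipeline start: seed=%s outdir=%s", config["seed"], outdir)

    stages = {}
    for name, fn in [("binding", run_binding_stage), ("melting", run_melting_stage),
                     ("titration", run_titration_stage), ("cleavage", run_cleavage_stage)]:
        try:
            stages[name] = fn(config, outdir)
        except Exception:
            log.exception("stage %r failed; partial outputs kept in %s", name, outdir)
            raise

    lines = ["clampkin pipeline report", "========================", ""]
    lines.append("Overall binding constants (Ka, per M):")
    lines.append(stages["binding"].to_string())
    lines += ["", "Melting temperatures (degC):", stages["melting"].to_string()]
    lines += ["", "Quench titration summary:"]
    lines += [f"  {k}: {v}" for k, v in stages["titration"].items()]
    lines += ["", "Cleavage fits:", stages["cleavage"].to_string(), ""]
    (outdir / "report.txt").write_text("\n".join(lines))
    log.info("pipeline done")
    return stages


def _slug(name: str) -> str:
    return name.replace("/", "_").replace("*", "x").replace(" ", "")
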