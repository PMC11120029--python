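"""Synthetic instrument data for every stage of the pipeline.

Emulates the four experiments the analysis consumes, with the statistical
structure of the real instruments:

* stopped-flow fluorescence traces — mass-action trajectories observed
  through a linear response model, sampled on a log grid that starts at the
  1.4 ms mixer dead time, with seeded additive Gaussian noise;
* UV melting curves — bimolecular two-state (van't Hoff) duplex dissociation
  between linear single- and double-strand baselines at 260/270 nm plus a
  transition-free 330 nm reference channel, on a 5-95 degC grid;
* clamp-fluorescence quench titrations with saturation;
* single-turnover cleavage time courses for alkali-treated and untreated
  aliquots.

Every generator records its ground-truth parameters and seed so downstream
recovery tests are self-contained, and is byte-deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cleavage as _cleavage
from . import hybridization as _hyb
from .melting import MeltingCurve
from .schemes import KineticScheme, integrate

__all__ = [
    "InstrumentModel",
    "ResponseModel",
    "Trace",
    "TraceSet",
    "default_design",
    "simulate_trace_set",
    "vant_hoff_duplex_fraction",
    "simulate_melting_curve",
    "simulate_titration",
    "simulate_cleavage_timecourse",
    "write_traceset_csv",
    "read_traceset_csv",
]

R_GAS = 8.314462618  # J/(mol K)


@dataclass
class InstrumentModel:
    """Stopped-flow acquisition model.

    dead_time is the interval between mixing and the first observable point
    (1.4 ms for the instrument emulated here); no sample is emitted before
    it.  noise_sd is a fraction of the full-scale (maximum absolute)
    noiseless signal of the trace set.
    """

    dead_time: float = 0.0014
    n_samples: int = 400
    t_max: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0
    sampling: np.ndarray | None = None  # overrides the default log grid

    def times(self) -> np.ndarray:
        if self.sampling is not None:
            t = np.asarray(self.sampling, dtype=float)
            if t.size and t[0] < self.dead_time:
                raise ValueError("sampling starts before the instrument dead time")
            return t
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        start = max(self.dead_time, 1e-6)
        return np.geomspace(start, self.t_max, self.n_samples)


@dataclass
class ResponseModel:
    """Linear fluorescence response: signal = background + sum coeff * conc."""

    background: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)

    def observe(self, trajectory) -> np.ndarray:
        signal = np.full(len(trajectory.times), self.background, dtype=float)
        for species, coeff in self.coefficients.items():
            signal += coeff * trajectory[species]
        return signal


@dataclass
class Trace:
    enzyme_total: float  # M
    duplex_total: float  # M
    times: np.ndarray  # s
    signal: np.ndarray  # a.u.


@dataclass
class TraceSet:
    """A concentration series sharing one mechanism and one response model."""

    traces: list[Trace]
    condition: str
    instrument: InstrumentModel
    response: ResponseModel
    truth: dict = field(default_factory=dict)  # generator ground truth


def default_design() -> tuple[tuple[float, float], ...]:
    """1 uM enzyme against a 0.4-1.6 uM duplex series (the figure design)."""
    return ((1e-6, 0.4e-6), (1e-6, 0.8e-6), (1e-6, 1.2e-6), (1e-6, 1.6e-6))


def protocol_design() -> tuple[tuple[float, float], ...]:
    """Duplex fixed at 1 uM with the enzyme varied in the micromolar range.

    This is the written measurement protocol; sweeping the enzyme over
    almost a decade moves both the observed relaxation rate and the bound
    fraction strongly, which makes the shared rate constants far better
    identified than the narrow duplex sweep of :func:`default_design`, so
    recovery analyses use it.
    """
    return ((0.5e-6, 1e-6), (1e-6, 1e-6), (2e-6, 1e-6), (4e-6, 1e-6))


def simulate_trace_set(
    scheme: KineticScheme,
    response: ResponseModel,
    instrument: InstrumentModel,
    design=None,
    condition: str = "oxoG/oxoG-clamp",
) -> TraceSet:
    """Simulate a stopped-flow concentration series under one mechanism.

    Each trace integrates the scheme from (E, S) = (enzyme_total,
    duplex_total) at t = 0 and observes it at the instrument sample times
    (all >= dead time), then adds Gaussian noise scaled to the full-scale
    signal of the whole set.
    """
    if design is None:
        design = default_design()
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    for e0, s0 in design:
        if e0 <= 0 or s0 <= 0:
            raise ValueError("design concentrations must be positive")
    times = instrument.times()
    clean: list[np.ndarray] = []
    for e0, s0 in design:
        traj = integrate(scheme, {"E": e0, "S": s0}, times)
        clean.append(response.observe(traj))
    full_scale = max(float(np.max(np.abs(s))) for s in clean)
    rng = np.random.default_rng(instrument.seed)
    traces = []
    for (e0, s0), signal in zip(design, clean):
        noisy = signal + rng.normal(0.0, instrument.noise_sd * full_scale, size=signal.shape)
        traces.append(Trace(e0, s0, times.copy(), noisy))
    truth = {
        "rate_constants": dict(scheme.rate_constants),
        "scheme": scheme.to_text(),
        "noise_sd": instrument.noise_sd,
        "full_scale": full_scale,
        "seed": instrument.seed,
    }
    return TraceSet(traces, condition, instrument, response, truth)


def vant_hoff_duplex_fraction(T_celsius, tm_celsius: float, dH: float, strand_conc: float):
    """Duplex fraction theta(T) for a non-self-complementary two-state duplex.

    Equal strand totals Cs; van't Hoff association constant anchored so that
    theta(Tm) = 1/2, which fixes K(Tm) = 2/Cs and eliminates dS:

        K(T) = (2/Cs) * exp[(-dH/R) * (1/T - 1/Tm)]   (T in kelvin)

    theta is then the exact root of the binding quadratic at Kd = 1/K.
    """
    if dH >= 0:
        raise ValueError("dH must be negative (association exothermic)")
    if strand_conc <= 0:
        raise ValueError("strand_conc must be positive")
    T = np.asarray(T_celsius, dtype=float) + 273.15
    Tm = tm_celsius + 273.15
    K = (2.0 / strand_conc) * np.exp((-dH / R_GAS) * (1.0 / T - 1.0 / Tm))
    theta = np.array(
        [_hyb.fraction_duplex(strand_conc, strand_conc, 1.0 / k) for k in np.atleast_1d(K)]
    )
    return theta if np.ndim(T_celsius) else float(theta[0])


#: (intercept a.u., slope a.u./degC) double- and single-strand baselines per
#: wavelength; 330 nm holds a single transition-free baseline.
DEFAULT_BASELINES = {
    260: ((0.80, 0.0008), (1.00, 0.0005)),
    270: ((0.70, 0.0008), (0.88, 0.0005)),
    330: ((0.02, 0.0001), (0.02, 0.0001)),
}


def simulate_melting_curve(
    tm: float,
    dH: float = -350e3,
    strand_conc: float = 2e-6,
    baselines: dict | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> MeltingCurve:
    """Two-state melting curve with linear baselines on a 5-95 degC grid.

    tm in degC, dH in J/mol (negative).  Per wavelength, absorbance is
    ds_baseline(T) * theta + ss_baseline(T) * (1 - theta) + noise; the
    330 nm channel carries its baseline only (theta-independent), emulating
    the drift-reference channel.
    """
    if grid is None:
        grid = np.arange(5.0, 95.0 + 1e-9, 0.5)
    if baselines is None:
        baselines = DEFAULT_BASELINES
    theta = vant_hoff_duplex_fraction(grid, tm, dH, strand_conc)
    rng = np.random.default_rng(seed)
    absorbance = {}
    for w, ((ds0, ds1), (ss0, ss1)) in baselines.items():
        ds = ds0 + ds1 * grid
        ss = ss0 + ss1 * grid
        mix = ds if w == 330 else ds * theta + ss * (1.0 - theta)
        absorbance[w] = mix + rng.normal(0.0, noise_sd, size=grid.shape)
    curve = MeltingCurve(grid, absorbance, label=label, strand_conc=strand_conc)
    return curve


def simulate_titration(
    clamp_conc: float,
    added_conc_series,
    Kd: float,
    quench_eff: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    partner_is_oxoG: bool = True,
) -> pd.DataFrame:
    """Relative-fluorescence titration table with ground truth in ``attrs``.

    A normal-G partner binds but does not quench (quench_eff forced to 0),
    reproducing the flat control series.
    """
    added = np.asarray(added_conc_series, dtype=float)
    if clamp_conc < 0 or np.any(added < 0):
        raise ValueError("concentrations must be non-negative")
    model = _hyb.QuenchModel(Kd=Kd, quench_eff=quench_eff if partner_is_oxoG else 0.0)
    signal = _hyb.predict_relative_fluorescence(model, clamp_conc, added, partner_is_oxoG)
    rng = np.random.default_rng(seed)
    noisy = signal + rng.normal(0.0, noise_sd, size=added.shape)
    df = pd.DataFrame({"partner_total_M": added, "relative_fluorescence": noisy})
    df.attrs["truth"] = {
        "clamp_conc": clamp_conc, "Kd": Kd,
        "quench_eff": model.quench_eff, "noise_sd": noise_sd, "seed": seed,
        "partner_is_oxoG": partner_is_oxoG,
    }
    return df


def simulate_cleavage_timecourse(
    kg: float,
    kl: float,
    active_fraction: float,
    times,
    alkali: bool,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "oxoG/C",
    stimulation_factor: float = 1.0,
) -> _cleavage.CleavageTimeCourse:
    """One gel readout (alkali-treated or untreated) with densitometry noise."""
    params = _cleavage.CleavageParams(
        kg=kg, kl=kl, active_fraction=active_fraction, stimulation_factor=stimulation_factor
    )
    alkali_tc, untreated_tc = _cleavage.predict_readouts(params, times)
    tc = alkali_tc if alkali else untreated_tc
    rng = np.random.default_rng(seed)
    noisy = np.clip(tc.readout + rng.normal(0.0, noise_sd, size=tc.readout.shape), 0.0, 1.0)
    return _cleavage.CleavageTimeCourse(tc.times, noisy, alkali_treated=alkali, condition=condition)


# -- tidy CSV I/O with a structured-text ground-truth sidecar ----------------

def write_traceset_csv(ts: TraceSet, path) -> None:
    path = Path(path)
    rows = []
    for i, tr in enumerate(ts.traces):
        rows.append(pd.DataFrame({
            "condition": ts.condition,
            "trace_id": i,
            "enzyme_total_M": tr.enzyme_total,
            "duplex_total_M": tr.duplex_total,
            "time_s": tr.times,
            "signal_au": tr.signal,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    meta = {
        "condition": ts.condition,
        "dead_time_s": ts.instrument.dead_time,
        "noise_sd": ts.instrument.noise_sd,
        "seed": ts.instrument.seed,
        "response": {"background": ts.response.background,
                     "coefficients": dict(ts.response.coefficients)},
        "truth": ts.truth,
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_traceset_csv(path) -> TraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        traces.append(Trace(
            float(grp["enzyme_total_M"].iloc[0]),
            float(grp["duplex_total_M"].iloc[0]),
            grp["time_s"].to_numpy(),
            grp["signal_au"].to_numpy(),
        ))
    instrument = InstrumentModel(
        dead_time=float(meta.get("dead_time_s", 0.0014)),
        noise_sd=float(meta.get("noise_sd", 0.0)),
        seed=int(meta.get("seed", 0)),
    )
    resp_meta = meta.get("response", {})
    response = ResponseModel(
        background=float(resp_meta.get("background", 0.0)),
        coefficients=dict(resp_meta.get("coefficients", {})),
    )
    condition = str(df["condition"].iloc[0]) if "condition" in df else meta.get("condition", "")
    return TraceSet(traces, condition, instrument, response, meta.get("truth", {}))
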