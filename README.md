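# clampkin

Kinetic and biophysical analysis of DNA duplexes carrying the fluorescent
**oxoG-clamp** — a phenoxazine-based cytosine analog whose emission is
selectively quenched when it pairs with 8-oxoguanine (oxoG) — and of their
processing by human 8-oxoguanine-DNA glycosylase (**OGG1**).

The package implements, as a tested reusable pipeline, the four analyses
such a study runs:

1. **Pre-steady-state stopped-flow kinetics.** Mass-action binding schemes
   (`E + S ⇌ ES ⇌ ES*`) are compiled to stiff ODE systems and fit globally
   to a concentration series of fluorescence traces: rate constants are
   shared across traces, per-trace backgrounds and per-species response
   increments are profiled out by linear least squares (variable
   projection). The minimal mechanism is chosen by stepwise expansion of
   the analysed time window with an extra-sum-of-squares F-test between
   nested schemes. The overall association constant is
   `K_a = K1 (1 + K2)` with `K1 = k1/k−1` and `K2 = k2/k−2`.
2. **Thermal denaturation.** Multi-wavelength UV melting curves
   (260/270 nm plus a transition-free 330 nm drift reference) are baseline
   corrected, Savitzky–Golay smoothed and differentiated; the maximum of
   the differential melting curve is the operational Tm, and ΔTm compares
   duplex stability across base-pair substitutions.
3. **Hybridization–quenching titrations.** Two-component equilibrium
   binding via the exact quadratic
   `D = [(A+B+Kd) − √((A+B+Kd)² − 4AB)]/2`, with static quenching of the
   bound clamp (`F/F0 = 1 − Q·f_duplex`); a normal-G partner binds but does
   not quench, which is the specificity control.
4. **Single-turnover cleavage.** OGG1's two activities as consecutive
   first-order steps — N-glycosylase (`kg`, oxoG → AP site) then AP lyase
   (`kl`, AP → nicked) — inside an active substrate pool `a`, with closed
   forms for both gel readouts: hot alkali converts AP sites to strand
   breaks, so the treated aliquot reports `a(1 − e^(−kg t))` while the
   untreated aliquot reports the nicked product only.

A synthetic-data module emulates all four instruments (1.4 ms stopped-flow
dead time, log-spaced sampling, seeded Gaussian noise, sigmoidal melting
curves with linear baselines, densitometry fractions), writing ground truth
into metadata so every analysis stage has self-contained recovery tests.

## Worked example

Simulate a stopped-flow series for the oxoG/oxoG-clamp duplex (1 µM duplex,
0.5–4 µM OGG1, 1% noise) and recover the binding constants:

```python
from clampkin import fixtures
from clampkin.globalfit import FitProblem, staged_global_fit
from clampkin.schemes import two_step_binding_scheme
from clampkin.synth import (InstrumentModel, ResponseModel,
                            protocol_design, simulate_trace_set)

scheme = fixtures.binding_scheme("oxoG/oxoG-clamp")
response = ResponseModel(fixtures.RESPONSE_BACKGROUND,
                         dict(fixtures.RESPONSE_COEFFICIENTS))
instrument = InstrumentModel(noise_sd=0.01, seed=13)  # 1.4 ms dead time
traces = simulate_trace_set(scheme, response, instrument, protocol_design())

guess = two_step_binding_scheme(1e7, 100.0, 10.0, 10.0)
result = staged_global_fit(FitProblem(traces, guess, multistart=2, seed=0))
for name, value in result.estimates.items():
    print(f"{name:4s} = {value:10.4g}  +/- {result.stderr[name]:.2g}")
d = result.derived
print(f"K1 = {d.K1:.3g} /M, K2 = {d.K2:.3g}, "
      f"Ka = {d.Ka:.3g} /M (+/- {result.ka_stderr:.2g})")
```

prints

```
k1   =  2.051e+07  +/- 1.3e+06
k_1  =        111  +/- 5.8
k2   =      9.733  +/- 0.44
k_2  =      25.76  +/- 1.3
K1 = 1.85e+05 /M, K2 = 0.378, Ka = 2.55e+05 /M (+/- 8.3e+03)
```

The generator's ground truth for this condition implies
`Ka = 2.5 × 10⁵ M⁻¹`: the bimolecular encounter (`k1`, `k−1`) and the
weak isomerisation equilibrium are recovered from the noisy series, and the
derived overall constant lands within its asymptotic standard error.
Individual isomerisation rates (`k2`, `k−2`) are sloppier than their ratio —
only `K2` enters the equilibrium signal — which the reported standard
errors understate along the flat direction; `Ka` is the robustly
identified quantity.

The same workflow is available from the shell:

```bash
clampkin demo --seed 1 --out demo_run     # all four stages, ~1 minute
clampkin simulate --kind traces --condition oxoG/C --out traces.csv
clampkin melt melting.csv                 # Tm from a melting-curve CSV
clampkin select traces.csv                # stepwise mechanism selection
```

`demo` writes per-stage CSV tables plus `report.txt` with the Ka table and
pairwise ratios (the specific oxoG/C duplex binds ≥ 10× tighter than the
clamp-containing one), the Tm/ΔTm table, the quench-titration summary and
the cleavage fits.

## Layout

- `clampkin.schemes` — kinetic scheme data model, ODE compilation, stiff
  integration, derived equilibrium constants
- `clampkin.synth` — synthetic instrument data for all four experiments
- `clampkin.globalfit` — global fitting, single-exponential diagnostics,
  stepwise mechanism selection, condition comparison
- `clampkin.melting` — baseline correction and derivative-maximum Tm
- `clampkin.hybridization` — binding quadratic and quench model/fitting
- `clampkin.cleavage` — consecutive-reaction closed forms and joint fitting
- `clampkin.fixtures` — study-condition parameter sets (documented as
  synthetic where the study reports only derived quantities)
- `clampkin.pipeline`, `clampkin.cli` — orchestration and the `clampkin`
  command

See `docs/methods.md` for the models, assumptions, parameter choices and
known limitations.
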