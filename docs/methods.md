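# Methods

This note documents the models behind each analysis stage, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices a user fitting real data should know about.

## Mass-action kinetic schemes

A `KineticScheme` is a list of elementary steps, each with at most two
reactants and two products (mass action up to bimolecular) and named rate
constants — bimolecular in M⁻¹ s⁻¹, unimolecular in s⁻¹. Reversible steps
are unrolled into paired irreversible reactions; the stoichiometry matrix
`N` gives `dc/dt = N·v(c)` with `v_j = k_j·Π c_reactants`, and the Jacobian
is assembled analytically from the same structure.

Integration uses LSODA with that Jacobian at `rtol = 1e-8`,
`atol = 1e-12 M`. These are deliberately tight: the binding problems mix
bimolecular rates near 10⁸ M⁻¹ s⁻¹ with unimolecular rates of order
10 s⁻¹, and the conservation checks in the test suite require totals
constant to 1e-9 relative. Concentrations down to −1e-12 M after
integration are treated as round-off and clipped to zero; anything lower
raises, carrying the scheme in the error.

There is no enzyme-regeneration (turnover) step and no temperature
dependence of rate constants: the scope is single-turnover pre-steady-state
binding. Schemes serialize to a plain text block
(`E + S <-> ES ; k1, k_1` plus a `[rates]` section) that round-trips.

### Derived constants

For the two-step binding scheme the package reports `K1 = k1/k−1`,
`K2 = k2/k−2` and the overall association constant

    Ka = K1 (1 + K2) = ([ES] + [ES*]) / ([E][S])  at equilibrium,

i.e. all enzyme-bound species lumped against free species. This is the
standard definition of an overall binding constant for a sequential
two-step mechanism and is validated in the tests by integrating randomized
schemes to steady state and regressing bound against free concentrations
(agreement to 0.1%). Note that the slow relaxation mode of the chain can be
much slower than the smallest rate constant (drain through a sparsely
populated intermediate), so "steady state" in those checks means thousands
of slow-rate time constants, not tens.

## Stopped-flow synthetic data

The emulated instrument mixes enzyme and duplex at t = 0, observes
fluorescence from 1.4 ms (the mixer dead time — nothing earlier is ever
emitted) on a 400-point log-spaced grid to 1 s, and adds Gaussian noise
whose standard deviation is a stated fraction (default 1%) of the
full-scale signal of the trace set. The response model is linear:
`F(t) = background + Σ c_species·[species](t)`, with the free
clamp-labelled duplex bright and enzyme-bound species dimmer.

Two concentration designs are built in:

- `protocol_design()`: duplex fixed at 1 µM, enzyme at 0.5/1/2/4 µM. This
  is the written measurement protocol, and it is the design used for
  recovery analyses: sweeping the enzyme almost a decade moves both the
  observed relaxation rate (`kobs ≈ k1(E+S) + k−1`) and the equilibrium
  bound fraction strongly, which is what identifies the shared rate
  constants.
- `default_design()`: enzyme 1 µM, duplex 0.4/0.8/1.2/1.6 µM (the figure
  design). Under weak binding (`Ka·C ≲ 0.3`) this narrow sweep leaves the
  likelihood for `Ka` nearly flat along a (rate, response-amplitude) ridge;
  it is provided for completeness but not used for parameter recovery.

The bound-species response coefficients default to 70% and 60% of the free
substrate's (`fixtures.RESPONSE_COEFFICIENTS`). At the partial occupancies
reached in the weak-binding conditions this produces a total signal change
of a few percent — a modest quench, matching the qualitative observation —
while keeping the kinetic amplitude resolvable above 1% instrument noise.
A Fisher-information analysis of the design fixed this level: at 10%-level
per-species dimming the overall binding constant is unidentifiable at that
noise (SE above 50%), at 30–40% dimming it is identified to ~10%.

What the generator does **not** model: photobleaching, inner-filter
effects, instrument drift, curve-to-curve averaging artifacts, or any
response nonlinearity. Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to those
real-instrument effects.

## Global fitting and mechanism selection

The fit minimises summed squared residuals over all traces simultaneously.
Nonlinear parameters are the logarithms of the free rate constants
(positive, spanning decades), searched with scipy's trust-region reflective
`least_squares` inside wide bounds (1e-4–1e12). The linear observation
parameters — one background offset per trace and one response increment per
bound species shared across the set — are profiled out at every function
evaluation by linear least squares (variable projection), which removes six
parameters from the nonlinear search and makes the response-rescaling
invariance (`SSR → c²·SSR`, rates unchanged) exact by construction.

The model is integrated from t = 0, but residuals are evaluated only at
sample times at or beyond the dead time: the unobserved pre-dead-time
evolution is thereby absorbed correctly rather than re-zeroed.

Plain multi-start (seeded log-space perturbations, sd 0.5 decades·ln10)
is not sufficient on these surfaces: direct full-window fits can fall into
a fast-equilibrium attractor where `k1` and `k−1` diverge together with
only their ratio pinned. `staged_global_fit` therefore mirrors the
experimental protocol — fit the initial, single-exponential part of the
curves first (default windows 0.02, 0.2, 1.0 s), warm-starting each
expansion — and runs that schedule from two start policies: the caller's
guesses and rates seeded by regressing per-trace single-exponential `kobs`
on total concentration (slope → k1, intercept → k−1). The candidate with
the lowest full-window SSR wins.

Standard errors are asymptotic, from the full (nonlinear + linear) numeric
Jacobian at the optimum; the SE of `Ka` follows by the delta method on the
log-rate covariance. On sloppy directions (typically `k2` vs `k−2`
individually) the local quadratic approximation understates the true
spread — `Ka` is the quantity these designs identify robustly, and the
Monte-Carlo tests check exactly that. A numerically singular Jacobian is
reported with the dominant unidentifiable parameter named, never silently.

Mechanism selection fits the current candidate at each window of an
increasing schedule and admits one more reversible step only when the
extra-sum-of-squares F-test rejects the smaller nested model at
α = 0.01 (AIC-style comparisons would behave similarly; the F-test is the
conventional choice for nested least-squares kinetic models). Selection
terminates when the full window is described without rejection; the report
records every comparison. Within selection, per-stage optimizer effort is
capped (80 function evaluations): unidentifiable expansions converge
slowly, and the F-test only needs the SSR improvement, which saturates
early.

## Melting curves and Tm estimation

The generator uses a non-self-complementary two-state model, `A + B ⇌ AB`
at equal strand totals `Cs` (default 2 µM each): the van't Hoff constant is
anchored so that the duplex fraction θ(Tm) = 1/2, which fixes
`K(Tm) = 2/Cs` and eliminates ΔS:

    K(T) = (2/Cs)·exp[(−ΔH/R)(1/T − 1/Tm)],  T in kelvin.

θ(T) is then the exact root of the same binding quadratic used for the
titration model. Absorbance per wavelength is
`ds(T)·θ + ss(T)·(1−θ) + noise` with linear single- and double-strand
baselines; the 330 nm channel carries only its baseline (nucleic acids do
not absorb there) and emulates the drift reference. The default dissociation
enthalpy is −350 kJ/mol, a typical value for a 13-mer duplex; default noise
is 0.002 a.u.

Analysis subtracts the 330 nm series pointwise from the UV channels
(recording the correction; a missing reference warns and skips, or can be
made a hard error), smooths and differentiates with a Savitzky–Golay filter,
and takes the temperature of the maximum absolute derivative per channel,
refined by the vertex of a parabola fit over ±7 grid points of the peak.
The consensus Tm is the unweighted mean of the 260 and 270 nm estimates
(the study protocol does not say whether the two wavelengths were averaged;
per-channel values are always reported alongside).

Two numerical choices deserve emphasis:

- **Smoothing window.** The default is 25 points (~12 °C at the 0.5 °C
  grid), wider than the conventional "a few degrees" rule. The derivative
  peak of these broad (~6–8 °C) bimolecular transitions is flat-topped; at
  0.2% noise a 3-point parabola on an 11-point-smoothed derivative wobbles
  by up to ±1.6 °C, while the 25-point window with the wide vertex fit
  brings the seed-to-seed spread to ~0.1–0.15 °C (sd) with worst-case
  anchor error 0.7 °C in a 20-seed check at the fixture conditions.
- **Estimator bias.** For this transition shape the true maximum-slope
  temperature lies intrinsically above the θ = 1/2 anchor — by +1.1 °C at
  ΔH = −350 kJ/mol on an unsmoothed fine grid — and heavier smoothing of
  the asymmetric peak partially re-centres it (≈ +0.4 °C net at the
  defaults). The bias largely cancels in ΔTm comparisons between duplexes
  of similar ΔH, which is how the pipeline's stability differences are
  reported. At ΔH = −250 kJ/mol the intrinsic bias exceeds 1 °C; recovery
  of the anchor temperature to ±1 °C should not be expected for such broad
  transitions, and the tests separate precision (noisy vs noiseless
  estimate) from bias accordingly.

A transition is reported only when the derivative peak rises at least
threefold above the median absolute derivative; a monotone (baseline-only)
curve raises "no transition detected". No ΔH/ΔS extraction, hysteresis
analysis or multi-transition deconvolution is attempted.

## Hybridization quenching

Quenching is a two-state static mixture: bound clamp partially dark, free
clamp bright, `F/F0 = 1 − Q·f_duplex(A, B, Kd)`, with no dynamic-quenching
term — the simplest model consistent with an equilibrium titration. The
bound fraction is the exact quadratic root in its cancellation-safe form
(`2AB/(A+B+Kd+√((A+B+Kd)²−4AB))`), accurate for `Kd` ten orders of
magnitude below the strand totals. Buffer and ionic-strength effects are
not parameters; they are absorbed into `Kd` and `Q`. A normal-G partner is
modelled with `Q = 0` exactly: it binds but does not quench.

The fixture values (`Kd = 0.1 µM`, `Q = 0.221`) reproduce a 20.0%
fluorescence decrease at the equimolar point of a 10 µM titration, with the
response saturating past 2× excess (< 0.5 percentage points further change
from 2× to 3×). Fitting warns when every titration point is saturating:
`Kd` and `Q` are then nearly collinear and the fitted `Kd` is only a lower
bound.

## Cleavage kinetics

Single-turnover conditions justify lumping binding into the first-order
chemistry constants: `intact → AP → nicked` with rates `kg` (N-glycosylase)
and `kl` (AP lyase), inside an active pool `a`. The closed forms are the
classic consecutive-reaction solutions, with the removable singularity at
`kl = kg` handled by the limit form `a·kg·t·e^(−kg t)` inside a relative
separation of 1e-9 (the general branch is itself cancellation-safe down to
~1e-13). The incomplete plateau is an amplitude (`a`), not a reversible
step: single-turnover gels plateau below 100% because a fraction of
substrate is never processed. Lyase stimulation by 8-bromoguanine is a pure
multiplier on `kl`; no product-assisted-catalysis mechanism is modelled.

The alkali-treated readout is `AP + nicked = a(1 − e^(−kg t))` — alkali
converts every AP site to a strand break, so the treated aliquot reports
pure glycosylase progress — and the untreated readout is the nicked product
only. Joint fitting shares `(kg, kl, a)` across both readouts, in log-rate
space with `a ∈ [0, 1]`. Gel time points are log-spaced (default
30 s – 2 h), the natural sampling for exponential progress curves. Null
data are flagged, not fudged: all-zero readouts return `kg = 0` with the
amplitude marked unidentifiable, and a fit whose implied plateau is within
3 residual standard deviations of zero is flagged `no_cleavage_detected`
(pure noise otherwise fits an arbitrary rate with a tiny amplitude).

The oxoG/C fixture (`kg = 2e-3 s⁻¹`, `kl = 2.5e-4 s⁻¹`, `a = 0.55`) gives
55.0% in the alkali readout and 44.6% nicked at 2 h; the clamp-opposite
condition is the null (`kg = 0`).

## Fixtures and problem sizes

The study reports derived quantities (overall binding constants, melting
temperatures, percent quench/cleavage) but not elementary rate constants;
`clampkin.fixtures` therefore carries synthetic parameter sets constructed
so the derived quantity each implies equals the reported value, with the
reported values stored alongside. Recovery analyses then close the loop:
generate data at the fixture, analyse it blind, and compare with the
reported number.

Problem sizes in the tests and demo are chosen to keep a full run on one
CPU in minutes: 4-trace sets of 150–400 points for the binding fits,
10 seeds per direction for selection consistency, 20-seed Monte-Carlo
checks where each fit is cheap (titration, cleavage) and 8-seed checks for
the ODE fits. The demo pipeline (all four stages at defaults) completes in
about a minute.

## Known limitations

- Asymptotic standard errors understate uncertainty along sloppy
  directions (`k2`/`k−2` individually); trust `Ka` and its Monte-Carlo
  behaviour instead. No Bayesian posterior sampling is provided.
- The narrow figure-style concentration design does not identify `Ka`
  under weak binding at 1% noise; use the enzyme-varied protocol design.
- The derivative-maximum Tm is a biased estimator of the two-state anchor
  temperature (documented above); it is the operational quantity, and ΔTm
  is the robust comparison.
- The mechanism search only distinguishes nested one- vs two-step binding
  schemes by default; branched or parallel mechanisms are out of scope.
- The quench model cannot separate steric from buffer contributions to
  `Q` and `Kd`; they are effective parameters.
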