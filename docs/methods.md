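# Methods

## Plant model

The gas path is modelled as two well-mixed compartments in series. Air
(21% O2) and nitrogen (99.996% pure, i.e. a residual O2 fraction of 4×10⁻⁵)
enter through three valves — a proportional nitrogen valve, an on-off air
valve, and a small proportional air valve — whose flows mix by mass balance:

    Q = Σ qᵢ,     C_in = Σ qᵢ Cᵢ / Q.

The mixed stream passes through the antechamber (0.05 L) and then the cage
(12.4 L geometric volume). The cage outlet is open, so volumetric outflow
equals inflow and pressure dynamics are ignored; supply pressures (2 bar N2,
1.2 bar air) enter only through the configured maximum valve flows, and total
delivered flow is capped at 50 L/min (flows are scaled down proportionally if
the commanded sum exceeds the cap). Each compartment follows the dilution ODE

    dC/dt = (Q/V_eff)(C_in − C),

integrated with fixed-step explicit Euler at dt = 0.01 s with a hard guard
`Q·dt/V_eff < 1` (the step would otherwise leave the containment interval).
A closed-form solution, `analytic_dilution`, serves as the integration
oracle; at the default step the integrator stays within 10⁻⁴ O2 fraction of
it over 300 s.

**Effective mixing volume.** `V_eff = volume × mixing_factor`. A single
well-mixed cage volume of 12.4 L at 50 L/min has a 14.9 s dilution time
constant and cannot reach 5.7% from 21% in under 5 s, yet the physical rig
does: its lid-mounted sensor sits near the gas inlet and equilibrates with a
smaller, faster region than the full cage, and the muffler distributes flow
unevenly in a way no lumped model captures. The cage mixing factor (default,
calibrated: 0.207, i.e. ≈2.6 L effective) absorbs this; it is the twin's main
geometric calibration parameter. The antechamber keeps factor 1.0. The
humidifier arm carries the same composition as the main arm and humidity is
not modelled.

**Sensors.** Each electrochemical cell is a first-order lag (`τ` seconds)
followed by additive Gaussian noise (σ = 5×10⁻⁴ O2 fraction) and uniform ADC
quantization (10 bits over a 0–25% O2 span, one sample per 0.1 s). Response
times of the physical cells are not published; the antechamber sensor
defaults to τ = 0.5 s, and the cage sensor's lag is a calibration parameter
(calibrated: 4.25 s — electrochemical O2 cells of this class are seconds-slow,
and this lag is what shapes the simulated undershoot depth).

## Controller

The regulator runs at the 0.1 s sensor sample period, not the plant step,
and has three cooperating parts:

1. **Setpoint FSM** — alternates between two O2 levels over two period
   lengths (defaults: 5.7% for 90 s, then 21% for 90 s), wrapping
   indefinitely within a session.
2. **PID flow demand on the cage error** — `u = clamp(kp·e + ki·∫e + kd·ė)`
   with `e = cage reading − setpoint`, output in [−1, 1], integral clamped
   to ±limit and frozen while the output is saturated outward (conditional
   anti-windup). `u > 0` opens the nitrogen valve proportionally; `u < 0` is
   air demand: above a 0.5 threshold it opens the on-off air valve (fast
   elevation back to normoxia), below it rides on the small proportional
   valve.
3. **Antechamber mix trim + flow-off latch** — an integral trim
   (gain 5×10⁻⁴ per %·s) opens the small air valve while the premixed
   composition reads below the setpoint, steering the delivered mix toward
   the set level during sustained nitrogen pushes; and when the cage reading
   is within the gating band of the setpoint (±0.2 points, 0.05-point
   hysteresis on exit) both main valves close and the PID memory is held.
   The small valve never closes below `min_command` (calibrated: 0.03 of an
   8.8 L/min valve), which is the undershoot-mitigation device: during the
   nitrogen purge it keeps a floor of air in the mix, so the cage bottoms
   out higher than it would with the valve shut.

The choice to drive the PID from the cage sensor and the mix trim from the
antechamber sensor (rather than a single antechamber-driven loop) is the
design decision that makes the published transient reproducible: a single
antechamber loop regulates the premix to the set level at near-zero total
flow, which leaves the cage far from the setpoint for minutes, and any
latch-driven refill then re-opens the valves against a fully air-flushed
antechamber, producing repeated deep dips instead of a quiet hold. With the
cage driving the flow demand, the descent runs at full nitrogen flow until
the (lagged) cage reading approaches the set level, the latch then cuts the
main valves, and the small valve's floor plus sub-threshold air demand
recovers the undershoot on the observed ~10 s timescale.

## Step-response metrics and calibration

Four metrics summarize a downward step, extracted from the *true* cage trace
with linear interpolation between samples (exact on piecewise-linear test
traces):

* **time to target** — first crossing of the set level. Together with the
  settle time this encodes two distinct operational readings of "fast":
  a rig can *reach* hypoxia within seconds yet need tens of seconds for the
  trace to *stay* at the set level.
* **settle time** — start of the final interval contained in
  setpoint ± band with no later exit (band default 0.5 points; the width is
  a documented choice, configurable, since bench reports rarely state one).
* **undershoot duration** — length of the maximal contiguous excursion below
  setpoint − band.
* **undershoot nadir** — minimum O2 within that excursion.

Missing features give NaN sentinels. Upward steps are mirrored.

Calibration identifies the free parameters (cage mixing factor, cage sensor
lag, small-valve maximum flow, kp, ki, `min_command`; bounds in the config)
by minimizing the weighted sum of squared *relative* metric residuals, so
seconds and percentage points are commensurable; a zero-valued target falls
back to an absolute residual. The search is multi-start Nelder–Mead
(default 8 starts: the current configuration plus seeded uniform draws), with
two chained simplex runs per start because the tick-quantized metrics make
the objective piecewise constant at fine scales and a fresh simplex escapes
those plateaus. The sensor-noise stream is held fixed across objective
evaluations so the objective is deterministic given the seed. A missing
metric contributes a large finite penalty (25) so the simplex can leave
featureless regions. Self-consistency is verified by parameter-recovery
experiments: parameter sets drawn within bounds are recovered from 5%-
perturbed starts to within 5% on all four metrics.

The shipped default configuration is the output of this calibration against
the target transient (reach ≤ 5 s — targeted at 4.5 s to stay inside the
bound, settle 27 s, undershoot 12 s, nadir 2% O2); one parameter set
reproduces all four jointly, and does so across independent sensor-noise
seeds.

## Protocol scheduling and exposure analytics

Sessions are anchored at hour 7 of each day — the start of the light phase,
when mice predominantly sleep — and always begin with the hypoxic phase
(the source protocol does not say which phase led; one had to be fixed).
The reference protocol yields exactly 160 complete 180 s cycles per 8 h
session over 21 days; a final partial cycle is truncated at the session
boundary so total in-session time is exact. Exposure summaries count
desaturation events as maximal runs of cage O2 below a threshold on the
output grid, with total time below threshold, mean event nadir and a per-day
breakdown.

## Validation statistics

Apoptotic-neuron counts live on a per-animal, per-region grid: two
conditions (IH, CTRL) × three hippocampal subfields (CA1, CA3, DG). A count
over `n` sections of a 280×280 µm frame on 35 µm sections converts to a
density `count / (0.28² · 0.035 · n)` neurons/mm³; counts are pooled across
the four sampled sections per animal (whether the source pooled or averaged
per section is unstated; pooling is the default here and only rescales the
density by a constant).

**Generator.** Counts are negative binomial (gamma-Poisson) with mean
`baseline × multiplier` and shape `dispersion` (variance μ + μ²/r;
r → ∞ recovers Poisson). Raw stereological counts are small integers, for
which Poisson-type overdispersion is the natural family — normality is an
assumption of the downstream ANOVA, not something the generator imposes.
Defaults mirror the validation study design: n = 8 IH / 7 CTRL animals, a
1.3× condition effect applied to every region of the IH group, baselines
CA1 = CA3 = 10 and DG = 20 counts per pooled frame (the DG baseline is set
above the CA subfields to reproduce the reported regional ordering; absolute
levels are unpublished, so these are round numbers at a realistic count
scale), dispersion r = 10 (moderate overdispersion, CV ≈ 36% at μ = 10,
typical of between-animal histology variation).

**Inference.** One-way ANOVA over the six condition×region cells uses the
classical decomposition (F from between/within sums of squares; degenerate
zero-variance inputs return F = 0, p = 1 when the between-group variance is
also zero). Pairwise comparisons are two-sided t tests adjusted by the
Holm–Šidák step-down rule: the k-th smallest of m raw p-values becomes
`1 − (1 − p)^(m−k+1)`, with running-maximum monotonicity enforcement and
stable ordering for ties. Two comparison families are predefined: the
primary condition contrasts (IH vs CTRL within each region, m = 3) and the
regional contrasts within each condition (m = 6). Each pairwise t pools the
variance of its two cells only (df = nₐ+n_b−2) by default; pooling the
omnibus mean square instead (available as `variance="pooled"`) inflates the
family-wise error of the condition contrasts above nominal when regional
variances differ — with count data they always do, since the variance grows
with the mean — measured at 0.076 vs 0.048 over 1000 null replicates at the
study's group sizes. A two-way (condition × region) table via statsmodels
OLS is provided because the source description does not say whether the
design was analysed one- or two-way; the one-way-by-cells route is the
default. Shapiro–Wilk normality screening is out of scope.

Calibration of the pipeline is checked, not assumed: under the null
generator the family-wise false-positive rate over 1000 seeded replicates
stays below 0.07, and under the 1.3× generator the mean recovered IH/CTRL
density ratio over 1000 replicates lies in [1.25, 1.35].

## What the synthetic data do and do not show

The generator reproduces the *design* of the validation experiment (group
sizes, regional baseline ordering, effect size, count scale) — not its data,
which are unpublished. Passing recovery and error-control checks therefore
demonstrates that the pipeline is statistically sound at the study's sample
sizes, not that the biological effect itself is re-derived. Real counting
data add features the generator omits: section-to-section correlation within
an animal, observer effects, possible zero inflation, and region-dependent
dispersion.

## Numerical choices and degenerate inputs

* Plant integration: explicit Euler, dt = 0.01 s, stability guard
  `Q·dt/V < 1`; controller tick 0.1 s tiles exactly onto plant steps.
* Sensor lag with τ = 0 is an identity; a lag faster than the step snaps to
  the input rather than overshooting.
* Zero total flow freezes compartment composition and returns a NaN
  sentinel for the (undefined) mixed inflow fraction.
* Metric extraction interpolates crossings linearly; a flat trace at the
  setpoint returns all-NaN rather than raising.
* All randomness flows from a single integer seed per run (sensor noise,
  calibration starts, count generation); identical seed + configuration
  gives bit-identical outputs, and every artifact embeds the config hash and
  seed.

## Known limitations

* The mixing factor is a lumped stand-in for spatial inhomogeneity; it is
  calibrated to the step response and should not be interpreted as a
  physical volume.
* CO2 accumulation, humidity, temperature and animal O2 consumption are not
  modelled; the hold phase in the twin is quieter than a cage with animals
  would be.
* The firmware's exact valve logic is unpublished; the cascade implemented
  here reproduces the published transient but is one of several control
  structures that could.
* Calibration minimizes four scalar metrics, not the full trace; parameter
  sets are identifiable only up to trade-offs that leave those metrics
  unchanged.
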