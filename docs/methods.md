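# Methods

## The monitoring model

`linacpdm` implements a predictive-maintenance (PdM) pipeline for medical
linear accelerators built on statistical process control of daily QA delivery
logs: (1) a fixed VMAT QA treatment is delivered every day; (2) the resulting
log files are ingested and decoded; (3) once a baseline is established, each
day's operating and performance values are charted; (4) windowed rules decide
warnings and alarms; (5) status is rolled up for the physics and service
teams. The working hypothesis is that a healthy accelerator's operating
parameters vary randomly about stable means, so a non-random deviation —
a step change or drift — is an early sign of component dysfunction that can
be serviced before an interlock ends clinical operation.

Two log files are produced per delivery:

* a **text log**: one snapshot of 45 named scalars (voltages, currents,
  temperatures, pressures) at the start of delivery, of which 35 are
  monitored;
* a **trajectory log**: 131 axis positions sampled every 20 ms throughout
  the delivery. 127 axes are monitored (gantry, four jaws, two MLC
  carriages, 120 MLC leaves); the four couch axes are recorded but excluded
  because the QA delivery does not move the couch.

Feature extraction reduces each day's pair to **525 monitored parameters**:
the 35 text values verbatim, a position per jaw/carriage (averaged over a
designed-static window), and per moving axis (gantry and each leaf) two
segment speeds plus two cross-correlation fidelity metrics, giving
35 + 4 + 2 + 4 + 120×4 = 525. Of the 490 trajectory-derived parameters,
482 are MLC-related (480 leaf metrics + 2 carriage positions).

### Segment speeds

Axis velocity over a designed window `[s, e)` is positional change over
time, `(x[e] − x[s]) / ((e − s)·Δt)` with Δt = 20 ms, sign preserved. The
default windows sit on the events that stress the machine hardest: gantry
snapshots 10–760 and 4120–4250 (maximal gantry speed), leaf snapshots
1780–1830 and 4115–4165 (maximum-speed gap displacements ending in an
abrupt halt).

### Cross-correlation fidelity

Positional/timing fidelity of the gantry and each leaf is scored against a
stored reference trace over a baseline window (gantry 2525–3350, leaves
2450–3200). For every lag in ±50 snapshots the day's window is compared
with the reference by zero-mean, unit-norm (Pearson) correlation; the chart
receives the maximum value (unitless, in [−1, 1]) and its lag (snapshots,
positive = the day's motion is delayed). Normalization makes the maximum an
interpretable fidelity score and renders the metric invariant to affine
transforms of the trace (gain/offset drift in the position encoder does not
masquerade as a timing fault). Ties are broken toward the smallest |lag|
(then the negative lag), so a perfect match reports lag 0 deterministically.
A zero-variance window or reference raises a degenerate-input error rather
than silently reporting zero. The reference defaults to the first in-control
baseline day's own trace; any stored trace in the trajectory dialect can be
substituted.

## Hybrid I/MR control charts

With one delivery per day the natural subgroup size is n = 1, hence
Individuals/Moving-Range charts with MR_t = |I_t − I_{t+1}|. From a baseline
of T points (default T = 20): grand mean Ī, mean moving range M̄R, and

```
I chart:   UCL/LCL = Ī ± [E2·M̄R + S_p],     3σ_(I)hybrid = E2·M̄R + S_p
MR chart:  UCL     = D4·M̄R + S_p,  LCL = D3·M̄R = 0,
           3σ_(R)hybrid = D4·M̄R + S_p
```

with the standard n = 2 constants E2 = 2.660, D3 = 0, D4 = 3.267. Classical
3σ limits on 525 parameters × machine-days yield an unacceptable
false-positive load, so each parameter's limit is inflated by a
specification-derived constant **S_p**: up to 10 % of the manufacturer's
operating range, up to 1 % of a published QC value/range, or an empirically
chosen constant (these caps are enforced at rule construction). S_p ≥ 0
strictly widens both charts and can only demote classifications, never
escalate them — a property the test suite checks on paired seeded streams.

Warning thresholds sit at two thirds of the hybrid 3σ distance ("2σ_hybrid");
for the MR chart the thresholds are measured from the chart floor (LCL = 0).
All comparisons are inclusive (≥).

### Run rules

* I chart — **alarm**: 2-of-3 or 3-of-5 consecutive points at ≥ 3σ_hybrid on
  the same side of the centerline; **warning**: the same windows at
  ≥ 2σ_hybrid.
* MR chart — **alarm**: 3-of-5 at ≥ 3σ_hybrid (upper side only); **warning**:
  3-of-5 at ≥ 2σ_hybrid.

Windows slide over consecutive *monitored* points: calendar gaps and missing
(non-finite) values are skipped, since log gaps are routine. A k-of-m rule
fires as soon as k qualifying points fall within a span of at most m
consecutive points; a monitored run shorter than m is evaluated as a single
truncated window, so e.g. two consecutive 3σ points alarm immediately rather
than waiting for a third observation. The rule engine is verified against an
independent exhaustive window-enumeration oracle (complete over all
sequences whose length covers every window shape, plus seeded random longer
runs).

### Degenerate charts and rebaselining

If E2·M̄R + S_p = 0 (constant baseline, zero S_p) the chart is flagged
degenerate and points are recorded unclassified until noise is observed —
the documented all-noiseless pipeline exercises exactly this path. After a
repair or adjustment the chart is rebaselined from the most recent n ≥ 2
points; the new limits govern the latest point and all future points while
earlier classifications are preserved as recorded.

## Status rollup and reporting

Each of the nine operational groups (RF generation, electron gun,
bending & energy, beam steering & uniformity, DC power supplies,
cooling & gas, collimation, gantry, MLC) is colored red if any member chart
is in alarm, orange if any warns and none alarms, green otherwise. The hot
list contains exactly the parameters in alarm, ordered by severity then id.
"Current" counts (alarms, beyond-limit points) cover the last ten monitored
points — two working weeks of daily deliveries. Reports are static text (or
a plain HTML wrapping) with per-parameter chart tables, a frequency
distribution of the individuals, a statistical summary and dated user
comments; regeneration from identical state is byte-identical, with any
timestamp injected by the caller. The nine-group assignment of individual
text parameters is shipped as documented configuration, not ground truth.

## The synthetic machine

The generator emulates the QA delivery and the machine's random variation;
its defaults define the study conditions used throughout the tests.

**Delivery plan** (4500 snapshots × 20 ms = 90 s): the gantry runs 4 deg/s
sectors under both speed windows with linear acceleration/deceleration ramps
between sectors; each leaf holds a static gap, performs a +2.5 cm/s
displacement under speed window 1, a small triangular excursion inside the
CC window, and a −2.5 cm/s return under speed window 2; jaws at ±5/±5.5 cm,
carriages at ±1 cm, couch static. The gantry's CC sector is nominally
1 deg/s with a brief 0.4 deg/s dose-rate notch (snapshots 2700–2900) inside
the CC baseline window: a strictly linear trace correlates equally at every
lag, which would leave the cross-correlation lag undefined, so the notch is
what makes timing faults identifiable. Position traces are built by
left-endpoint integration of the piecewise speed profile, so a constant-speed
window integrates to exactly v·Δt per snapshot and an abrupt halt does not
bleed into the next sample. A `scale` divisor compresses every index
(plan and extraction windows together) for fast multi-day tests; the
full-scale geometry is the study condition.

**Noise**: independent per-snapshot Gaussian positional noise — 0.05 deg
(gantry), 0.02 cm (leaves, jaws, carriages), couch held — and Gaussian noise
per text value with optional linear drift. Where the fault table specifies a
deviation as "1 STD" of the fleet operating value, the corresponding noise σ
is pinned to that same printed value (RF driver 0.5 V, gun high voltage
559 V, target current 11 nC, …); the remaining nominals and σ are fixed,
field-realistic choices recorded in `_defaults.py`. All randomness derives
from a seed via per-(day, axis) substreams, so a single axis can be
regenerated bit-identically — the fault injector uses this so an injected
day differs from its in-control twin by exactly the injected deviation.

**Fault injection** supports three modes: `add_shift` (constant offset on a
value or axis; on a *speed* parameter it is realized physically, as a ramp of
the given slope across the speed window, held afterwards — re-timing the
trace rather than editing the extracted number), `time_shift_snapshots`
(whole-snapshot trace delay with edge-value hold), and `scale`
(multiplicative). Injections are local to their target; any coupling between
extracted metrics of the same axis (e.g. a trace delay moving both CC
metrics) is mathematical, not code-induced.

**The default suite** has 45 scenarios: the 35 text rows of the published
deviation table (two of them zero-magnitude negative controls), the four
jaws and two carriages at +0.2 cm, gantry speed +0.2 deg/s, a 10-snapshot
gantry trace delay, leaf speed +0.1 cm/s and a 2-snapshot leaf trace delay
(the MLC scenarios act on all 120 leaves of both banks as one scenario
each; `per_bank=True` splits them for a per-bank accounting, 47 scenarios).

**The detection study** simulates a shared in-control history (default
20 baseline + 30 monitored days), injects each scenario from its onset day
(sustained by default), charts only the scenario's related parameters and
records two verdicts per scenario: single-point limit exceedance on any
related I and/or MR chart (the headline detection criterion) and the
windowed alarm rules, each with its first signal day. End-to-end seeded
determinism — identical seeds, identical tables — is an acceptance test.

### What the generator does not emulate

Real accelerator baselines carry autocorrelated drift, thermal transients,
servo quantization and occasional re-tuning; the synthetic machine's noise
is white and Gaussian by design (that is the model's own operating
assumption). Published fleet detection rates were measured against real
baselines whose noise characteristics are not public, so this package's
detection table is a property-preserving re-enactment, not a reproduction:
passing tests demonstrate the pipeline's mechanics (extraction identities,
limit math, rule behaviour, locality, determinism), not field sensitivity.
Dose, imaging and beam-generation physics are out of scope: text-log values
are modeled as noisy scalars, not derived from a machine model.

## Numerical choices

* Log dialects write shortest round-trip decimals (`repr`), so
  write∘read is bit-identical and noiseless simulator output survives a
  file round-trip exactly.
* Cross-correlation evaluates lags in order of increasing |lag| with strict
  improvement, implementing the documented tie-break without a second pass.
* Segment windows are half-open `[start, end)` for duration arithmetic with
  0-based snapshot indices; the velocity quotient uses `end − start`
  snapshots.
* Chart thresholds compare inclusively (≥); single-point limit exceedance in
  the detection study is likewise inclusive.
* `baseline_stats` requires ≥ 2 finite values; rebaselining requires
  2 ≤ n ≤ recorded points.
* The false-alarm sanity check uses a long (2000-point) baseline so the
  estimated limits converge to the classical 3σ and the observed per-point
  beyond-limit rate can be compared against 0.27 % with a binomial
  tolerance; short baselines (T = 20) have noticeably heavier estimation
  tails, which is expected and untested.

## Known limitations

* The 35 text parameters' nominals, noise and S_p rules are a documented
  synthetic commissioning choice; on a real machine they must be fitted to
  fleet data and the manufacturer's specifications.
* Detection of one-standard-deviation text shifts under classical limits
  (S_p = 0) is genuinely marginal over 30 monitored days — several such
  scenarios report "not detected" in the shipped study, which is the honest
  behaviour of the criterion at those signal-to-noise ratios.
* Only the I/MR rule families described above are implemented; CUSUM/EWMA
  and the full Western Electric set are deliberate non-goals.
* One state directory assumes a single writer; there is no concurrency
  control.
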