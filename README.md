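# linacpdm

Predictive maintenance (PdM) for medical linear accelerators. Unscheduled
linac downtime interrupts radiotherapy courses; component failure is often
preceded by a gradual, measurable drift in operating parameters. `linacpdm`
turns the log files of a fixed daily VMAT QA delivery into a per-machine
statistical surveillance system for medical physicists and service
engineers: ingest the day's logs, chart 525 operating/performance
parameters, and raise warnings/alarms before an interlock does.

## What it monitors

Each delivery writes two logs: a **text log** (one snapshot of 45 operating
values — PFN/gun/bend-magnet voltages and currents, symmetry, DC supplies,
cooling; 35 monitored) and a **trajectory log** (131 axis positions every
20 ms; 127 monitored — gantry, 4 jaws, 2 carriages, 120 MLC leaves; couch
recorded but excluded). Feature extraction yields, per day:

* the 35 text values verbatim,
* jaw/carriage positions averaged over a designed-static window,
* two segment speeds for the gantry and for every leaf (positional change
  over time across maximal-speed windows of the delivery),
* two cross-correlation fidelity metrics per moving axis against a stored
  reference trace: max normalized correlation and its lag,

for 35 + 490 = 525 parameters, each on an Individuals/Moving-Range chart
(subgroup n = 1, baseline T = 20) with *hybrid* limits

    I chart:  UCL/LCL = Ī ± [E₂·M̄R + Sₚ]        (E₂ = 2.660)
    MR chart: UCL = D₄·M̄R + Sₚ,  LCL = D₃·M̄R = 0 (D₄ = 3.267, D₃ = 0)

where Sₚ inflates the classical 3σ limit from the parameter's specification:
up to 10 % of the operating range, up to 1 % of a published QC value, or an
empirical constant. Alarms are 2-of-3 / 3-of-5 consecutive points at
≥ 3σ_hybrid (same side, I chart; upper side 3-of-5 for MR), warnings the
same windows at ≥ 2σ_hybrid. A seeded synthetic-machine module generates
realistic log pairs and re-enacts a 45-scenario fault-injection study.

## Worked example

Chart a PFN voltage-like baseline of 20 daily values and compute its hybrid
limits with Sₚ = 0.1:

```python
from linacpdm import baseline_stats, individual_limits, mr_limits

values = [99.2, 100.1, 99.7, 100.4, 99.9, 100.0, 99.5, 100.2, 99.8, 100.3,
          100.0, 99.6, 100.1, 99.9, 100.2, 99.7, 100.0, 99.8, 100.1, 99.9]
gm, mrs, mrm = baseline_stats(values)
ilim = individual_limits(gm, mrm, sp=0.1)
mlim = mr_limits(mrm, sp=0.1)
```

prints (via the obvious f-strings):

```
grand mean Ibar   = 99.9200
mean moving range = 0.4158
I chart : UCL 101.1260  LCL 98.7140  (3 sigma_hybrid 1.2060)
MR chart: UCL 1.4584  LCL 0.0000
```

i.e. the centerline is the 20-day mean, the hybrid half-width is
E₂·M̄R + Sₚ = 2.660·0.4158 + 0.1 = 1.206, and the MR chart's lower limit is
identically zero. A new day at 101.2 would be flagged ≥ 3σ_hybrid; two such
days within any three consecutive points raise an alarm.

Run the full synthetic fault-injection study from the CLI:

```bash
$ pdm detect-study --seed 11 --out table.csv
45 scenarios; 37/43 non-control deviations detected (86.0 %); table -> table.csv
```

The CSV has one row per scenario (parameter, error description, level,
I/MR detection verdicts, first signal day). The 43 non-control scenarios are
sustained shifts/scalings/trace-delays at the published magnitudes; the two
zero-magnitude rows (gun current, water level) are negative controls and
stay undetected. One-standard-deviation text shifts under classical limits
are genuinely marginal at this horizon, hence a detection fraction below
one — see `docs/methods.md` for what this study does and does not show.

Daily operation is the same pipeline incrementally:

```bash
pdm init   --machine TB01 --root state/
pdm simulate --days 25 --seed 7 --out logs/        # or real exported logs
pdm ingest --machine TB01 --root state/ --tlog logs/SIM01-2026-01-05.tlog.csv \
           --ttxt logs/SIM01-2026-01-05.ttxt
pdm status --machine TB01 --root state/            # exit 0 green / 1 warning / 2 alarm
pdm report --machine TB01 --root state/ --out reports/
pdm rebaseline --machine TB01 --root state/ --param pfn_voltage --n 20
```

`status` prints the nine-group red/orange/green rollup and the hot list of
parameters in alarm; `report` writes a static text/HTML document with chart
tables, frequency distributions and comments.

## Layout

```
src/linacpdm/
  registry.py   the 525-parameter schema and Sp rules
  logio.py      text/trajectory log dialects (see docs/formats.md)
  features.py   speeds, cross-correlation, daily sample extraction
  spc.py        hybrid I/MR charts, run rules, rebaselining
  simulate.py   synthetic delivery, machine noise, fault injection, study
  monitor.py    ingest, status rollup, reports, persistence
  cli.py        the `pdm` command
docs/methods.md  model, defaults and their rationale, limitations
```
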