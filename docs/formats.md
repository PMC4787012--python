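# Log file dialects

Both per-delivery logs are plain text, UTF-8, LF-terminated, diff-able and
language-neutral. Numeric values are written as shortest round-trip decimals
(Python `repr`), so `write ∘ read` is the identity to the last bit. Header
lines start with `#` and carry `key = value` pairs; `format_version` is `1`.

## Text log (`.ttxt`)

One snapshot of exactly 45 named scalars written at the start of delivery.
Keys are unique; units are documented in the parameter registry, not in the
file.

```
# format_version = 1
# machine_id = TB01
# date = 2026-01-05
pfn_hv_current = 99.17823905944824
pfn_voltage = 15.063052868133122
afc_error = -0.012911674967589
...                                   (45 key = value lines in total)
```

Validation: required header fields (`format_version`, `machine_id`, `date`),
parseable ISO date, exactly 45 entries, no duplicate keys, every value a
finite decimal. Violations raise a format error naming the line and key.

## Trajectory log (`.tlog.csv`)

Axis positions sampled every `sample_interval_ms` (20 ms in the default
dialect) for the whole delivery; 131 axes in the default registry. The
column header repeats the declared axis order; snapshot indices are 0-based
and must run 0..N−1 without gaps.

```
# format_version = 1
# machine_id = TB01
# date = 2026-01-05
# sample_interval_ms = 20.0
# axes = gantry,jaw_x1,jaw_x2,jaw_y1,jaw_y2,carriage_a,carriage_b,mlc_a01,...,couch_rtn
snapshot_index,gantry,jaw_x1,...,couch_rtn
0,-179.0,-5.0213,...,0.0
1,-178.92,-4.9978,...,0.0
...
```

Validation: required header fields (the above plus `sample_interval_ms` and
`axes`), positive sampling interval, unique axis names, column header
matching the declaration, rectangular numeric rows (ragged rows rejected
with their line number), strictly sequential snapshot indices, at least one
row.

Units by axis class: gantry and couch rotation in degrees, jaws/carriages/
leaves and couch translations in centimetres.

Reference traces for cross-correlation are stored in this same dialect
(one file per machine state directory, `references.tlog.csv`).
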