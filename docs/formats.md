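# File formats

All files are plain text. Writes are atomic (temp file + rename). Floating
point values are written with 17 significant digits and round-trip exactly.

## Stationary-point database directory

A database is a directory holding:

| file | required | content |
|---|---|---|
| `min.data` | yes | one minimum per line |
| `ts.data` | no | one transition state per line |
| `metadata.json` | no | units, `kappa`, `ndim`, provenance |
| `minima.xyz` | no | one XYZ frame per minimum, in id order |
| `manifest.json` | no | generator design truth (synthetic databases) |

### min.data

```
energy  log_freq_product  degeneracy  1.0 1.0 1.0
```

* `energy` — potential energy of the minimum (units from metadata, default
  "reduced").
* `log_freq_product` — sum of log positive normal-mode frequencies over the
  kappa vibrational degrees of freedom.
* `degeneracy` — multiplicative permutation-inversion / point-group weight
  (n_a > 0).
* the trailing three columns are moments-of-inertia placeholders kept for
  ecosystem compatibility; written as `1.0`, ignored on read.

Exactly 6 whitespace-separated columns per line; a malformed line is
reported with its line number.

### ts.data

```
energy  log_freq_product  degeneracy  min1  min2  1.0 1.0 1.0
```

`min1`/`min2` are **1-based** minimum ids on disk (ecosystem convention);
internal ids are 0-based. A file id of 0 is rejected. Exactly 8 columns.
The log-frequency product of a transition state sums the positive modes
only (the single negative mode and zero modes are excluded).

### metadata.json

```json
{"units": "reduced", "kappa": 12, "ndim": 3, "...": "free-form"}
```

## XYZ archives

Standard multi-frame XYZ: atom-count line, comment line, then
`element x y z` per site. Two-dimensional configurations are written with
`z = 0`.

## Thermodynamics outputs (`hexscape thermo`)

* `cv.csv` — columns `kBT`, `CV_over_kB` (total, including the kinetic
  kappa offset), `mean_energy`.
* `features.json` — list of feature objects:

```json
{
  "kind": "peak" | "inflection",
  "kbt_location": 0.1205,
  "grid_index": 123,
  "is_melting": false,
  "positive_set": {"members": [[id, dp_dT], ...], "achieved_coverage": 0.984},
  "negative_set": {"members": [[id, dp_dT], ...], "achieved_coverage": 0.991}
}
```

* `contributions.csv` — long-form table: `feature`, `sign`, `minimum_id`,
  `dp_dT`.

## Disconnectivity tree JSON (`hexscape tree`)

```json
{
  "delta_e": 0.12,
  "e_top": 6.0,
  "n_leaves": 25,
  "roots": [ <node> ]
}
```

A `<node>` is either an internal superbasin node

```json
{"energy": 3.2, "x": 0.5, "minima": [0, 1, 4], "children": [ ... ]}
```

(drawn at the lowest threshold at which its members still interconvert) or
a leaf

```json
{"energy": 0.0, "x": 0.25, "minima": [0], "minimum_id": 0, "colour": "red"}
```

placed at the minimum's own energy. Leaf colours follow the contribution
sets used for `--colour-from`: feature 1 positive/negative = red/blue,
feature 2 = green/orange, feature 3 = pink/purple, feature 4 = grey/yellow,
unmatched leaves `"neutral"`.

## Descriptor CSV (`hexscape descriptors`)

Columns: `minimum_id`, `energy`, `relative_energy` (above the global
minimum), `end_to_end`, `dihedral` (signed degrees in (-180, 180]),
`contributes` (member of the feature's contribution sets).

## Propensity table (`hexscape correlate` input)

CSV with columns `sequence`, `feature_kbt` (empty = no feature in the
window; the row is excluded and listed), `propensity`; optional `group`
and boolean `is_amyloid` enable the per-group lowest-temperature check.

## Config files

`--config` accepts YAML or JSON holding a flat mapping of defaults;
explicit command-line flags take precedence.
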