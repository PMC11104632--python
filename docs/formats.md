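# File formats

All formats are plain text or standard image files; every CLI run can
be reproduced from its manifest (config + seed + checksums).

## Frame output (`noisefield generate`)

Numbered 8-bit grayscale images `frame_000000.png`, … (or `.pgm`,
binary P5) plus `manifest.json`:

```json
{
  "config": {"width_px": 1920, "height_px": 1200, "dot_px": 7,
             "levels": [255, 191, 127, 64, 0],
             "density_ratios": [1.0, 0.75, 0.5, 0.25, 0.0],
             "n_frames": 60, "fps": 60.0, "dot_pitch_mm_per_px": 0.27,
             "rng": {"algorithm": "xorshift32", "seed": 7, "lcg_params": null}},
  "frames": [{"file": "frame_000000.png", "frame_index": 0, "sha256": "…"}]
}
```

Identical config + seed ⇒ identical frame bytes and checksums.

## Visual-field record (JSON)

```json
{
  "laterality": "OD",
  "md": -4.7,
  "psd_p_lt_5": true,
  "ght": "outside_normal_limits",
  "fp": 0.05, "fn": 0.1,
  "pd_shown": true,
  "points": [{"x": -3, "y": 3, "pd": "lt1pct"}, …]
}
```

* `points` uses **chart coordinates**: `x` positive toward the
  patient's right on the printout, `y` positive superior; temporal is
  `+x` for OD and `−x` for OS.  All 76 positions of the 30-2 layout
  must be present exactly once (missing entries may be omitted and
  default to `ge5pct`).
* `pd` ∈ `ge5pct | lt5pct | lt2pct | lt1pct | lt0_5pct`.
* `ght` ∈ `within_normal_limits | outside_normal_limits | borderline |
  other`; `fp`/`fn` are fractions in [0, 1] or null.
* `pd_shown: false` marks a severely depressed field whose pattern
  deviation map the instrument withheld (stage M4).

## Shadow record (JSON)

```json
{
  "responded": true,
  "reproducible": true,
  "laterality": "OD",
  "regions": [
    {"quadrants": ["inf_nasal", "inf_temporal"],
     "ecc": 12.0, "temporal": false, "straddles": false, "isolated": false}
  ]
}
```

`quadrants` ⊆ {`sup_nasal`, `sup_temporal`, `inf_nasal`,
`inf_temporal`} (non-empty); `ecc` is the centroid eccentricity in
degrees; `temporal`, `straddles` (horizontal meridian) and `isolated`
are the flags used by the blind-spot exclusion.

## Cohort CSV

Header (fixed order, UTF-8):

```
eye_id,group,stage,cg_outcome,analog_outcome,preference
```

* `group` ∈ `normal | ppg | glaucoma`; `stage` ∈ `M1…M4`, non-empty
  iff `group=glaucoma`.
* outcomes ∈ `agreement | partial_agreement | no_agreement |
  no_response`.
* `preference` ∈ `cg | same | analog`, non-empty iff both outcomes are
  detections (agreement or partial agreement).

Parse errors name the offending row and column.

## Simulation config (`noisefield cohort simulate --config`)

```json
{"M1": {"n": 100,
        "outcomes": {"agreement|agreement": 0.5,
                     "partial_agreement|no_response": 0.2,
                     "no_response|no_response": 0.3},
        "preference": [0.7, 0.22, 0.08]}}
```

Outcome keys are `cg|analog` pairs; probabilities must sum to 1 per
stage; `preference` gives the cg/same/analog shares within the
both-detected stratum.

## Analysis report (`noisefield cohort analyze --report`)

JSON with `cg` / `analog` blocks (per-stage rows: n, detected, rate %,
exact 95 % CI, adjusted residual, subset letter, McNemar b/c/p; plus
chi-square and specificity) and a `preference` block (per-stage counts,
shares, exact binomial p).  Rates are rounded to 0.1 %; p-values are
unrounded.
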