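# File formats and schemas

## Region annotations (`*_regions.json`)

One JSON object per scene, schema tag `eggshade/regions-v1`:

```json
{
 "schema": "eggshade/regions-v1",
 "px_per_cm": 10.0,
 "nest_centre": [256.0, 256.0],
 "standard_polygon": [[x, y], ...],
 "egg_polygons": [[[x, y], ...], ...]
}
```

Coordinate convention: 0-based pixel coordinates, `x` to the right
(columns), `y` down (rows); the centre of pixel `(row r, col c)` is the
point `(x=c, y=r)`.  Polygons are closed implicitly (the last vertex is not
a repeat of the first) and must be simple.  Rasterization uses the
pixel-centre-inside rule.

## Scene images

Per scene: `<scene_id>_vis.tif` (3-channel, 16-bit, R/G/B) and
`<scene_id>_uv.tif` (single channel, 16-bit), mirroring the two exposures
taken in the field.  Calibrated reflectance and cone-catch images are
32-bit float TIFFs.

## Radiation log (`radiation.csv`)

One row per 5-min sample: `treatment` (when multi-treatment), `day`,
`timestamp` (ISO 8601), `irradiance_wm2`, `illuminance_lux`, `uv_index`.

## Per-egg reflectance table

Columns: `scene_id`, `day`, `treatment`, `egg_id`, `band_set`
(`VIS` | `UV`), `mean_reflectance`.

## Experiment-1 summary

Columns: `treatment`, `band_set`, `mean_day0`, `mean_final`, `pct_change`
(percent, computed from unrounded means), `irradiance_wm2`, `uv_index`.

## Camouflage scores / experiment-2 summary

Scores: `nest_id`, `day`, `visual_model`, `chi2` (half-normalized
chi-square distance in [0, 1]).  Summary: `visual_model`, `day`, `mean`,
`se` (across nests), `n`.
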