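# File formats

## Field TIFF

One multi-page grayscale TIFF per field, float32, one page per z-slice per
channel in channel-major order: all nuclear slices, then dendrite, then
presynaptic. The first page's description holds JSON metadata:

```json
{"plate_id": "P1", "well": "B02", "field_index": 1,
 "pixel_size": 0.6, "n_slices": 5,
 "channel_order": ["nuclear", "dendrite", "presynaptic"]}
```

Default filename: `{plate_id}_{well}_f{field:02d}.tif`.

## Field measurement CSV

One row per field; written by `synaptoscreen process` / `run_field_pipeline`.

| column | meaning |
|---|---|
| `plate_id` | plate identifier |
| `well` | row letter + 2-digit column, e.g. `B02` |
| `field` | field index within the well (1-based) |
| `AreaOccupied_MAP2PositiveNeurites` | neurite (dendrite-marker) mask area, pixels |
| `Count_SYNAPSIN1PunctaOnMAP2PositiveNeurites` | presynaptic puncta overlapping the neurite mask |
| `Count_Nuclei` | detected nuclei in the field |
| `AreaOccupied_SYNAPSIN1` | summed area of all retained puncta, pixels |

## Ground-truth CSV (simulator)

One row per planted object: `field_id, well, object_type (punctum|nucleus),
y, x, equivalent_diameter, on_neurite, class (neuronal|astrocytic|empty)`.
Coordinates are 0-based (y, x) pixels.

## Layout YAML

```yaml
plates:
  P01:
    batch_id: batch1
    control_columns: [2, 11]     # vehicle columns among the inner wells
    sentinel: false
    treatments:                  # absent or empty on sentinel plates
      B03: [compound_id, 3.0, 1] # well: [compound, concentration_uM, replicate]
```

Inner wells are rows B–G × columns 2–11 (60 wells); wells in
`control_columns` carry the vehicle and must not be treated. The YAML
round-trips losslessly through `ScreenLayout.to_yaml` / `from_yaml`.

## Well / condition tables (screen analysis output)

`wells.csv`: `plate_id, well, batch_id, role (assay|control|sentinel),
condition, n_fields, map2_area, count, nuclei, syn_area, density, qc_fail`,
plus `pct_<metric>` (percent of intra-plate control mean) and
`z_density, z_map2, z_nuclei` (intra-plate Z-scores) for metrics
density, map2_area, nuclei.

`conditions.csv`: `condition, n_wells_used, qc_fail`, the well-mean metric
and z columns, and `hit_class`
(`enhancer_candidate | toxic | inactive | qc_fail`).

`rejections.csv`: `plate_id, well, field, reason` for every record removed
by QC (field outside the area band, well with < 5 fields, condition with
< 2 wells).

`library_fractions.csv`: `hit_class, count, percent` with percent of the
declared library size, rounded to 2 decimals.

## Simulation config YAML (`synaptoscreen simulate --config`)

```yaml
seed: 9
fields_per_well: 12
field:            # any FieldSpec field, e.g.:
  image_shape: [256, 256]
  n_slices: 5
  n_on_puncta: 60
artifacts:        # any ArtifactSpec field
  channel_shift: [3, -2]
  illumination_gradient: [1.0, 0.0, 0.0005]
effects:
  density:   {B03: 2.0}   # per-well multiplier on planted on-neurite density
  viability: {B03: 0.8}   # per-well multiplier on planted nuclei counts
```

## Plate QC

Input counts CSV: `well, count` (neuronal nuclei per well). Verdict JSON:
`{"mean": ..., "sd": ..., "covariance_pct": ..., "pass": true|false}`.
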