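# CSV schemas

All tables are plain CSV with a header row; reading and writing through
`droptxtl.io` is lossless round-trip.

## Droplet ensemble table (`ensemble.csv`)

| column     | type  | meaning                                            |
|------------|-------|----------------------------------------------------|
| droplet_id | int   | stable identifier within the table                 |
| R_um       | float | droplet radius, μm                                 |
| I_gfp      | float | total reporter fluorescence, arbitrary units       |
| I_v        | float | total volume-marker fluorescence, arbitrary units (∝ R³) |
| qc_pass    | bool  | record enters fits only when true                  |

## Image measurement table (`image_measurements.csv` / `segmentation.csv`)

| column          | type  | meaning                                        |
|-----------------|-------|------------------------------------------------|
| droplet_id      | int   | label of the kept object                       |
| R_um            | float | radius from object area via S = πR², μm        |
| total_intensity | float | background-subtracted sum over object pixels   |
| mean_intensity  | float | total / area                                   |
| background      | float | background level subtracted (same for all rows)|
| qc_pass         | bool  | always true for kept objects                   |

To feed image measurements into the scaling fits, rename `total_intensity`
to `I_gfp` (or `I_v` for a marker channel).

## Time course (`timecourse.csv`)

| column    | type  | meaning                       |
|-----------|-------|-------------------------------|
| t_min     | float | time since reaction start, min|
| intensity | float | reporter signal, a.u.         |

## Image ground truth (`image_ground_truth.csv`)

One row per rasterised object: `object_id, cy, cx, radius_px, axis_ratio,
area_px2, R_equiv_um, intensity, total_intensity`.  `total_intensity` is the
integrated (anti-aliased) signal above background actually drawn.

## Parameter config (`config/reference_params.yaml`)

Flat mapping of model symbols to values.  `T_s_min` (minutes) and
`lambda_nm` (nm) are converted to internal units (s, μm) on load; all other
rates are s⁻¹ and `k_R` is molecules·μm⁻³·s⁻¹.
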