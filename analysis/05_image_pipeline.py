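#!/usr/bin/env python
"""Exercise the droplet image pipeline against synthetic ground truth.

Rasterises a droplet field (discs of 6–30 px radius, one deformed 3:1
ellipse mimicking a wetted/coalesced droplet, one sub-threshold debris
speck), then segments, applies the roundness (M ≥ 0.75) and size
(S ≥ 78.6 μm²) filters, measures radii and background-subtracted total
intensities, and compares everything with the generator's ground truth.

Writes results/image_pipeline.json and results/image_measurements.csv;
the raster itself goes to scratch/droplet_field.tif.
"""

import argparse
from pathlib import Path

import numpy as np

from droptxtl import (
    DiscSpec,
    SyntheticImageSpec,
    apply_filters,
    generate_image,
    measure_droplets,
    segment,
)
from droptxtl.io import write_image, write_report, write_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise-sd", type=float, default=0.0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    discs = [(60, 60, 6), (60, 170, 9), (60, 300, 13), (170, 60, 17),
             (170, 190, 22), (185, 330, 30)]
    objects = [DiscSpec(cy=cy, cx=cx, radius_px=r, intensity=30 + 2 * i)
               for i, (cy, cx, r) in enumerate(discs)]
    objects.append(DiscSpec(cy=300, cx=90, radius_px=7, intensity=35, axis_ratio=3.0))
    objects.append(DiscSpec(cy=300, cx=250, radius_px=3, intensity=35))

    spec = SyntheticImageSpec(image_size=(360, 400), objects=tuple(objects),
                              background_level=10.0, noise_sd=args.noise_sd,
                              seed=args.seed)
    image, truth = generate_image(spec)
    write_image(image, Path("scratch") / "droplet_field.tif")

    seg = segment(image)
    kept = apply_filters(seg)
    table = measure_droplets(image, kept)
    write_table(table, args.out_dir / "image_measurements.csv")

    print(f"detected {seg.n_objects} objects; {kept.n_objects} pass the "
          "roundness and size filters (ellipse and debris rejected)")

    true_discs = truth[(truth["axis_ratio"] == 1.0) & (truth["radius_px"] >= 5)]
    matched = table.sort_values("R_um").reset_index(drop=True)
    ref = true_discs.sort_values("radius_px").reset_index(drop=True)
    r_err = np.abs(matched["R_um"].to_numpy() - ref["radius_px"].to_numpy())
    i_err = np.abs(matched["total_intensity"].to_numpy()
                   / ref["total_intensity"].to_numpy() - 1.0)
    print(f"radius recovery: max error {r_err.max():.2f} px; "
          f"total-intensity recovery: max error {100 * i_err.max():.2f}%")

    write_report(
        {"n_objects_detected": seg.n_objects, "n_kept": kept.n_objects,
         "n_true_droplets": int(len(ref)),
         "max_radius_error_px": float(r_err.max()),
         "max_intensity_rel_error": float(i_err.max()),
         "noise_sd": args.noise_sd},
        args.out_dir / "image_pipeline.json", seed=args.seed,
    )


if __name__ == "__main__":
    main()
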