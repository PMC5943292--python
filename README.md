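# droptxtl

Cell-free transcription–translation (TXTL) reactions confined in cell-sized
water-in-oil droplets do not simply scale with volume: steric depletion of
ribosomes from a thin (λ ≈ 30 nm) surface layer represses translation near
the interface, and because a droplet's surface-to-volume ratio is 3λ/R, the
total protein produced in a droplet of radius R follows an anomalous
geometric scaling — approaching ⟨cV⟩ ∝ R⁴ for small droplets and returning
to the ordinary R³ law above a crossover radius R_c ≈ 17 μm.

`droptxtl` implements the full analysis for this system, for people studying
gene expression in emulsion droplets, liposomes or other microcompartments:

* the kinetic model of free mRNA `r`, surface-layer mRNA `r*` and protein `c`

      dr/dt  = k_R − k_on·r·(3λ/R) + k_off·r* − γ_R·r
      dr*/dt = k_on·r·(3λ/R) − k_off·r* − γ*_R·r*
      dc/dt  = α·r + α*·r*

  with its closed-form steady states, the endpoint protein amount
  ⟨cV⟩(R) = r₀V/((3λ/R)(θ/τ)+1)·(α + α*·3λ/(τR))·T_s, the limiting
  repression/activation/unregulated regime curves (β → 4, 2, 3), and the
  crossover radius R_c = 3λθ·k_on/(k_off+γ*_R);
* power-law exponent estimation for droplet ensembles (I_GFP ∝ R^β,
  I_GFP ∝ I_v^β against a volume marker, piecewise fits split at R_c);
* least-squares recovery of the identifiable model parameters and the
  implied crossover radius, plus the intersection estimator for the
  saturation time T_s;
* the droplet image pipeline: binarisation, 8-connected labeling, roundness
  (M = 4πS/L² ≥ 0.75) and size (S ≥ 78.6 μm², i.e. R ≥ 5 μm) filters,
  background-subtracted per-droplet total intensity, radius from S = πR²;
* synthetic-data generators (ensembles, time courses, rasterised droplet
  fields with ground truth) so every stage is testable end to end.

## Worked example

```python
from droptxtl import (reference_params, crossover_radius, EnsembleSpec,
                      generate_ensemble, fit_power_law, piecewise_fit,
                      FitConfig, fit_model)

params = reference_params()
print(crossover_radius(params))          # 17.142857142857142

ens = generate_ensemble(EnsembleSpec(n_droplets=250, params=params,
                                     noise_cv=0.2, seed=1))
print(fit_power_law(ens["R_um"], ens["I_gfp"]).beta)   # 3.5110939859883734
below, above = piecewise_fit(ens, crossover_radius(params))
print(below.beta, above.beta)            # 3.654852792135686 3.394762742875959

res = fit_model(ens, FitConfig(params=params, seed=1))
print(res.implied_R_c)                   # 18.3116849785048
```

Reading the numbers: the crossover radius of the reference parameter set is
17.14 μm.  A simulated ensemble of 250 droplets with 20% intensity noise
shows a global exponent β ≈ 3.51 — between the volume law (3) and the
small-droplet repression limit (4), as expected when the radius window
5–50 μm straddles R_c.  The piecewise exponents bracket it (steeper below
R_c than above), and refitting the model to the noisy data recovers the
crossover radius to within ≈7% on this seed.

The same analysis as a reproducible narrative:

```
python analysis/01_model_regimes.py      # regime map and local exponents
python analysis/02_simulate_ensemble.py  # synthetic droplet experiment
python analysis/03_scaling_fits.py       # scaling exponents
python analysis/04_fit_model.py          # parameter recovery + T_s
python analysis/05_image_pipeline.py     # segmentation vs ground truth
```

Each script prints what it found and writes its tables under `results/`.
There is also a CLI for one-off runs (`droptxtl simulate ensemble`,
`droptxtl scaling fit`, `droptxtl fit model`, `droptxtl fit tsat`,
`droptxtl image measure`, `droptxtl demo`); CSV column schemas are in
`docs/schemas.md` and the science is documented in `docs/methods.md`.

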