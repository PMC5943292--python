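"""Synthetic data with the statistical structure the droplet analysis assumes.

Three generators stand in for the microscopy experiment:

* :func:`generate_ensemble` — a polydisperse droplet table (radius, reporter
  intensity following the endpoint model with multiplicative lognormal noise,
  and a volume marker scaling as R³);
* :func:`generate_time_course` — a saturating expression time course with the
  model's linear early phase;
* :func:`generate_image` — rasterised anti-aliased discs (plus optional
  elliptical "deformed droplets" and small debris) on a noisy background,
  with a ground-truth table for every object.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .model import endpoint_protein, sphere_volume_um3, steady_state_mrna
from .params import ModelParams

__all__ = [
    "EnsembleSpec",
    "DiscSpec",
    "SyntheticImageSpec",
    "generate_ensemble",
    "generate_time_course",
    "generate_image",
]

ENSEMBLE_COLUMNS = ["droplet_id", "R_um", "I_gfp", "I_v", "qc_pass"]


class EnsembleSpec(BaseModel):
    """Recipe for a droplet ensemble.

    Radii are drawn log-uniformly (default) or lognormally on
    ``radius_range`` = (5, 50) μm — the analysable size window once
    sub-5-μm objects are filtered out.  ``noise_cv`` is the coefficient of
    variation of the multiplicative lognormal intensity noise (mean 1, so the
    noise is unbiased); the default 0.2 is a typical droplet-to-droplet
    fluorescence spread.  Gains convert molecules to arbitrary intensity
    units.
    """

    model_config = ConfigDict(frozen=True)

    n_droplets: int
    params: ModelParams
    radius_range: tuple[float, float] = (5.0, 50.0)
    radius_law: Literal["log-uniform", "lognormal"] = "log-uniform"
    noise_cv: float = 0.2
    marker_gain: float = 1.0
    gfp_gain: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "EnsembleSpec":
        lo, hi = self.radius_range
        if not (0 < lo < hi):
            raise ValueError(f"radius_range must satisfy 0 < lo < hi, got {self.radius_range}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_droplets < 2:
            raise ValueError("need at least 2 droplets for any downstream fit")
        return self


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors with E[ε] = 1 and sd/mean = cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_ensemble(spec: EnsembleSpec) -> pd.DataFrame:
    """Sample a droplet table: R, reporter total I_gfp, volume-marker total I_v."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.radius_range
    if spec.radius_law == "log-uniform":
        radii = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_droplets))
    else:  # lognormal, clipped into range
        mu = math.log(math.sqrt(lo * hi))
        sigma = math.log(hi / lo) / 4.0
        radii = np.clip(rng.lognormal(mu, sigma, spec.n_droplets), lo, hi)

    protein = np.array([endpoint_protein(R, spec.params) for R in radii])
    eps_gfp = _lognormal_mean_one(rng, spec.noise_cv, spec.n_droplets)
    eps_marker = _lognormal_mean_one(rng, spec.noise_cv, spec.n_droplets)
    volumes = 4.0 / 3.0 * np.pi * radii**3

    return pd.DataFrame(
        {
            "droplet_id": np.arange(spec.n_droplets),
            "R_um": radii,
            "I_gfp": spec.gfp_gain * protein * eps_gfp,
            "I_v": spec.marker_gain * volumes * eps_marker,
            "qc_pass": True,
        }
    )


def generate_time_course(
    R: float,
    params: ModelParams,
    plateau_model: Literal["hard", "smooth"] = "hard",
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    n_points: int = 150,
    t_end: float | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Expression time course for one droplet: columns ``t_min``, ``intensity``.

    The early phase rises at the model's steady-state synthesis rate; the
    plateau mimics resource depletion.  ``hard`` is a piecewise-linear kink at
    T_s; ``smooth`` is P·(1 − exp(−t/T_s)), whose initial slope and plateau
    match the hard model's ramp and ceiling.  ``noise_sd`` is additive
    Gaussian noise as a fraction of the plateau.
    """
    if not R > 0:
        raise ValueError(f"droplet radius must be positive, got {R}")
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = 4.0 * params.T_s
    t = np.linspace(0.0, t_end, n_points)

    r_bar, r_star_bar = steady_state_mrna(R, params)
    rate = (params.alpha * r_bar + params.alpha_star * r_star_bar) * sphere_volume_um3(R)
    plateau = rate * params.T_s

    if plateau_model == "hard":
        intensity = rate * np.minimum(t, params.T_s)
    elif plateau_model == "smooth":
        intensity = plateau * (1.0 - np.exp(-t / params.T_s))
    else:
        raise ValueError(f"unknown plateau model {plateau_model!r}")

    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd * plateau, n_points)
    if normalize:
        intensity = intensity / intensity[-1]
    return pd.DataFrame({"t_min": t / 60.0, "intensity": intensity})


# ---------------------------------------------------------------------------
# image synthesis


class DiscSpec(BaseModel):
    """One rasterised object: a disc, or an ellipse when ``axis_ratio`` > 1."""

    model_config = ConfigDict(frozen=True)

    cy: float
    cx: float
    radius_px: float          # for ellipses: semi-minor axis b; a = b·axis_ratio
    intensity: float
    axis_ratio: float = 1.0
    angle_deg: float = 0.0

    @model_validator(mode="after")
    def _validate(self) -> "DiscSpec":
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.axis_ratio < 1.0:
            raise ValueError("axis_ratio is major/minor and must be >= 1")
        return self


class SyntheticImageSpec(BaseModel):
    """Recipe for a synthetic droplet micrograph."""

    model_config = ConfigDict(frozen=True)

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    objects: tuple[DiscSpec, ...] = ()
    background_level: float = 10.0
    noise_sd: float = 0.0
    overlap_allowed: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticImageSpec":
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.overlap_allowed:
            h, w = self.image_size
            for obj in self.objects:
                a = obj.radius_px * obj.axis_ratio
                if not (a <= obj.cy <= h - 1 - a and a <= obj.cx <= w - 1 - a):
                    raise ValueError(
                        f"object at ({obj.cy}, {obj.cx}) extends outside the frame"
                    )
        return self


def _coverage(obj: DiscSpec, shape: tuple[int, int], supersample: int = 8) -> np.ndarray:
    """Fractional pixel coverage of one object, by supersampling.

    Pixel centres sit at integer coordinates (origin top-left); a pixel spans
    ±0.5 around its centre.
    """
    h, w = shape
    a = obj.radius_px * obj.axis_ratio  # semi-major
    b = obj.radius_px                   # semi-minor
    pad = a + 1.5
    y0, y1 = max(0, int(obj.cy - pad)), min(h, int(obj.cy + pad) + 1)
    x0, x1 = max(0, int(obj.cx - pad)), min(w, int(obj.cx + pad) + 1)
    out = np.zeros(shape)
    if y0 >= y1 or x0 >= x1:
        return out

    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    yy = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel()  # (ny*s,)
    xx = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel()
    theta = math.radians(obj.angle_deg)
    ct, st = math.cos(theta), math.sin(theta)
    dy = yy[:, None] - obj.cy
    dx = xx[None, :] - obj.cx
    u = dx * ct + dy * st    # along major axis
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cov = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
    out[y0:y1, x0:x1] = cov
    return out


def generate_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterise the objects onto a noisy background.

    Returns the float image and a ground-truth table with one row per object:
    centre, equivalent radius (px and μm), axis ratio, true area and true
    background-subtracted total intensity.
    """
    rng = np.random.default_rng(spec.seed)
    image = np.full(spec.image_size, float(spec.background_level))
    rows = []
    for i, obj in enumerate(spec.objects):
        cov = _coverage(obj, spec.image_size)
        image += obj.intensity * cov
        area_px = math.pi * obj.radius_px**2 * obj.axis_ratio
        rows.append(
            {
                "object_id": i,
                "cy": obj.cy,
                "cx": obj.cx,
                "radius_px": obj.radius_px,
                "axis_ratio": obj.axis_ratio,
                "area_px2": area_px,
                "R_equiv_um": math.sqrt(area_px / math.pi) * spec.pixel_size_um,
                "intensity": obj.intensity,
                "total_intensity": obj.intensity * cov.sum(),
            }
        )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, spec.image_size)
    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "cy", "cx", "radius_px", "axis_ratio",
            "area_px2", "R_equiv_um", "intensity", "total_intensity",
        ],
    )
    return image, truth
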