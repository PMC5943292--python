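"""Power-law exponent estimation for droplet ensembles.

Total reporter intensity is modelled as I ∝ x^β with x either the droplet
radius R or the volume-marker intensity I_v.  Exponents are estimated by
ordinary least squares of log I on log x (unweighted; fits are
scale-equivariant, so gain factors only move the intercept).  A piecewise
variant fits the two sides of a split radius — by convention the
model-derived crossover radius R_c — independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScalingFit", "fit_power_law", "fit_intensity_exponent", "piecewise_fit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingFit:
    """Result of a log-log power-law fit I ∝ x^β."""

    beta: float
    log_intercept: float
    fit_range: tuple[float, float]
    n_points: int
    residual_sd: float
    stderr_beta: float

    @property
    def amplitude(self) -> float:
        """Prefactor exp(log_intercept) so that I ≈ amplitude · x^beta."""
        return math.exp(self.log_intercept)


def _as_positive(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(
            f"{name} must be strictly positive for a log-log fit; "
            f"offending rows: {bad[:10].tolist()}"
            + ("…" if bad.size > 10 else "")
        )
    return arr


def fit_power_law(x, y) -> ScalingFit:
    """OLS fit of log y on log x; returns the exponent β with its standard
    error and the residual spread in log space."""
    x = _as_positive(x, "x")
    y = _as_positive(y, "y")
    if x.shape != y.shape:
        raise ValueError(f"x and y must have equal length, got {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError(f"need at least 2 points for a power-law fit, got {x.size}")
    lx, ly = np.log(x), np.log(y)
    res = stats.linregress(lx, ly)
    resid = ly - (res.intercept + res.slope * lx)
    dof = max(x.size - 2, 1)
    return ScalingFit(
        beta=float(res.slope),
        log_intercept=float(res.intercept),
        fit_range=(float(x.min()), float(x.max())),
        n_points=int(x.size),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        stderr_beta=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
    )


def _qc_records(records: pd.DataFrame) -> pd.DataFrame:
    if "qc_pass" in records.columns:
        records = records[records["qc_pass"]]
    n_before = len(records)
    records = records[(records["I_gfp"] > 0) & (records["I_v"] > 0)]
    dropped = n_before - len(records)
    if dropped:
        logger.info("dropped %d records with non-positive intensity", dropped)
    return records


def fit_intensity_exponent(records: pd.DataFrame) -> ScalingFit:
    """Exponent of I_gfp against the volume marker I_v (I_gfp ∝ I_v^β).

    β = 1 is ordinary volume scaling (purified-protein control behaviour);
    under exact power laws in R this equals β(I_gfp vs R)/β(I_v vs R).
    """
    records = _qc_records(records)
    return fit_power_law(records["I_v"], records["I_gfp"])


def piecewise_fit(
    records: pd.DataFrame, R_split: float, y: str = "I_gfp"
) -> tuple[ScalingFit, ScalingFit]:
    """Independent power-law fits of ``y`` vs R below and above ``R_split``.

    Points exactly at ``R_split`` go to the upper segment.
    """
    records = _qc_records(records)
    below = records[records["R_um"] < R_split]
    above = records[records["R_um"] >= R_split]
    for side, name in [(below, "below"), (above, "above")]:
        if len(side) < 2:
            raise ValueError(
                f"piecewise fit needs >= 2 points {name} R_split={R_split}, got {len(side)}"
            )
    return (
        fit_power_law(below["R_um"], below[y]),
        fit_power_law(above["R_um"], above[y]),
    )
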