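"""Least-squares estimation of the confined-expression model from droplet data.

The endpoint model predicts total reporter intensity

    I(R) = g·⟨cV⟩(R) = g·r₀·V/((3λ/R)(θ/τ) + 1)·(α + α*·3λ/(τR))·T_s

with a free gain g (intensity units per molecule; the fluorescence
calibration is not part of the analysis).  Because g, k_R, α and α* enter
only through the products g·r₀·α and g·r₀·α*, the raw parameterisation is
degenerate.  The default "identifiable" parameterisation therefore fits

    A_bulk = g·r₀·α,  A_surf = g·r₀·α*,  k_off,

holding k_on, γ_R, γ*_R, λ and T_s fixed; the crossover radius implied by the
estimates, R_c = 3λθ·k_on/(k̂_off + γ*_R), is the headline derived quantity.
The raw parameterisation (free k_R, k_off, α, α*, g) is available for
exploring the degeneracy.

Fitting is nonlinear least squares in log space by default (the data span
about three decades; a linear-space loss is dominated by the largest
droplets), multi-started from heuristic slope-based guesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import stats

from .model import crossover_radius, endpoint_protein, sphere_volume_um3
from .params import ModelParams

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_model",
    "predict_intensity",
    "estimate_saturation_time",
]

_IDENTIFIABLE = ("A_bulk", "A_surf", "k_off")
_RAW = ("k_R", "k_off", "alpha", "alpha_star", "gain")


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_model`.

    ``params`` supplies the fixed constants (k_on, γ_R, γ*_R, λ, T_s) and, in
    the raw parameterisation, the starting values of the free rates.
    """

    params: ModelParams
    parameterization: Literal["identifiable", "raw"] = "identifiable"
    loss_space: Literal["log", "linear"] = "log"
    n_restarts: int = 10
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.params.k_on <= 0:
            raise ValueError(
                "model fitting requires a positive fixed k_on; the surface-free "
                "limit is reached by k_off -> inf (implied R_c -> 0), not k_on = 0"
            )

    @property
    def free_names(self) -> tuple[str, ...]:
        return _IDENTIFIABLE if self.parameterization == "identifiable" else _RAW


@dataclass(frozen=True)
class FitResult:
    """Estimates with convergence diagnostics and the implied crossover."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    implied_R_c: float
    n_points: int
    parameterization: str
    loss_space: str
    message: str = ""


def predict_intensity(
    R: np.ndarray, estimates: Mapping[str, float], config: FitConfig
) -> np.ndarray:
    """Model intensity at radii ``R`` for a given estimate vector."""
    R = np.asarray(R, dtype=float)
    p = config.params
    V = 4.0 / 3.0 * np.pi * R**3
    if config.parameterization == "identifiable":
        a, b, k_off = (estimates[k] for k in _IDENTIFIABLE)
        tau = (k_off + p.gamma_R_star) / p.k_on
        surface = (3.0 * p.lam / R) * (p.theta / tau)
        return V * p.T_s * (a + b * 3.0 * p.lam / (tau * R)) / (surface + 1.0)
    full = p.replace(
        k_R=estimates["k_R"], k_off=estimates["k_off"],
        alpha=estimates["alpha"], alpha_star=estimates["alpha_star"],
    )
    return estimates["gain"] * np.array([endpoint_protein(r, full) for r in R])


def _initial_guess(R: np.ndarray, y: np.ndarray, config: FitConfig) -> dict[str, float]:
    """Slope-based heuristics: the large-droplet branch pins the bulk
    amplitude, the split radius seeds k_off."""
    p = config.params
    top = R >= np.quantile(R, 0.75)
    a0 = float(np.median(y[top] / (4.0 / 3.0 * np.pi * R[top] ** 3 * p.T_s)))
    R_mid = float(np.exp(np.median(np.log(R))))
    tau0 = 3.0 * p.lam * p.theta / R_mid
    k_off0 = max(tau0 * p.k_on - p.gamma_R_star, 1e-6)
    b0 = 0.02 * a0
    if config.parameterization == "identifiable":
        return {"A_bulk": a0, "A_surf": b0, "k_off": k_off0}
    # raw: split a0 between gain and rates using the fixed-params scale
    return {
        "k_R": p.k_R, "k_off": k_off0, "alpha": p.alpha,
        "alpha_star": p.alpha_star, "gain": a0 / (p.r0 * p.alpha),
    }


def _default_bounds(x0: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    out = {}
    for name, v in x0.items():
        if name == "k_off":
            out[name] = (1e-8, 1e3)
        else:
            out[name] = (v * 1e-6, v * 1e6)
    return out


def fit_model(records: pd.DataFrame, config: FitConfig) -> FitResult:
    """Fit the endpoint model to a droplet table (columns R_um, I_gfp).

    Multi-start nonlinear least squares; the best-loss restart is reported.
    Non-convergence is flagged on the result, never silent.
    """
    data = records
    if "qc_pass" in data.columns:
        data = data[data["qc_pass"]]
    data = data[data["I_gfp"] > 0]
    R = data["R_um"].to_numpy(dtype=float)
    y = data["I_gfp"].to_numpy(dtype=float)
    names = config.free_names
    if R.size < len(names):
        raise ValueError(
            f"need at least {len(names)} informative points, got {R.size}"
        )

    x0_map = _initial_guess(R, y, config)
    bounds = {**_default_bounds(x0_map), **dict(config.bounds)}
    log_lo = np.log([bounds[n][0] for n in names])
    log_hi = np.log([bounds[n][1] for n in names])
    log_x0 = np.clip(np.log([x0_map[n] for n in names]), log_lo, log_hi)

    log_y = np.log(y)

    def residuals(log_x: np.ndarray) -> np.ndarray:
        est = dict(zip(names, np.exp(log_x)))
        pred = predict_intensity(R, est, config)
        if config.loss_space == "log":
            return np.log(np.maximum(pred, 1e-300)) - log_y
        return pred - y

    rng = np.random.default_rng(config.seed)
    best = None
    any_success = False
    for i in range(max(config.n_restarts, 1)):
        start = log_x0 if i == 0 else np.clip(
            log_x0 + rng.normal(0.0, 1.0, len(names)), log_lo, log_hi
        )
        sol = least_squares(residuals, start, bounds=(log_lo, log_hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol

    est = dict(zip(names, np.exp(best.x)))
    # delta-method standard errors from the Jacobian in log space
    stderr = {n: float("nan") for n in names}
    dof = R.size - len(names)
    if dof > 0:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * 2.0 * best.cost / dof
            for n, lx, var in zip(names, best.x, np.diag(cov)):
                stderr[n] = float(math.exp(lx) * math.sqrt(max(var, 0.0)))
        except np.linalg.LinAlgError:
            pass

    implied = crossover_radius(config.params.replace(k_off=est["k_off"]))
    return FitResult(
        estimates=est,
        stderr=stderr,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(any_success),
        implied_R_c=float(implied),
        n_points=int(R.size),
        parameterization=config.parameterization,
        loss_space=config.loss_space,
        message=str(best.message),
    )


def estimate_saturation_time(
    time_course: pd.DataFrame, plateau_fraction: float = 0.2
) -> float:
    """Saturation time from the intersection of the early linear rise with
    the plateau.

    The plateau is the mean of the trailing ``plateau_fraction`` of samples.
    The linear phase is chosen among prefixes of the record (up to where the
    signal first exceeds 80% of the plateau) by maximising R²; ties go to the
    longest prefix.  Returns the intersection time in the units of the input
    time column.
    """
    t = time_course.iloc[:, 0].to_numpy(dtype=float)
    y = time_course.iloc[:, 1].to_numpy(dtype=float)
    n = t.size
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    n_plateau = max(int(math.ceil(plateau_fraction * n)), 3)
    plateau_t, plateau_y = t[-n_plateau:], y[-n_plateau:]
    plateau = float(plateau_y.mean())
    if plateau <= 0:
        raise ValueError("plateau level is non-positive; curve does not saturate")
    tail = stats.linregress(plateau_t, plateau_y)
    if tail.slope * (plateau_t[-1] - plateau_t[0]) > 0.1 * plateau:
        raise ValueError("signal still rising in the plateau window; not saturated")

    first_high = int(np.argmax(y > 0.8 * plateau))
    if not (y > 0.8 * plateau).any():
        raise ValueError("signal never approaches the plateau level")
    k_max = max(first_high, 4)
    best_r2, best_fit = -np.inf, None
    for k in range(4, k_max + 1):
        res = stats.linregress(t[:k], y[:k])
        r2 = res.rvalue**2
        if res.slope > 0 and r2 >= best_r2 - 1e-12:
            best_r2, best_fit = max(r2, best_r2), res
    if best_fit is None:
        raise ValueError("no rising linear phase found; curve is not increasing")
    return float((plateau - best_fit.intercept) / best_fit.slope)
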