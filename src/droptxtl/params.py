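"""Kinetic parameters of the surface-regulation model of confined cell-free
gene expression (CFGE).

A droplet of radius ``R`` holds a well-mixed bulk and a thin surface layer of
thickness ``lam`` (λ).  Free mRNA (concentration ``r``) is transcribed at rate
``k_R``, exchanges with the surface layer (attachment ``k_on`` scaled by the
surface-to-volume capacity factor 3λ/R, dissociation ``k_off``), and both mRNA
pools degrade (``gamma_R``, ``gamma_R_star``).  Protein is translated from the
bulk pool at rate ``alpha`` and from the surface pool at ``alpha_star``;
accumulation stops at the saturation time ``T_s`` when resources are depleted.

Internal units are micrometres, seconds and molecules·μm⁻³ throughout.
Config files may use the lab-facing units (minutes for ``T_s``, nanometres for
λ); :meth:`ModelParams.from_mapping` converts on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["ModelParams", "reference_params"]

#: config keys accepted with automatic unit conversion -> (field, factor)
_UNIT_ALIASES = {
    "T_s_min": ("T_s", 60.0),       # minutes -> seconds
    "lambda_nm": ("lam", 1e-3),     # nm -> μm
    "lam_nm": ("lam", 1e-3),
    "lambda_um": ("lam", 1.0),
    "lam_um": ("lam", 1.0),
}


class ModelParams(BaseModel):
    """All rate constants of the confined-expression model, in s⁻¹ / μm.

    ``k_on``, ``alpha`` and ``alpha_star`` may be zero (regime switches:
    ``k_on = 0`` removes surface exchange entirely); every other rate and the
    layer thickness must be strictly positive.
    """

    model_config = ConfigDict(frozen=True)

    k_R: float          # transcription rate, molecules μm⁻³ s⁻¹
    k_on: float         # surface attachment rate, s⁻¹
    k_off: float        # surface dissociation rate, s⁻¹
    gamma_R: float      # free-mRNA degradation rate, s⁻¹
    gamma_R_star: float  # surface-layer mRNA degradation rate, s⁻¹
    alpha: float        # bulk translation rate, s⁻¹
    alpha_star: float   # surface-layer translation rate, s⁻¹
    T_s: float          # saturation time, s
    lam: float = 0.03   # surface-layer thickness λ, μm

    @model_validator(mode="after")
    def _check_positive(self) -> "ModelParams":
        strictly = {"k_R": self.k_R, "k_off": self.k_off, "gamma_R": self.gamma_R,
                    "gamma_R_star": self.gamma_R_star, "T_s": self.T_s, "lam": self.lam}
        for name, value in strictly.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name, value in [("k_on", self.k_on), ("alpha", self.alpha),
                            ("alpha_star", self.alpha_star)]:
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        return self

    # ---- derived quantities ------------------------------------------------
    @property
    def r0(self) -> float:
        """Unregulated steady-state mRNA concentration k_R/γ_R (μm⁻³)."""
        return self.k_R / self.gamma_R

    @property
    def theta(self) -> float:
        """Degradation-rate ratio θ = γ*_R/γ_R (dimensionless)."""
        return self.gamma_R_star / self.gamma_R

    @property
    def tau(self) -> float:
        """Exchange ratio τ = (k_off + γ*_R)/k_on; infinite when k_on = 0."""
        if self.k_on == 0:
            return float("inf")
        return (self.k_off + self.gamma_R_star) / self.k_on

    def replace(self, **changes: float) -> "ModelParams":
        return self.model_copy(update=changes)

    # ---- I/O ---------------------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        """Build from a flat config mapping, converting lab units.

        Accepts ``T_s_min`` (minutes) and ``lambda_nm``/``lam_nm`` in place of
        the internal-unit ``T_s`` (s) and ``lam`` (μm).
        """
        data: dict[str, float] = {}
        for key, value in mapping.items():
            if key in _UNIT_ALIASES:
                field, factor = _UNIT_ALIASES[key]
                if field in data:
                    raise ValueError(f"duplicate specification of {field!r} via {key!r}")
                data[field] = float(value) * factor
            else:
                data[key] = float(value)
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load from a flat JSON or YAML file of symbol -> value."""
        path = Path(path)
        text = path.read_text()
        mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(mapping, Mapping):
            raise ValueError(f"{path} does not contain a flat mapping")
        return cls.from_mapping(mapping)


def reference_params() -> ModelParams:
    """Parameter set for deGFP expression from an E. coli TXTL extract in
    DOPC-stabilised water-in-oil droplets (fixed + least-squares-fitted
    values; crossover radius ≈ 17 μm)."""
    return ModelParams(
        k_R=3.22e-3,
        k_on=1.0,
        k_off=3.86e-3,
        gamma_R=1.39e-3,
        gamma_R_star=1.39e-3,
        alpha=9.02,
        alpha_star=1.96e-1,
        T_s=153 * 60.0,
        lam=0.03,
    )
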