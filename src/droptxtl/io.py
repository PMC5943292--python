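"""Table, image and report I/O.

CSV schemas (documented in docs/schemas.md):

* droplet table — droplet_id, R_um, I_gfp, I_v, qc_pass
* measurement table (from image analysis) — droplet_id, R_um,
  total_intensity, mean_intensity, background, qc_pass
* time course — t_min, intensity

JSON reports always embed the seed and package version for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

DROPLET_COLUMNS = ["droplet_id", "R_um", "I_gfp", "I_v", "qc_pass"]
TIMECOURSE_COLUMNS = ["t_min", "intensity"]


def read_droplet_table(path: str | Path, required: Sequence[str] = ("R_um",)) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_timecourse(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: time course needs (time, intensity) columns")
    return df


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        img = imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, got shape {img.shape}")
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if hasattr(obj, "model_dump"):
        return _jsonable(obj.model_dump())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(payload: Mapping[str, Any], path: str | Path, seed: int | None = None) -> None:
    """Write a JSON report; the seed is recorded in the artifact's metadata."""
    out = dict(payload)
    if seed is not None:
        out.setdefault("metadata", {})
        out["metadata"] = {**out["metadata"], "seed": seed}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(out), indent=2, sort_keys=True) + "\n")
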