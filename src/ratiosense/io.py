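"""Readers, writers and run manifests shared by the CLI and library users.

Formats: TIFF for images, CSV for tables/traces/timelines, JSON for
summaries and manifests, TOML (or JSON) for configs.  Every CLI run writes a
manifest next to its outputs recording the package version, the seed, and a
hash of the configuration, so outputs are traceable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .frap import FRAPTrace
from .image_metrics import CellImage, Linescan


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def read_config(path: str | Path) -> dict:
    """Load a TOML (or JSON) configuration file."""
    p = Path(path)
    if p.suffix == ".json":
        return json.loads(p.read_text())
    with open(p, "rb") as fh:
        return tomllib.load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write run metadata (version, seed, config hash + echo) as JSON."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    write_json(
        path,
        {
            "package": "ratiosense",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config),
            "config": config,
        },
    )
    return path


# --- images -----------------------------------------------------------------


def write_image(path: str | Path, image: CellImage) -> None:
    """Write intensity and ROI mask as a two-page 32-bit TIFF."""
    tifffile.imwrite(
        path,
        np.stack([image.intensity, image.roi_mask.astype(float)]).astype(np.float32),
    )


def read_image(path: str | Path, roi_path: str | Path | None = None) -> CellImage:
    """Read a TIFF image; the ROI comes from page 2 or a separate mask TIFF."""
    arr = tifffile.imread(path)
    if roi_path is not None:
        mask = tifffile.imread(roi_path) > 0
        intensity = arr if arr.ndim == 2 else arr[0]
    elif arr.ndim == 3 and arr.shape[0] >= 2:
        intensity, mask = arr[0], arr[1] > 0
    else:
        raise ParameterError("no ROI mask: pass roi_path or a two-page TIFF")
    return CellImage(intensity=np.asarray(intensity, float), roi_mask=mask)


# --- tables -----------------------------------------------------------------


def write_linescan(path: str | Path, ls: Linescan) -> None:
    pd.DataFrame(
        {"position": ls.positions, "intensity": ls.intensity}
    ).to_csv(path, index=False)


def read_linescan(path: str | Path, background: float = 0.0) -> Linescan:
    df = pd.read_csv(path)
    return Linescan(
        positions=df["position"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        background=background,
    )


def write_frap_trace(path: str | Path, trace: FRAPTrace) -> None:
    pd.DataFrame(
        {
            "time": trace.times,
            "bleach_signal": trace.bleach_signal,
            "cell_signal": trace.cell_signal,
        }
    ).to_csv(path, index=False)


def read_frap_trace(
    path: str | Path, bleach_radius: float = 1.0, n_prebleach: int = 0
) -> FRAPTrace:
    df = pd.read_csv(path)
    return FRAPTrace(
        times=df["time"].to_numpy(),
        bleach_signal=df["bleach_signal"].to_numpy(),
        cell_signal=df["cell_signal"].to_numpy(),
        bleach_radius=bleach_radius,
        n_prebleach=n_prebleach,
    )


def read_timelines(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_timelines(path: str | Path, timelines: pd.DataFrame) -> None:
    timelines.to_csv(path, index=False)
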