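"""Disk formats: multi-page TIFF stacks, CSV tables, YAML configs, JSON summaries.

CSV numeric fields are serialized at full precision (`repr` round-trip), so a
write-then-read cycle reproduces values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from azquant.containers import MovieStack


def save_stack(path: str | Path, stack: MovieStack) -> None:
    """Multi-page grayscale TIFF (page order = time) + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_um": stack.pixel_size_um,
        "stim_times_s": list(stack.stim_times_s) if stack.stim_times_s else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_stack(path: str | Path) -> MovieStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return MovieStack(
        data=data,
        frame_interval_s=meta.get("frame_interval_s", 1.0),
        pixel_size_um=meta.get("pixel_size_um", 1.0),
        stim_times_s=tuple(meta["stim_times_s"]) if meta.get("stim_times_s") else None,
    )


def save_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image), photometric="minisblack")


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    """CSV with full-precision floats (exact round-trip)."""
    table.to_csv(Path(path), index=False, float_format="%.17g")


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")


def save_config(path: str | Path, cfg) -> None:
    """Write a config (dataclass or mapping) as a YAML key-value file."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        d = dataclasses.asdict(cfg)
    else:
        d = dict(cfg)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_summary(path: str | Path, summary: dict) -> None:
    """Machine-readable headline statistics (versioned JSON schema)."""
    payload = {"schema_version": 1, **_jsonable(summary)}
    Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
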