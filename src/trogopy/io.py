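"""Readers and writers for on-disk artifacts.

Volumes travel as multi-page TIFF with dimension metadata embedded as a
JSON document in the TIFF image description; missing metadata is an error,
never a guess. Event tables are CSV (see :mod:`trogopy.events`), run
configuration is JSON, run logs are line-delimited JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import tifffile

from .volumes import LabelVolume, TimeLapseVolume

_STACK_KEYS = ("axes", "shape", "voxel_spacing_nm", "frame_interval_s", "channel_names")
_LABEL_KEYS = ("axes", "shape", "voxel_spacing_nm", "label_table")


def write_stack(vol: TimeLapseVolume, path: str | Path) -> None:
    """Write a ``(t, channel, z, y, x)`` stack as multi-page TIFF."""
    meta = {
        "axes": "TCZYX",
        "shape": list(vol.data.shape),
        "voxel_spacing_nm": list(vol.voxel_spacing_nm),
        "frame_interval_s": vol.frame_interval_s,
        "channel_names": list(vol.channel_names),
    }
    data = vol.data
    tifffile.imwrite(
        Path(path),
        data.reshape(-1, *data.shape[-2:]),
        description=json.dumps(meta, sort_keys=True),
        photometric="minisblack",
    )


def _read_description(path: Path, required: tuple[str, ...]) -> dict:
    try:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
            pages = tf.asarray()
    except Exception as exc:  # truncated / not a TIFF
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    try:
        meta = json.loads(desc or "{}")
    except json.JSONDecodeError:
        meta = {}
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(
            f"{path}: missing dimension metadata keys {missing}; "
            f"required keys are {list(required)}"
        )
    return {"meta": meta, "pages": pages}


def read_stack(path: str | Path) -> TimeLapseVolume:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    out = _read_description(path, _STACK_KEYS)
    meta, pages = out["meta"], out["pages"]
    shape = tuple(meta["shape"])
    data = np.asarray(pages).reshape(shape)
    return TimeLapseVolume(
        data=data,
        voxel_spacing_nm=tuple(meta["voxel_spacing_nm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channel_names=tuple(meta["channel_names"]),
    )


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    meta = {
        "axes": "ZYX" if labels.data.ndim == 3 else "TZYX",
        "shape": list(labels.data.shape),
        "voxel_spacing_nm": list(labels.voxel_spacing_nm),
        "label_table": {str(k): v for k, v in labels.label_table.items()},
    }
    tifffile.imwrite(
        Path(path),
        labels.data.reshape(-1, *labels.data.shape[-2:]),
        description=json.dumps(meta, sort_keys=True),
        photometric="minisblack",
    )


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    out = _read_description(path, _LABEL_KEYS)
    meta, pages = out["meta"], out["pages"]
    data = np.asarray(pages).reshape(tuple(meta["shape"]))
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"{path}: label volume must be integer-typed, got {data.dtype}")
    return LabelVolume(
        data=data,
        voxel_spacing_nm=tuple(meta["voxel_spacing_nm"]),
        label_table={int(k): v for k, v in meta["label_table"].items()},
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class RunLog:
    """Append-only line-delimited JSON run log."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def record(self, stage: str, *, seed: int | None = None, config: dict | None = None,
               **extra) -> None:
        entry = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stage": stage,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        }
        entry.update(extra)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")

    def entries(self) -> list[dict]:
        if not self.path.exists():
            return []
        with open(self.path) as fh:
            return [json.loads(line) for line in fh if line.strip()]
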