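"""File I/O: TIFF stacks with JSON sidecars, CSV tables, JSON reports.

Conventions (documented because particle-tracking CSV dialects differ):
header row, comma separation, coordinates in micrometres with the origin at
the illumination centre, frame indices 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import OpticalTimingConfig
from .simulate import ImageStack, PhotonTrace

__all__ = ["save_stack", "load_stack", "save_trace", "load_trace",
           "save_table", "load_table", "save_json", "RunLogger"]


def save_stack(stack: ImageStack, path) -> None:
    """Write a multi-page 16-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.uint16))
    sidecar = {
        "optical": dataclasses.asdict(stack.optical),
        "meta": stack.meta,
    }
    sidecar["optical"]["image_dim_px"] = list(stack.optical.image_dim_px)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    opt = dict(sidecar["optical"])
    opt["image_dim_px"] = tuple(opt["image_dim_px"])
    return ImageStack(data=data, optical=OpticalTimingConfig(**opt),
                      meta=sidecar.get("meta", {}))


def save_trace(trace: PhotonTrace, path) -> None:
    """Two-column CSV (bin_index, counts); dwell recorded in the header."""
    path = Path(path)
    df = pd.DataFrame({"bin_index": np.arange(len(trace.counts)),
                       "counts": trace.counts})
    with open(path, "w") as fh:
        fh.write(f"# dwell_s={trace.dwell_s!r}\n")
        df.to_csv(fh, index=False)


def load_trace(path) -> PhotonTrace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        dwell = float(first.split("=", 1)[1]) if first.startswith("#") else None
        df = pd.read_csv(fh) if dwell is not None else None
    if dwell is None:
        df = pd.read_csv(path)
        raise ValueError("trace CSV is missing the '# dwell_s=' header")
    return PhotonTrace(counts=df["counts"].to_numpy(np.int64), dwell_s=dwell)


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable))


class RunLogger:
    """Append-only machine-readable run log (JSON lines)."""

    def __init__(self, path):
        self.path = Path(path)

    def log(self, event: str, **fields) -> None:
        rec = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event}
        rec.update(fields)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=_jsonable) + "\n")
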