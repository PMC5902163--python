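"""Reading and writing the pipeline's on-disk formats.

Tables are CSV with a provenance header block of ``# key=value`` lines;
movies are multi-page 16-bit TIFF with a JSON sidecar carrying the frame
interval; ground truth and summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import Movie

__all__ = [
    "write_csv_with_meta",
    "read_csv_with_meta",
    "write_movie",
    "read_movie",
    "write_json",
]


def write_csv_with_meta(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_csv_with_meta(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def write_movie(movie: Movie, path: str | Path) -> None:
    """16-bit multi-page TIFF plus a `<stem>.meta.json` sidecar."""
    path = Path(path)
    data = movie.data
    scale = 1.0
    if data.max() > 65535:
        scale = 65535.0 / float(data.max())
    tifffile.imwrite(path, (data * scale).astype(np.uint16))
    sidecar = {
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "intensity_scale": scale,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    sidecar_path = path.with_suffix(".meta.json")
    meta = json.loads(sidecar_path.read_text())
    scale = meta.get("intensity_scale", 1.0) or 1.0
    return Movie(
        data=data / scale,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_um=meta.get("pixel_size_um"),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
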