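"""Reading and writing the pipeline's on-disk formats.

Traces travel as CSV with columns ``time_s,intensity,units`` plus an
optional JSON sidecar for convoy parameters and reporter geometry; movies
as multi-page TIFF (dimension order t, z, y, x, documented in a JSON
sidecar); per-cell counts as CSV with columns ``cell_id,nascent,mature``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .convoy import ConvoyParams, GeneGeometry, IntensityTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_params_json",
    "read_params_json",
    "write_movie_tiff",
    "read_movie_tiff",
]


def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "intensity": trace.values, "units": trace.units}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> IntensityTrace:
    df = pd.read_csv(path)
    units = str(df["units"].iloc[0]) if "units" in df else "arbitrary"
    return IntensityTrace(
        df["time_s"].to_numpy(float), df["intensity"].to_numpy(float), units=units
    )


def write_params_json(
    path: str | Path,
    params: ConvoyParams | None = None,
    geom: GeneGeometry | None = None,
    extra: dict | None = None,
) -> None:
    doc: dict = dict(extra or {})
    if params is not None:
        doc["convoy_params"] = dataclasses.asdict(params)
    if geom is not None:
        doc["geometry"] = dataclasses.asdict(geom)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_params_json(
    path: str | Path,
) -> tuple[ConvoyParams | None, GeneGeometry | None, dict]:
    doc = json.loads(Path(path).read_text())
    params = (
        ConvoyParams(**doc["convoy_params"]) if "convoy_params" in doc else None
    )
    geom = GeneGeometry(**doc["geometry"]) if "geometry" in doc else None
    extra = {k: v for k, v in doc.items() if k not in ("convoy_params", "geometry")}
    return params, geom, extra


def write_movie_tiff(
    stack: np.ndarray, path: str | Path, frame_interval_s: float | None = None
) -> None:
    """Write a (t, z, y, x) stack; a JSON sidecar documents the axis order."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )
    sidecar = {"axes": "TZYX", "shape": list(stack.shape)}
    if frame_interval_s is not None:
        sidecar["frame_interval_s"] = frame_interval_s
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return np.asarray(stack), sidecar
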