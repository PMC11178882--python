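"""File formats: multi-page TIFF movies with JSON sidecars, CSV tables.

Movies are written as 16-bit multi-page TIFF, one page per frame, with a
JSON sidecar carrying the acquisition metadata (frame rate, pixel size,
seed, protocol).  Ground-truth spikes and traces go to plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, Movie

__all__ = ["write_movie", "read_movie", "write_ground_truth",
           "read_spike_csv", "write_trace_csv", "write_targets_csv",
           "read_targets_csv", "write_weights_tiff"]


def write_weights_tiff(path: str | Path, weights) -> Path:
    """Pixel-weight image as 32-bit float TIFF."""
    path = Path(path)
    img = weights.weights if hasattr(weights, "weights") else weights
    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    return path


def write_movie(path: str | Path, movie: Movie) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    sidecar = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        **movie.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    frame_rate = meta.pop("frame_rate_hz", 500.0)
    pixel_size = meta.pop("pixel_size_um", 0.1625)
    return Movie(np.asarray(data), frame_rate, pixel_size, meta)


def write_ground_truth(dirpath: str | Path, truth: GroundTruth) -> None:
    dirpath = Path(dirpath)
    rows = [(cid, t) for cid, times in truth.spike_times_ms.items()
            for t in times]
    pd.DataFrame(rows, columns=["cell_id", "spike_time_ms"]).to_csv(
        dirpath / "ground_truth_spikes.csv", index=False)
    params = {
        "protocol_id": truth.protocol.protocol_id,
        "holding_mv": truth.protocol.holding_mv,
        "illumination_epochs_ms": list(map(list,
                                           truth.protocol.illumination_epochs_ms)),
        "step_amplitudes_mv": list(truth.protocol.step_amplitudes_mv),
        "bleach_end_fraction_3s": truth.bleach.end_fraction_3s,
        "bleach_recovery_fraction": truth.bleach.recovery_fraction,
        "seed": truth.seed,
    }
    (dirpath / "ground_truth_params.json").write_text(
        json.dumps(params, indent=2))


def read_spike_csv(path: str | Path, cell_id: int | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    return df["spike_time_ms"].to_numpy(dtype=float)


def write_trace_csv(path: str | Path, times_ms, raw, detrended=None,
                    dff_pct=None) -> None:
    cols = {"time_ms": times_ms, "raw": raw}
    if detrended is not None:
        cols["detrended"] = detrended
    if dff_pct is not None:
        cols["dff_pct"] = dff_pct
    pd.DataFrame(cols).to_csv(path, index=False)


def write_targets_csv(path: str | Path, cells) -> None:
    pd.DataFrame(
        [(i, c.centroid_um[0], c.centroid_um[1]) for i, c in enumerate(cells)],
        columns=["cell_id", "x_um", "y_um"]).to_csv(path, index=False)


def read_targets_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(r.x_um), float(r.y_um)) for r in df.itertuples()]
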