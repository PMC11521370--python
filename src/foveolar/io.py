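"""CSV/JSON/TIFF readers and writers for the pipeline's file dialects.

Units are embedded in column names: positions in arcmin (``x_arcmin``) or
raster pixels (``x_px``, requiring a pixel scale to convert), times in ms,
densities in cones/deg^2.  Readers auto-detect the pixel vs arcmin dialect
and refuse ambiguous files; malformed rows are reported with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from foveolar.drift import DriftMetrics, GazeTrace
from foveolar.mosaic import ConeMosaic, DensityMap, FoveolarLandmarks
from foveolar.psychophysics import TrialRecord

__all__ = [
    "read_cone_csv", "write_cone_csv",
    "read_trace_csv", "write_trace_csv",
    "read_trials_csv", "write_trials_csv",
    "write_landmarks_json", "read_landmarks_json",
    "write_density_tiff", "write_density_csv",
    "write_metrics_csv", "write_run_log",
]


class FormatError(ValueError):
    """Structured file-format error with location information."""


def read_cone_csv(path, image_extent, pixel_scale_arcmin: float = 0.1
                  ) -> ConeMosaic:
    """Read cone centers from CSV with ``x_px,y_px`` or ``x_arcmin,y_arcmin``.

    Pixel-unit files are converted with ``pixel_scale_arcmin``.  Files
    carrying both or neither dialect are refused as ambiguous.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    has_px = {"x_px", "y_px"} <= cols
    has_am = {"x_arcmin", "y_arcmin"} <= cols
    if has_px and has_am:
        raise FormatError(f"{path}: both pixel and arcmin columns present; "
                          "ambiguous units")
    if has_px:
        xy = df[["x_px", "y_px"]].to_numpy(dtype=float) * pixel_scale_arcmin
    elif has_am:
        xy = df[["x_arcmin", "y_arcmin"]].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: need columns x_px,y_px or "
                          f"x_arcmin,y_arcmin; found {sorted(cols)}")
    bad = np.flatnonzero(~np.isfinite(xy).all(axis=1))
    if bad.size:
        raise FormatError(f"{path}: non-numeric coordinates at data line(s) "
                          f"{(bad + 2).tolist()}")
    return ConeMosaic(cone_centers=xy, image_extent=image_extent,
                      pixel_scale=pixel_scale_arcmin)


def write_cone_csv(mosaic: ConeMosaic, path) -> None:
    pd.DataFrame(mosaic.cone_centers, columns=["x_arcmin", "y_arcmin"]
                 ).to_csv(path, index=False)


def read_trace_csv(path, frame_rate_hz: float = 30.0,
                   window_ms: tuple[float, float] | None = None
                   ) -> list[GazeTrace]:
    """Read per-trial gaze traces from ``trial,frame,t_ms,x_arcmin,y_arcmin``.

    Returns one GazeTrace per trial id.  Non-monotone timestamps within a
    trial are a structured error; a missing-frame gap is tolerated here (the
    drift stage flags blinks from gaps).
    """
    df = pd.read_csv(path)
    need = {"trial", "t_ms", "x_arcmin", "y_arcmin"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: missing columns "
                          f"{sorted(need - set(df.columns))}")
    traces = []
    for trial, g in df.groupby("trial", sort=True):
        t = g["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise FormatError(f"{path}: non-monotone t_ms in trial {trial} "
                              f"near data line {g.index[k] + 2}")
        traces.append(GazeTrace(
            times_ms=t,
            xy=g[["x_arcmin", "y_arcmin"]].to_numpy(dtype=float),
            trial_id=int(trial), frame_rate_hz=frame_rate_hz,
            window_ms=window_ms))
    return traces


def write_trace_csv(traces: list[GazeTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trial": tr.trial_id,
            "frame": np.arange(len(tr.times_ms)),
            "t_ms": tr.times_ms,
            "x_arcmin": tr.xy[:, 0],
            "y_arcmin": tr.xy[:, 1],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    need = {"run", "trial", "gap_arcsec", "orientation", "response"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: missing columns "
                          f"{sorted(need - set(df.columns))}")
    return [TrialRecord(run=int(r.run), trial=int(r.trial),
                        gap_arcsec=float(r.gap_arcsec),
                        orientation=str(r.orientation),
                        response=str(r.response),
                        correct=str(r.response) == str(r.orientation))
            for r in df.itertuples()]


def write_trials_csv(trials: list[TrialRecord], path) -> None:
    pd.DataFrame([{
        "run": t.run, "trial": t.trial, "gap_arcsec": t.gap_arcsec,
        "orientation": t.orientation, "response": t.response,
        "correct": t.correct,
    } for t in trials]).to_csv(path, index=False)


def write_landmarks_json(landmarks: FoveolarLandmarks, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=2))


def read_landmarks_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_density_tiff(dmap: DensityMap, path) -> None:
    """Density map as 32-bit float TIFF with resolution metadata."""
    tifffile.imwrite(path, dmap.values.astype(np.float32),
                     metadata={"pixel_scale_arcmin": dmap.pixel_scale,
                               "stride": dmap.stride, "k": dmap.k})


def write_density_csv(dmap: DensityMap, path) -> None:
    np.savetxt(path, dmap.values, delimiter=",", fmt="%.3f")


def write_metrics_csv(metrics: list[DriftMetrics], path) -> None:
    pd.DataFrame([vars(m) for m in metrics]).to_csv(path, index=False)


def write_run_log(path, **entries) -> None:
    """JSON run log: seed, parameters, versions, exclusion counts."""
    import foveolar
    log = {"foveolar_version": foveolar.__version__}
    log.update(entries)
    Path(path).write_text(json.dumps(log, indent=2, default=str))
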