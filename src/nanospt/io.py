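"""Shared file formats: trajectory CSV, TIFF movies, polygon files, JSON.

All writes are atomic (write to a temp file in the target directory,
then rename), so a crashed run never leaves a half-written artifact.
The trajectory CSV schema is the single canonical exchange format used
by every module: columns particle_id, frame, t_s, x_um, y_um, mass.
"""

from __future__ import annotations

import json
import os
import tempfile
from io import BytesIO
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .synthdata import NucleusMap, SaturationCurve, SyntheticMovie
from .tracking import Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "atomic_write_bytes",
    "atomic_write_text",
    "write_json",
    "read_json",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_saturation_csv",
    "read_saturation_csv",
    "write_nucleus_map_csv",
    "read_nucleus_map_csv",
]

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um", "mass"]
SCHEMA_COMMENT = "# nanospt trajectory schema v1\n"


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: str | Path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def write_json(path: str | Path, obj: Any) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_trajectories_csv(path: str | Path, trajs: list[Trajectory]) -> None:
    """Write trajectories in the canonical CSV schema (header mandatory)."""
    frames = []
    for tr in trajs:
        if len(tr) > 1:
            frame_idx = np.rint(tr.t_s / tr.frame_interval_s).astype(int)
        else:
            frame_idx = np.zeros(1, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": tr.particle_id,
                    "frame": frame_idx,
                    "t_s": tr.t_s,
                    "x_um": tr.x_um,
                    "y_um": tr.y_um,
                    "mass": tr.mass,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    atomic_write_text(path, SCHEMA_COMMENT + df.to_csv(index=False))


def read_trajectories_csv(path: str | Path, pixel_size_um: float = 1.0) -> list[Trajectory]:
    """Read the canonical trajectory CSV back into Trajectory objects."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {missing}")
    trajs = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("t_s")
        trajs.append(
            Trajectory(
                particle_id=int(pid),
                t_s=grp["t_s"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                mass=grp["mass"].to_numpy(),
                pixel_size_um=pixel_size_um,
            )
        )
    return trajs


def write_movie_tiff(path: str | Path, movie: SyntheticMovie) -> None:
    """Write a movie as 16-bit multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = np.clip(np.rint(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    buf = BytesIO()
    tifffile.imwrite(buf, frames, photometric="minisblack")
    atomic_write_bytes(path, buf.getvalue())
    write_json(
        path.with_suffix(".json"),
        {
            "pixel_size_um": movie.pixel_size_um,
            "frame_interval_s": movie.frame_interval_s,
            "psf_sigma_px": movie.psf_sigma_px,
            "background_level": movie.background_level,
            "noise_model": movie.noise_model,
            "clipped": movie.clipped,
            "seed": movie.seed,
        },
    )


def read_movie_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    meta = read_json(sidecar) if sidecar.exists() else {}
    return stack.astype(float), meta


def write_saturation_csv(path: str | Path, curve: SaturationCurve) -> None:
    df = pd.DataFrame(
        {
            "power_uW": curve.P_exc_uW,
            "counts_per_s": curve.detected_counts_per_s,
            "direction": curve.direction,
        }
    )
    atomic_write_text(path, df.to_csv(index=False))


def read_saturation_csv(path: str | Path, integration_s: float = 1.0) -> SaturationCurve:
    df = pd.read_csv(path)
    for col in ("power_uW", "counts_per_s"):
        if col not in df.columns:
            raise ValueError(f"saturation CSV is missing column {col!r}")
    direction = (
        df["direction"].to_numpy()
        if "direction" in df.columns
        else np.array(["up"] * len(df))
    )
    return SaturationCurve(
        P_exc_uW=df["power_uW"].to_numpy(dtype=float),
        detected_counts_per_s=df["counts_per_s"].to_numpy(dtype=float),
        integration_s=integration_s,
        direction=direction,
    )


def write_nucleus_map_csv(path: str | Path, nmap: NucleusMap) -> None:
    """Write nucleus polygons as a vertex list CSV (polygon_id, x_um, y_um)."""
    rows = []
    for i, ring in enumerate(nmap.polygons):
        for x, y in ring:
            rows.append((i, x, y))
    df = pd.DataFrame(rows, columns=["polygon_id", "x_um", "y_um"])
    atomic_write_text(path, df.to_csv(index=False))


def read_nucleus_map_csv(path: str | Path) -> NucleusMap:
    df = pd.read_csv(path)
    for col in ("polygon_id", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"nucleus CSV is missing column {col!r}")
    rings = []
    for _, grp in df.groupby("polygon_id", sort=True):
        ring = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.allclose(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[:1]])
        rings.append(ring)
    return NucleusMap(polygons=rings)
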