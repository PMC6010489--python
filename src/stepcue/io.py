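"""Readers and writers for the package's tabular interchange formats.

CSV is canonical.  Step-length files carry columns ``id, condition,
length_m``; trajectory files carry ``id, condition, point_index, x_m,
y_m``.  XLSX files with the same column layout are accepted for
supplementary-style tables.  Invalid rows (missing values, non-positive
lengths) are rejected per row and counted, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import StepSample
from .segmentation import Trajectory

logger = logging.getLogger("stepcue")

__all__ = [
    "read_step_lengths",
    "write_step_lengths",
    "read_trajectories",
    "write_trajectories",
    "write_field",
]

_STEP_COLS = ["id", "condition", "length_m"]
_TRAJ_COLS = ["id", "condition", "point_index", "x_m", "y_m"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_step_lengths(path) -> list[StepSample]:
    """Read per-individual step lengths; rejects bad rows with a logged count."""
    df = _read_table(path)
    missing = set(_STEP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ok = df["length_m"].notna() & (pd.to_numeric(df["length_m"], errors="coerce") > 0)
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("%s: rejected %d invalid rows of %d", path, rejected, len(df))
    df = df[ok]
    samples = []
    for (ind, cond), grp in df.groupby(["id", "condition"], sort=False):
        samples.append(
            StepSample(grp["length_m"].to_numpy(float), individual=str(ind),
                       condition=str(cond))
        )
    logger.info("%s: read %d samples (%d rows)", path, len(samples), len(df))
    return samples


def write_step_lengths(samples: list[StepSample], path) -> None:
    rows = [
        {"id": s.individual, "condition": s.condition, "length_m": float(l)}
        for s in samples
        for l in s.lengths
    ]
    pd.DataFrame(rows, columns=_STEP_COLS).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read digitized trajectories; rows with NaN coordinates are rejected."""
    df = _read_table(path)
    missing = set(_TRAJ_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ok = df[["x_m", "y_m", "point_index"]].notna().all(axis=1)
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("%s: rejected %d invalid rows of %d", path, rejected, len(df))
    df = df[ok]
    trajs = []
    for (ind, cond), grp in df.groupby(["id", "condition"], sort=False):
        grp = grp.sort_values("point_index")
        trajs.append(
            Trajectory(points=grp[["x_m", "y_m"]].to_numpy(float),
                       id=str(ind), condition=str(cond))
        )
    return trajs


def write_trajectories(trajs: list[Trajectory], path) -> None:
    rows = []
    for t in trajs:
        for i, (x, y) in enumerate(t.points):
            rows.append({"id": t.id, "condition": t.condition,
                         "point_index": i, "x_m": float(x), "y_m": float(y)})
    pd.DataFrame(rows, columns=_TRAJ_COLS).to_csv(path, index=False)


def write_field(field, path_csv, path_json) -> None:
    """Serialize a cue field: points as CSV, geometry as a JSON sidecar."""
    pd.DataFrame(field.points, columns=["x_m", "y_m"]).to_csv(path_csv, index=False)
    meta = {
        "rho": field.rho, "delta": field.delta, "D": field.D,
        "domain": field.domain, "seed": field.seed,
        "n_points": int(len(field.points)),
    }
    Path(path_json).write_text(json.dumps(meta, indent=2))
    if field.mask is not None:
        mask_path = Path(path_csv).with_suffix(".mask.txt")
        np.savetxt(mask_path, field.mask.astype(int), fmt="%d")
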