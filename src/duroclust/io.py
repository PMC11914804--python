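"""Writers for trajectories, field snapshots and cluster-metric tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import ClusterShape
from .experiments import RunResult


def trajectory_frame(result: RunResult) -> pd.DataFrame:
    """Long-format trajectory table: time, cell_id, x, y, phi per frame."""
    rec = result.record
    if rec.trajectory is None:
        raise ValueError("run was executed without trajectory recording")
    frames, nc, _ = rec.trajectory.shape
    return pd.DataFrame(
        {
            "time": np.repeat(rec.times, nc),
            "cell_id": np.tile(np.arange(nc), frames),
            "x": rec.trajectory[:, :, 0].ravel(),
            "y": rec.trajectory[:, :, 1].ravel(),
            "phi": rec.trajectory[:, :, 2].ravel(),
        }
    )


def write_trajectory(result: RunResult, path: str | Path) -> None:
    trajectory_frame(result).to_csv(path, index=False)


def write_timeseries(result: RunResult, path: str | Path) -> None:
    """Cluster-number, degraded-area and speed time series as CSV."""
    pd.DataFrame(
        {
            "time": result.times,
            "S1": result.S1,
            "S2": result.S2,
            "degraded_percent": result.degraded_percent,
            "mean_speed": result.mean_speed,
            "mean_local_rho": result.record.mean_local_rho,
        }
    ).to_csv(path, index=False)


def write_fields(fields, path: str | Path, time: float = 0.0) -> None:
    """Field snapshot (ux, uy, C, rho) with grid metadata (N, dx, time)."""
    np.savez(
        path,
        time=time,
        N=fields.N,
        dx=fields.dx,
        ux=fields.ux,
        uy=fields.uy,
        C=fields.C,
        rho=fields.rho,
    )


def read_fields(path: str | Path):
    """Load a snapshot written by :func:`write_fields`."""
    from .state import SubstrateFields

    with np.load(path) as data:
        fields = SubstrateFields(
            int(data["N"]), float(data["dx"]),
            data["ux"], data["uy"], data["C"], data["rho"],
        )
        return fields, float(data["time"])


def shapes_frame(shapes: list[ClusterShape]) -> pd.DataFrame:
    """Per-cluster metric table (one row per analyzed cluster)."""
    return pd.DataFrame(
        {
            "size": [s.size for s in shapes],
            "length": [s.length for s in shapes],
            "width": [s.width for s in shapes],
            "aspect_ratio": [s.aspect_ratio for s in shapes],
            "connectivity_index": [s.connectivity_index for s in shapes],
            "area": [s.area for s in shapes],
            "axis_geo_x": [s.major_axis_geometric[0] for s in shapes],
            "axis_geo_y": [s.major_axis_geometric[1] for s in shapes],
            "axis_cov_x": [s.major_axis_covariance[0] for s in shapes],
            "axis_cov_y": [s.major_axis_covariance[1] for s in shapes],
            "isotropic": [s.isotropic for s in shapes],
        }
    )
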