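"""Snapshot and trajectory serialization.

Tissue snapshots go to flat CSV (one row per node: id, class, cell id,
region, x, y) readable by any downstream tool; full trajectories go to a
compressed ``.npz`` container (metric time series plus the final node
table).  Both round-trip through their readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .state import NodeClass, Region, TissueState

__all__ = [
    "snapshot_to_dataframe",
    "write_snapshot_csv",
    "read_snapshot_csv",
    "write_trajectory_npz",
    "read_trajectory_npz",
]


def snapshot_to_dataframe(state: TissueState) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": np.arange(state.n_nodes),
            "node_class": [NodeClass.NAMES[c] for c in state.node_class],
            "cell_id": state.cell_id,
            "region": [Region.NAMES[r] for r in state.region],
            "x": state.pos[:, 0],
            "y": state.pos[:, 1],
        }
    )


def write_snapshot_csv(state: TissueState, path) -> None:
    snapshot_to_dataframe(state).to_csv(path, index=False)


def read_snapshot_csv(path) -> pd.DataFrame:
    """Read a node-table snapshot back; validates the column contract."""
    df = pd.read_csv(path)
    expected = ["node_id", "node_class", "cell_id", "region", "x", "y"]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot file missing columns: {sorted(missing)}")
    return df[expected]


def write_trajectory_npz(traj, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        times=traj.times,
        global_curvature=traj.global_curvature,
        mean_nuclear_fraction=traj.mean_nuclear_fraction,
        mean_height=traj.mean_height,
        converged=np.array(traj.converged),
        steps_run=np.array(traj.steps_run),
        final_pos=traj.final_state.pos,
        final_node_class=traj.final_state.node_class,
        final_cell_id=traj.final_state.cell_id,
        final_region=traj.final_state.region,
    )


def read_trajectory_npz(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
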