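"""Tidy CSV / JSON serialization of trajectories and run summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .core import class_labels, classify_outcome
from .simulate import Trajectory

__all__ = ["trajectory_to_frame", "save_trajectory_csv", "save_replicate_summary"]


def trajectory_to_frame(traj: Trajectory, replicate_id: int = 0) -> pd.DataFrame:
    """Long-format trajectory: (replicate_id, generation, class_label, count).

    Rows with zero count are dropped; absent (class, generation) pairs are
    implicitly zero.
    """
    counts = traj.counts_matrix()
    names = class_labels(traj.params)
    frame = pd.DataFrame(counts, columns=names)
    frame["generation"] = range(len(traj.states))
    long = frame.melt(
        id_vars="generation", var_name="class_label", value_name="count"
    )
    long = long[long["count"] > 0].reset_index(drop=True)
    long.insert(0, "replicate_id", replicate_id)
    return long.sort_values(["generation", "class_label"], ignore_index=True)


def save_trajectory_csv(traj: Trajectory, path: str | Path, replicate_id: int = 0):
    trajectory_to_frame(traj, replicate_id).to_csv(path, index=False)


def save_replicate_summary(traj: Trajectory, path: str | Path, replicate_id: int = 0):
    """JSON summary of one replicate: parameter echo, seed and outcome flags."""
    outcome = classify_outcome(traj.final, traj.params)
    payload = {
        "software": {"name": "compensim", "version": __version__},
        "replicate_id": replicate_id,
        "params": dataclasses.asdict(traj.params),
        "outcome": dataclasses.asdict(outcome),
        "final_counts_nonzero": {
            name: int(k)
            for name, k in zip(class_labels(traj.params), traj.final.counts)
            if k > 0
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
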