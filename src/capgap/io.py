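"""Readers and writers for OpenSim-style STO/MOT files and plain CSV.

STO/MOT dialect: a small text header terminated by ``endheader``, then a
tab-delimited table whose first column is ``time``.  CSV is RFC-4180
with a header row.  Both round-trip through pandas DataFrames.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import TrialData
from .static_opt import TrialSolution

__all__ = [
    "read_sto",
    "write_sto",
    "read_table",
    "write_table",
    "trial_to_frame",
    "trial_from_frame",
    "solution_to_frame",
]


def write_sto(path, df: pd.DataFrame, name: str | None = None) -> None:
    """Write a DataFrame (first column ``time``) as a tab-delimited STO file."""
    path = Path(path)
    if df.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    lines = [
        name or path.stem,
        "version=1",
        f"nRows={len(df)}",
        f"nColumns={len(df.columns)}",
        "inDegrees=no",
        "endheader",
        "\t".join(df.columns),
    ]
    body = "\n".join(
        "\t".join(format(v, ".10g") for v in row) for row in df.to_numpy(dtype=float)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_sto(path) -> pd.DataFrame:
    """Read a tab-delimited STO/MOT file (header ends at ``endheader``)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    try:
        start = next(i for i, line in enumerate(lines) if line.strip() == "endheader") + 1
    except StopIteration:
        raise ValueError(f"{path}: no 'endheader' line — not an STO/MOT file") from None
    header = lines[start].strip().split("\t")
    data = np.loadtxt(lines[start + 1 :], ndmin=2)
    if data.shape[1] != len(header):
        raise ValueError(f"{path}: column count mismatch")
    return pd.DataFrame(data, columns=header)


def write_table(path, df: pd.DataFrame, fmt: str = "csv", name: str | None = None) -> None:
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "sto":
        write_sto(path, df, name=name)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".sto", ".mot"):
        return read_sto(path)
    return pd.read_csv(path)


def trial_to_frame(trial: TrialData) -> pd.DataFrame:
    """Flatten a trial to one table: time, per-DOF angle/velocity/moment."""
    data = {"time": trial.time}
    for k, dof in enumerate(trial.dof_names):
        data[f"{dof}_angle"] = trial.angles[:, k]
        data[f"{dof}_velocity"] = trial.angular_velocities[:, k]
        data[f"{dof}_moment"] = trial.net_moments[:, k]
    data["percent_cycle"] = trial.percent_cycle
    return pd.DataFrame(data)


def trial_from_frame(df: pd.DataFrame, activity: str, body_mass: float) -> TrialData:
    """Rebuild a TrialData from a table written by :func:`trial_to_frame`."""
    dof_names = [c[: -len("_angle")] for c in df.columns if c.endswith("_angle")]
    return TrialData(
        activity=activity,
        time=df["time"].to_numpy(),
        dof_names=dof_names,
        angles=np.column_stack([df[f"{d}_angle"].to_numpy() for d in dof_names]),
        angular_velocities=np.column_stack(
            [df[f"{d}_velocity"].to_numpy() for d in dof_names]
        ),
        net_moments=np.column_stack([df[f"{d}_moment"].to_numpy() for d in dof_names]),
        body_mass=body_mass,
        percent_cycle=df["percent_cycle"].to_numpy() if "percent_cycle" in df else None,
    )


def solution_to_frame(sol: TrialSolution) -> pd.DataFrame:
    """Per-frame activations, reserve activations and reserve moments."""
    data = {"time": sol.time}
    for j, m in enumerate(sol.muscle_names):
        data[f"{m}_activation"] = sol.activations[:, j]
    for k, dof in enumerate(sol.dof_names):
        data[f"reserve_{dof}_activation"] = sol.reserve_activations[:, k]
        data[f"reserve_{dof}_moment"] = sol.reserve_moments[:, k]
    return pd.DataFrame(data)
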