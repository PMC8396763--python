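"""Plain-text IO: trial trajectory TSV files and the tabular CSV outputs.

Trajectory files carry columns ``frame, time_s`` followed by
``<marker>_X/_Y/_Z`` in metres for the hip and both feet, one file per
trial, named ``P<participant>_T<trial>.tsv``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .datatypes import REQUIRED_MARKERS, MarkerTrajectory

_AXES = ("X", "Y", "Z")


def trajectory_to_frame(traj: MarkerTrajectory) -> pd.DataFrame:
    data = {
        "frame": np.arange(traj.n_samples),
        "time_s": traj.time,
    }
    for marker in REQUIRED_MARKERS:
        for a, axis in enumerate(_AXES):
            data[f"{marker}_{axis}"] = traj.positions[marker][:, a]
    return pd.DataFrame(data)


def write_trajectory_tsv(traj: MarkerTrajectory, path) -> Path:
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, sep="\t", index=False,
                                     float_format="%.6f")
    return path


def trial_filename(participant_id: str, trial_id) -> str:
    return f"{participant_id}_T{int(trial_id):03d}.tsv"


_NAME_RE = re.compile(r"(?P<participant>[^_]+)_T(?P<trial>\d+)\.tsv$")


def read_trajectory_tsv(path) -> MarkerTrajectory:
    """Read one trial TSV back into a :class:`MarkerTrajectory`.

    The sampling rate is recovered from the median time step; participant
    and trial ids are parsed from the ``P<participant>_T<trial>.tsv``
    naming convention when the filename matches it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["time_s"] + [f"{m}_{a}" for m in REQUIRED_MARKERS
                             for a in _AXES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    time = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(time)))
    positions = {
        m: df[[f"{m}_{a}" for a in _AXES]].to_numpy(float)
        for m in REQUIRED_MARKERS
    }
    meta = {"source": str(path)}
    m = _NAME_RE.search(path.name)
    if m:
        meta["participant_id"] = m.group("participant")
        meta["trial_id"] = int(m.group("trial"))
    return MarkerTrajectory(
        time=time, positions=positions, sampling_rate=1.0 / dt, meta=meta,
    )


def list_trajectory_files(directory) -> List[Path]:
    return sorted(Path(directory).glob("*.tsv"))


def write_binary_png(binary: np.ndarray, path) -> Path:
    """Write a boolean raster as an 8-bit grayscale PNG fixture."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray((np.asarray(binary, dtype=np.uint8) * 255))
    img.save(path)
    return path
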