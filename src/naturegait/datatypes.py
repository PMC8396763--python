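"""Core domain containers shared by all pipeline stages.

Coordinate convention throughout: X is lateral movement, Y is the direction
of travel down the laboratory, Z is vertical. Positions are in metres,
times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Markers required by the gait analysis.
REQUIRED_MARKERS = ("hip", "left_foot", "right_foot")

#: QC flags a trial can accumulate.
QC_MISSING_MARKERS = "missing_markers"
QC_OVERLONG_STEP = "overlong_step"
QC_SAME_FOOT_REPEAT = "same_foot_repeat"
QC_TOO_FEW_STEPS = "too_few_steps"


@dataclass
class MarkerTrajectory:
    """Time-indexed 3D positions for the named markers of one walking trial.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Uniformly spaced sample times in seconds.
    positions : dict of str -> ndarray, shape (n, 3)
        Per-marker coordinates in metres, columns (X, Y, Z).
    sampling_rate : float
        Samples per second.
    meta : dict
        Free-form provenance (participant/trial ids, synthesis ground
        truth, processing markers such as ``truncated``).
    """

    time: np.ndarray
    positions: dict
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trajectory needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time spacing must equal 1/sampling_rate")
        for name in REQUIRED_MARKERS:
            if name not in self.positions:
                raise ValueError(f"missing required marker {name!r}")
        self.positions = {
            k: np.asarray(v, dtype=float) for k, v in self.positions.items()
        }
        for name, pos in self.positions.items():
            if pos.shape != (self.time.size, 3):
                raise ValueError(
                    f"marker {name!r} must have shape (n_samples, 3)"
                )

    @property
    def n_samples(self) -> int:
        return self.time.size

    def copy_with(self, positions: dict, time: Optional[np.ndarray] = None,
                  **meta) -> "MarkerTrajectory":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return MarkerTrajectory(
            time=self.time if time is None else time,
            positions=positions,
            sampling_rate=self.sampling_rate,
            meta=new_meta,
        )

    def has_missing(self) -> bool:
        """True if any required marker contains NaN samples."""
        return any(
            np.isnan(self.positions[m]).any() for m in REQUIRED_MARKERS
        )


@dataclass
class StationaryPeriod:
    """Maximal run of samples in which a foot marker stays put (stance proxy)."""

    foot: str
    start_index: int
    end_index: int  # inclusive
    mid_position: np.ndarray

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")


@dataclass
class StepEvent:
    """One detected footfall.

    ``position_y`` is the Y coordinate of the foot marker at the middle of
    the stationary period; ``landing_time`` is the time of maximal Y
    deceleration before the period, ``lifting_time`` the time of maximal
    Y acceleration after it.
    """

    foot: str
    position: np.ndarray
    landing_time: float
    lifting_time: float
    mid_index: int = -1

    @property
    def position_y(self) -> float:
        return float(self.position[1])


@dataclass
class GaitParams:
    """Per-trial step lengths and stride times plus the QC flags raised
    while deriving them."""

    step_lengths: np.ndarray
    stride_times: np.ndarray
    qc_flags: set
    n_steps_used: int


@dataclass
class TrialGait:
    """Per-trial gait summary used as the modelling outcome."""

    mean_velocity: float
    mean_step_length: float
    mean_stride_time: float
    step_length_sd: float
    stride_time_sd: float
    n_steps_used: int
    qc_flags: set = field(default_factory=set)

    @property
    def is_clean(self) -> bool:
        return not self.qc_flags


@dataclass
class ImageMeta:
    """Stimulus image metadata: environment label, norming-sample liking
    score, pair membership, and optional fractal dimension / mean
    discomfort."""

    image_id: str
    environment: str  # {nature, urban, control}
    liking: Optional[float] = None
    pair_id: Optional[str] = None
    fractal_dim: Optional[float] = None
    discomfort_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.environment not in ("nature", "urban", "control"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.liking is not None and not (1.0 <= self.liking <= 7.0):
            raise ValueError("liking must lie on the 7-point scale [1, 7]")


@dataclass
class TrueTrialParams:
    """Latent ground truth for one synthetic walking trial."""

    participant_id: str
    image_id: str
    trial_id: int
    true_velocity: float
    true_step_length: float
    true_stride_time: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.true_velocity <= 0 or self.true_stride_time <= 0:
            raise ValueError("velocity and stride time must be positive")
        if not (0 < self.true_step_length < 1.3):
            raise ValueError("step length must lie in (0, 1.3) m")
        if self.n_steps < 6:
            raise ValueError("need at least 6 steps per trial")
        v_implied = 2.0 * self.true_step_length / self.true_stride_time
        if abs(v_implied - self.true_velocity) > 0.05 * self.true_velocity:
            raise ValueError(
                "kinematically inconsistent: v != 2*step_length/stride_time "
                "within 5%"
            )


@dataclass
class ParticipantRecord:
    """Participant-level bookkeeping used for cohort exclusions."""

    participant_id: str
    task: str  # {memory, discomfort}
    prop_valid_data: float = 1.0
    memory_accuracy: Optional[float] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.task not in ("memory", "discomfort"):
            raise ValueError(f"unknown task {self.task!r}")
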