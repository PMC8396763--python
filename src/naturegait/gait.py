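"""Step detection and gait parametrisation from 3D marker trajectories.

The processing chain mirrors standard walkway practice: zero-phase 5 Hz
low-pass filtering of hip and foot markers, truncation of the acceleration
(first 0.5 m) and deceleration (last 2 m) portions of the 12 m capture
space, stance detection as stationary periods of each foot marker (< 5 cm
displacement over 0.1 s), landing/lifting times from Y-axis acceleration
extrema, and per-trial summaries of step length, stride time, velocity and
their variabilities, with quality-control flags for inconsistent walking
(missing markers, steps over 1.3 m, consecutive same-foot steps).
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    QC_MISSING_MARKERS,
    QC_OVERLONG_STEP,
    QC_SAME_FOOT_REPEAT,
    QC_TOO_FEW_STEPS,
    REQUIRED_MARKERS,
    GaitParams,
    MarkerTrajectory,
    StationaryPeriod,
    StepEvent,
    TrialGait,
)

MAX_STEP_LENGTH_M = 1.3  # steps longer than this mark a trial inconsistent


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def butterworth_zero_phase_gain(freq, cutoff: float = 5.0, order: int = 2):
    """Squared-magnitude gain of an order-``order`` Butterworth low-pass
    applied forward and backward: 1 / (1 + (f/fc)^(2*order))."""
    freq = np.asarray(freq, dtype=float)
    return 1.0 / (1.0 + (freq / cutoff) ** (2 * order))


def _spectral_lowpass(x: np.ndarray, fs: float, cutoff: float,
                      order: int) -> np.ndarray:
    """Zero-phase Butterworth low-pass applied in the frequency domain.

    The forward+backward cascade of an order-n Butterworth has real,
    non-negative frequency response 1/(1+(f/fc)^(2n)); applying that
    response directly to the (mirror-padded) spectrum realises the
    bidirectional filter without the bilinear-transform frequency warping
    a sampled-time recursion would introduce.
    """
    n = x.size
    pad = min(n - 1, max(int(round(2 * fs)), 8))
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    f = np.fft.rfftfreq(xp.size, d=1.0 / fs)
    spectrum = np.fft.rfft(xp) * butterworth_zero_phase_gain(f, cutoff, order)
    y = np.fft.irfft(spectrum, xp.size)
    return y[pad:pad + n]


def lowpass_filter(traj: MarkerTrajectory, cutoff: float = 5.0,
                   order: int = 2, method: str = "spectral"
                   ) -> MarkerTrajectory:
    """Low-pass filter every coordinate of the hip and foot markers.

    Parameters
    ----------
    cutoff : float
        Cut-off frequency in Hz (default 5).
    order : int
        Butterworth order of the underlying one-way filter (default 2);
        the bidirectional application squares its magnitude response.
    method : {"spectral", "filtfilt"}
        "spectral" (default) applies the exact analytic forward+backward
        magnitude in the frequency domain; "filtfilt" uses the classic
        bilinear-design recursion via :func:`scipy.signal.filtfilt`.

    Output has the same length and timestamps as the input.
    """
    if traj.sampling_rate <= 2 * cutoff:
        raise ValueError("sampling_rate must exceed twice the cutoff")
    min_len = int(np.ceil(3 * traj.sampling_rate / cutoff))
    if traj.n_samples < min_len:
        raise ValueError(
            f"trajectory too short to filter: {traj.n_samples} samples, "
            f"minimum is {min_len} (3 warm-up lengths at fs/cutoff)"
        )
    if method == "filtfilt":
        from scipy.signal import butter, filtfilt
        b, a = butter(order, cutoff, fs=traj.sampling_rate)

        def run(col):
            return filtfilt(b, a, col)
    elif method == "spectral":
        def run(col):
            return _spectral_lowpass(col, traj.sampling_rate, cutoff, order)
    else:
        raise ValueError(f"unknown filter method {method!r}")

    filtered = {}
    for name, pos in traj.positions.items():
        out = np.empty_like(pos)
        for axis in range(3):
            out[:, axis] = run(pos[:, axis])
        filtered[name] = out
    return traj.copy_with(filtered, filtered=True)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def truncate_trial(traj: MarkerTrajectory, start_cut: float = 0.5,
                   end_margin: float = 2.0) -> MarkerTrajectory:
    """Restrict a trial to the constant-speed portion of the walk.

    Samples are retained while the hip marker's Y position lies in
    ``[Y_first + start_cut, Y_max - end_margin]``; with a 12 m capture
    space and the defaults this leaves 9.5 m for analysis. A trajectory
    already truncated (``meta['truncated']``) is returned unchanged, so
    the operation is idempotent.
    """
    if traj.meta.get("truncated"):
        return traj
    hip_y = traj.positions["hip"][:, 1]
    finite = hip_y[np.isfinite(hip_y)]
    if finite.size == 0:
        raise ValueError("hip marker entirely missing")
    y0, y_end = float(finite[0]), float(finite.max())
    span = y_end - y0
    if span <= start_cut + end_margin:
        raise ValueError(
            f"hip span {span:.2f} m does not exceed start_cut + end_margin "
            f"= {start_cut + end_margin:.2f} m"
        )
    with np.errstate(invalid="ignore"):
        mask = (hip_y >= y0 + start_cut) & (hip_y <= y_end - end_margin)
    idx = np.flatnonzero(mask)
    lo, hi = idx[0], idx[-1] + 1
    positions = {k: v[lo:hi] for k, v in traj.positions.items()}
    return MarkerTrajectory(
        time=traj.time[lo:hi],
        positions=positions,
        sampling_rate=traj.sampling_rate,
        meta={**traj.meta, "truncated": True,
              "capture_window_y": (y0 + start_cut, y_end - end_margin)},
    )


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

def _y_acceleration(y: np.ndarray, fs: float) -> np.ndarray:
    """Second-order central finite difference; endpoints copied."""
    a = np.empty_like(y)
    a[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) * fs * fs
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def find_stationary_periods(traj: MarkerTrajectory, foot: str,
                            window_s: float = 0.1,
                            threshold_m: float = 0.05,
                            min_stationary_s: float = 0.15,
                            use_3d: bool = True) -> List[StationaryPeriod]:
    """Find maximal runs where the foot marker moves less than
    ``threshold_m`` across a centred ``window_s`` window.

    Samples closer than half a window to either end cannot be certified
    and are treated as moving. Runs shorter than ``min_stationary_s`` are
    discarded as spurious swing-reversal artefacts.
    """
    pos = traj.positions[foot]
    n = traj.n_samples
    half = max(int(round(window_s * traj.sampling_rate / 2.0)), 1)
    stationary = np.zeros(n, dtype=bool)
    if n > 2 * half:
        delta = pos[2 * half:] - pos[:-2 * half]
        if use_3d:
            disp = np.linalg.norm(delta, axis=1)
        else:
            disp = np.abs(delta[:, 1])
        stationary[half:n - half] = disp < threshold_m
    min_len = max(int(round(min_stationary_s * traj.sampling_rate)), 1)
    periods: List[StationaryPeriod] = []
    boundaries = np.flatnonzero(np.diff(stationary.astype(np.int8)))
    starts = [0] if stationary[0] else []
    starts += list(boundaries[~stationary[boundaries]] + 1)
    ends = list(boundaries[stationary[boundaries]])
    if stationary[-1]:
        ends.append(n - 1)
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_len:
            mid = (s + e) // 2
            periods.append(StationaryPeriod(foot, s, e, pos[mid].copy()))
    return periods


def _extremum_time(accel: np.ndarray, time: np.ndarray, lo: int, hi: int,
                   fallback: int, kind: str) -> float:
    """Time of the acceleration extremum in sample range [lo, hi); the
    earliest index wins ties (np.argmin/argmax return the first)."""
    if hi <= lo:
        return float(time[fallback])
    window = accel[lo:hi]
    off = int(np.argmin(window) if kind == "min" else np.argmax(window))
    return float(time[lo + off])


def detect_steps(traj: MarkerTrajectory, window_s: float = 0.1,
                 threshold_m: float = 0.05,
                 min_stationary_s: float = 0.15,
                 use_3d: bool = True) -> List[StepEvent]:
    """Detect footfalls from stationary periods of the two foot markers.

    Each stationary period yields one event positioned at the marker's
    mid-period location. The landing time is the minimum of the signed Y
    acceleration between the previous period's end (or trajectory start)
    and the period start — the maximal deceleration of the approaching
    swing; the lifting time is the maximum Y acceleration between the
    period's end and the next period's start (or trajectory end).
    Events from both feet are merged and sorted by landing time.
    """
    events: List[StepEvent] = []
    for foot in ("left_foot", "right_foot"):
        periods = find_stationary_periods(
            traj, foot, window_s, threshold_m, min_stationary_s, use_3d
        )
        accel = _y_acceleration(traj.positions[foot][:, 1],
                                traj.sampling_rate)
        for i, period in enumerate(periods):
            prev_end = periods[i - 1].end_index if i > 0 else -1
            next_start = (periods[i + 1].start_index
                          if i + 1 < len(periods) else traj.n_samples)
            landing = _extremum_time(
                accel, traj.time, prev_end + 1, period.start_index + 1,
                period.start_index, "min",
            )
            lifting = _extremum_time(
                accel, traj.time, period.end_index, next_start,
                period.end_index, "max",
            )
            if lifting <= landing:
                lifting = float(traj.time[period.end_index])
            mid = (period.start_index + period.end_index) // 2
            events.append(StepEvent(
                foot=foot.replace("_foot", ""),
                position=period.mid_position,
                landing_time=landing,
                lifting_time=lifting,
                mid_index=mid,
            ))
    events.sort(key=lambda e: (e.landing_time, e.foot))
    return events


# ---------------------------------------------------------------------------
# gait parameters
# ---------------------------------------------------------------------------

def _positional_order(events: Sequence[StepEvent]) -> List[StepEvent]:
    """Events ordered by Y position — the physical footfall order of a
    straight forward walk.

    Landing times of stances truncated at the analysis-window edges are
    undefined (the reason the first/last step of each foot is removed),
    so position, not landing time, establishes step adjacency.
    """
    return sorted(events, key=lambda e: (e.position_y, e.landing_time))


def _trim_first_last_per_foot(events: Sequence[StepEvent]) -> List[int]:
    """Indices (into the position-ordered event list) that survive removal
    of each foot's first and last event."""
    kept: List[int] = []
    for foot in ("left", "right"):
        foot_idx = [i for i, e in enumerate(events) if e.foot == foot]
        kept.extend(foot_idx[1:-1])
    return sorted(kept)


def compute_gait_params(events: Sequence[StepEvent],
                        max_step_m: float = MAX_STEP_LENGTH_M) -> GaitParams:
    """Step lengths and stride times from time-ordered step events.

    The first and last event of each foot are removed (their lifting or
    landing references fall outside the truncated capture window). For
    every remaining event the step length is its Y position minus the Y
    position of the immediately preceding opposite-foot event; stride
    times are landing-to-landing intervals within each foot. Violations
    of the walking-consistency rules (overlong steps, same-foot repeats,
    too few steps) are flagged, not raised.
    """
    events = _positional_order(events)
    flags: set = set()
    kept_idx = _trim_first_last_per_foot(events)
    for foot in ("left", "right"):
        if sum(1 for i in kept_idx if events[i].foot == foot) < 3:
            flags.add(QC_TOO_FEW_STEPS)
    step_lengths: List[float] = []
    for i in kept_idx:
        event = events[i]
        if i == 0:
            continue
        prev = events[i - 1]
        if prev.foot == event.foot:
            flags.add(QC_SAME_FOOT_REPEAT)
            continue
        step = event.position_y - prev.position_y
        if step <= 0:
            continue  # positional tie; no forward advance to measure
        if step > max_step_m:
            flags.add(QC_OVERLONG_STEP)
        step_lengths.append(step)
    stride_times: List[float] = []
    for foot in ("left", "right"):
        landings = [events[i].landing_time for i in kept_idx
                    if events[i].foot == foot]
        stride_times.extend(np.diff(landings).tolist())
    return GaitParams(
        step_lengths=np.asarray(step_lengths, dtype=float),
        stride_times=np.asarray(stride_times, dtype=float),
        qc_flags=flags,
        n_steps_used=len(step_lengths),
    )


def compute_velocity(traj: MarkerTrajectory,
                     use_path_length: bool = False) -> float:
    """Walking speed: hip displacement divided by elapsed time over the
    truncated trial.

    By default the net Y displacement is used (participants walk straight
    down the laboratory); ``use_path_length=True`` substitutes the 3D path
    length of the hip marker.
    """
    elapsed = float(traj.time[-1] - traj.time[0])
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    hip = traj.positions["hip"]
    if use_path_length:
        distance = float(np.linalg.norm(np.diff(hip, axis=0), axis=1).sum())
    else:
        distance = float(hip[-1, 1] - hip[0, 1])
    return distance / elapsed


def qc_trial(traj: MarkerTrajectory, events: Sequence[StepEvent],
             max_step_m: float = MAX_STEP_LENGTH_M) -> set:
    """Walking-consistency checks; always returns a (possibly empty) flag set.

    Flags ``missing_markers`` for any NaN in a required marker,
    ``same_foot_repeat`` when successive events share a foot,
    ``overlong_step`` for any inter-foot advance above ``max_step_m``,
    and ``too_few_steps`` when a foot yields under three usable events.
    """
    flags: set = set()
    if traj.has_missing():
        flags.add(QC_MISSING_MARKERS)
    events = _positional_order(events)
    if not events:
        flags.add(QC_TOO_FEW_STEPS)
        return flags
    for prev, nxt in zip(events, events[1:]):
        if prev.foot == nxt.foot:
            flags.add(QC_SAME_FOOT_REPEAT)
        else:
            advance = nxt.position_y - prev.position_y
            if advance > max_step_m:
                flags.add(QC_OVERLONG_STEP)
    flags |= compute_gait_params(events, max_step_m).qc_flags
    return flags


def summarize_trial(traj: MarkerTrajectory, cutoff: float = 5.0,
                    order: int = 2, start_cut: float = 0.5,
                    end_margin: float = 2.0, window_s: float = 0.1,
                    threshold_m: float = 0.05,
                    min_stationary_s: float = 0.15,
                    use_3d: bool = True) -> TrialGait:
    """Run the full per-trial chain: filter, truncate, detect steps,
    parametrise, QC. Returns NaN summaries when markers are missing."""
    if traj.has_missing():
        return TrialGait(
            mean_velocity=np.nan, mean_step_length=np.nan,
            mean_stride_time=np.nan, step_length_sd=np.nan,
            stride_time_sd=np.nan, n_steps_used=0,
            qc_flags={QC_MISSING_MARKERS},
        )
    filtered = lowpass_filter(traj, cutoff=cutoff, order=order)
    truncated = truncate_trial(filtered, start_cut, end_margin)
    events = detect_steps(truncated, window_s, threshold_m,
                          min_stationary_s, use_3d)
    params = compute_gait_params(events)
    flags = qc_trial(truncated, events)
    velocity = compute_velocity(truncated)
    sl, st = params.step_lengths, params.stride_times
    return TrialGait(
        mean_velocity=velocity,
        mean_step_length=float(sl.mean()) if sl.size else np.nan,
        mean_stride_time=float(st.mean()) if st.size else np.nan,
        step_length_sd=float(sl.std(ddof=1)) if sl.size > 1 else 0.0,
        stride_time_sd=float(st.std(ddof=1)) if st.size > 1 else 0.0,
        n_steps_used=params.n_steps_used,
        qc_flags=flags,
    )


class GaitFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of :class:`MarkerTrajectory` objects to a
    per-trial gait table (pandas DataFrame).

    Stateless apart from its parameters; ``fit`` only validates them, so
    the extractor slots into sklearn pipelines ahead of the multilevel
    model.
    """

    def __init__(self, cutoff: float = 5.0, order: int = 2,
                 start_cut: float = 0.5, end_margin: float = 2.0,
                 window_s: float = 0.1, threshold_m: float = 0.05,
                 min_stationary_s: float = 0.15, use_3d: bool = True):
        self.cutoff = cutoff
        self.order = order
        self.start_cut = start_cut
        self.end_margin = end_margin
        self.window_s = window_s
        self.threshold_m = threshold_m
        self.min_stationary_s = min_stationary_s
        self.use_3d = use_3d

    def fit(self, X, y=None):
        if self.cutoff <= 0 or self.order < 1:
            raise ValueError("cutoff must be positive and order >= 1")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        import pandas as pd

        rows = []
        for traj in X:
            summary = summarize_trial(
                traj, cutoff=self.cutoff, order=self.order,
                start_cut=self.start_cut, end_margin=self.end_margin,
                window_s=self.window_s, threshold_m=self.threshold_m,
                min_stationary_s=self.min_stationary_s, use_3d=self.use_3d,
            )
            rows.append({
                "participant_id": traj.meta.get("participant_id"),
                "trial_id": traj.meta.get("trial_id"),
                "image_id": traj.meta.get("image_id"),
                "mean_velocity": summary.mean_velocity,
                "mean_step_length": summary.mean_step_length,
                "mean_stride_time": summary.mean_stride_time,
                "step_length_sd": summary.step_length_sd,
                "stride_time_sd": summary.stride_time_sd,
                "n_steps_used": summary.n_steps_used,
                "qc_flags": ";".join(sorted(summary.qc_flags)),
            })
        return pd.DataFrame(rows)
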