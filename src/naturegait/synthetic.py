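"""Synthetic study generator.

Emulates the walking-toward-images experiment end to end: a stimulus set
of 50 liking-matched nature/urban pairs plus grey control images, a
cross-classified standardized-velocity model (participant, image and
trial variance components with a fixed liking effect), and 100 Hz marker
trajectories with alternating stance/swing foot motion and 1 mm capture
noise — so that every downstream stage can be exercised, and round-trip
tested against known ground truth, without the deposited dataset.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .datatypes import (
    ImageMeta,
    MarkerTrajectory,
    ParticipantRecord,
    TrueTrialParams,
)

FAULT_OVERLONG_STEP = "overlong_step"
FAULT_SAME_FOOT_REPEAT = "same_foot_repeat"
FAULT_MISSING_MARKERS = "missing_markers"
_KNOWN_FAULTS = {FAULT_OVERLONG_STEP, FAULT_SAME_FOOT_REPEAT,
                 FAULT_MISSING_MARKERS}


def _rng(config: GeneratorConfig, rng: Optional[np.random.Generator],
         stream: int) -> np.random.Generator:
    """Per-operation generator: either the caller's, or one derived
    deterministically from (config.seed, stream)."""
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# stimulus metadata
# ---------------------------------------------------------------------------

def generate_image_metadata(config: GeneratorConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> List[ImageMeta]:
    """Generate the stimulus set: ``n_pairs`` liking-matched nature/urban
    pairs plus ``n_control`` blank control images.

    Pair liking scores are uniform on [liking_low, liking_high]; each pair
    member receives the shared score plus jitter bounded by the pairing
    tolerance. Per-image mean discomfort is built from a bivariate-normal
    construction with liking at correlation ``discomfort_liking_r`` and
    clipped to the 7-point scale; fractal dimensions are drawn from the
    per-environment normal summaries. Controls carry no liking, discomfort
    or fractal values.
    """
    if config.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _rng(config, rng, stream=1)
    n = config.n_pairs
    pair_liking = rng.uniform(config.liking_low, config.liking_high, size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * config.liking_jitter

    liking = np.clip(pair_liking[:, None] + jitter, 1.0, 7.0)
    z_pair = (pair_liking - pair_liking.mean()) / max(pair_liking.std(), 1e-12)
    r = config.discomfort_liking_r
    noise = rng.standard_normal((n, 2))
    images: List[ImageMeta] = []
    for env_col, env in enumerate(("nature", "urban")):
        if env == "nature":
            fd = rng.normal(config.fractal_nature_mean,
                            config.fractal_nature_sd, size=n)
        else:
            fd = rng.normal(config.fractal_urban_mean,
                            config.fractal_urban_sd, size=n)
        fd = np.clip(fd, 1.0, 2.0)
        disc = config.discomfort_mean + config.discomfort_sd * (
            r * z_pair + np.sqrt(max(1.0 - r * r, 0.0)) * noise[:, env_col]
        )
        disc = np.clip(disc, 1.0, 7.0)
        for k in range(n):
            images.append(ImageMeta(
                image_id=f"{env[0]}{k:03d}",
                environment=env,
                liking=float(liking[k, env_col]),
                pair_id=f"p{k:03d}",
                fractal_dim=float(fd[k]),
                discomfort_mean=float(disc[k]),
            ))
    for k in range(config.n_control):
        images.append(ImageMeta(image_id=f"c{k:03d}", environment="control"))
    return images


def images_to_frame(images: Iterable[ImageMeta]) -> pd.DataFrame:
    return pd.DataFrame([{
        "image_id": im.image_id,
        "environment": im.environment,
        "liking": im.liking,
        "pair_id": im.pair_id,
        "fractal_dim": im.fractal_dim,
        "discomfort_mean": im.discomfort_mean,
    } for im in images])


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

def generate_trial_table(config: GeneratorConfig,
                         images: Sequence[ImageMeta],
                         rng: Optional[np.random.Generator] = None,
                         with_truths: bool = True,
                         ) -> Tuple[pd.DataFrame, List[TrueTrialParams]]:
    """Simulate one trial per participant x image under the
    cross-classified standardized-velocity model.

    The latent outcome is ``z_v = b0 + b_LIK*z_lik + b_ENV*ENV + b_TK*TK
    + b_FR*z_fr + b_VD*z_vd + u_participant + v_image + eps`` with
    independent zero-mean Gaussian components at the configured variances;
    control trials instead receive a configurable speed offset (controls
    were walked faster) and are excluded from modelling downstream. The
    latent z is mapped affinely to physical velocity, from which each
    trial's step length and stride time are derived kinematically
    (v = 2 * step_length / stride_time holds by construction).

    Returns the trial table and the list of latent per-trial ground-truth
    parameters for round-trip testing.
    """
    images = list(images)
    if not images:
        raise ValueError("images must be non-empty")
    for name in ("var_participant", "var_image", "var_trial"):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = _rng(config, rng, stream=2)

    J = config.n_participants
    M = len(images)
    participants = np.array([f"P{i + 1:02d}" for i in range(J)])
    n_memory = int(round(config.memory_fraction * J))
    is_discomfort_task = np.arange(J) >= n_memory

    u = rng.normal(0.0, np.sqrt(config.var_participant), size=J)
    v = rng.normal(0.0, np.sqrt(config.var_image), size=M)
    step_ratio = np.clip(
        rng.normal(config.step_ratio_mean, config.step_ratio_sd, size=J),
        0.45, 0.65,
    )
    eps = rng.normal(0.0, np.sqrt(config.var_trial), size=(J, M))
    # presentation order: each participant sees the images once, shuffled
    trial_no = np.argsort(rng.random((J, M)), axis=1).argsort(axis=1) + 1

    env = np.array([im.environment for im in images])
    control = env == "control"
    liking = np.array([np.nan if im.liking is None else im.liking
                       for im in images])
    fractal = np.array([np.nan if im.fractal_dim is None
                        else im.fractal_dim for im in images])
    disc_mean = np.array([np.nan if im.discomfort_mean is None
                          else im.discomfort_mean for im in images])

    def z_over(values, mask):
        out = np.zeros_like(values)
        sd = values[mask].std()
        out[mask] = (values[mask] - values[mask].mean()) / max(sd, 1e-12)
        return out

    z_lik = z_over(liking, ~control)
    z_fr = z_over(fractal, ~control)

    latent = np.where(
        is_discomfort_task[:, None] & ~control[None, :],
        disc_mean[None, :] + rng.normal(
            0.0, config.discomfort_trial_sd, size=(J, M)),
        np.nan,
    )
    rating = np.clip(np.rint(latent), 1, 7)

    z = config.intercept + u[:, None] + v[None, :] + eps
    z += np.where(control[None, :], config.control_speed_offset, 0.0)
    z += config.beta_liking * np.where(control, 0.0, z_lik)[None, :]
    z += config.beta_fractal * np.where(control, 0.0, z_fr)[None, :]
    z += config.beta_environment * (env == "urban")[None, :].astype(float)
    z += (config.beta_task
          * (is_discomfort_task[:, None] & ~control[None, :]))
    if config.beta_discomfort != 0.0:
        rated = np.isfinite(latent)
        if rated.any():
            sd = latent[rated].std()
            z_vd = (latent - np.nanmean(latent)) / max(sd, 1e-12)
            z = np.where(rated, z + config.beta_discomfort * z_vd, z)

    table = pd.DataFrame({
        "participant_id": np.repeat(participants, M),
        "trial_id": trial_no.ravel(),
        "image_id": np.tile([im.image_id for im in images], J),
        "environment": np.tile(env, J),
        "task": np.repeat(
            np.where(is_discomfort_task, "discomfort", "memory"), M),
        "liking": np.tile(liking, J),
        "fractal_dim": np.tile(fractal, J),
        "discomfort_rating": rating.ravel(),
        "is_control": np.tile(control, J),
        "z_velocity": z.ravel(),
        "step_ratio": np.repeat(step_ratio, M),
    })
    table = table.sort_values(["participant_id", "trial_id"],
                              kind="mergesort").reset_index(drop=True)

    table["true_velocity"] = (config.velocity_mean
                              + config.velocity_sd * table["z_velocity"])
    if (table["true_velocity"] <= 0).any():
        raise ValueError("generated a non-positive velocity; reduce "
                         "velocity_sd or the variance components")
    table["true_step_length"] = np.minimum(
        table["step_ratio"] * table["true_velocity"], 1.25)
    table["true_stride_time"] = (2.0 * table["true_step_length"]
                                 / table["true_velocity"])
    analysed_span = config.walkway_length - 2.5  # after 0.5 m + 2 m cuts
    table["n_steps"] = np.maximum(
        np.rint(analysed_span / table["true_step_length"]).astype(int), 6)
    table = table.drop(columns="step_ratio")

    truths: List[TrueTrialParams] = []
    if not with_truths:
        return table, truths
    for row in table.itertuples():
        truths.append(TrueTrialParams(
            participant_id=row.participant_id,
            image_id=row.image_id,
            trial_id=row.trial_id,
            true_velocity=float(row.true_velocity),
            true_step_length=float(row.true_step_length),
            true_stride_time=float(row.true_stride_time),
            n_steps=int(row.n_steps),
        ))
    return table, truths


def generate_participants(config: GeneratorConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> List[ParticipantRecord]:
    """Participant-level records (task assignment, data completeness,
    memory accuracy) for the exclusion stage. The default cohort is fully
    compliant; tests construct failing records explicitly."""
    rng = _rng(config, rng, stream=3)
    records = []
    n_memory = int(round(config.memory_fraction * config.n_participants))
    for i in range(config.n_participants):
        task = "memory" if i < n_memory else "discomfort"
        acc = float(rng.uniform(0.65, 0.95)) if task == "memory" else None
        records.append(ParticipantRecord(
            participant_id=f"P{i + 1:02d}",
            task=task,
            prop_valid_data=1.0,
            memory_accuracy=acc,
        ))
    return records


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

def _min_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk displacement profile on [0, 1]: a single acceleration
    maximum and a single minimum per swing, so landing/lifting times are
    unambiguous on clean data."""
    return 10.0 * s ** 3 - 15.0 * s ** 4 + 6.0 * s ** 5


def _foot_track(t: np.ndarray, placements: np.ndarray,
                landings: np.ndarray, swing_time: float,
                lift_height: float) -> np.ndarray:
    """Piecewise stance/swing track of one foot marker.

    The foot rests at ``placements[k]`` from ``landings[k]`` until
    ``landings[k+1] - swing_time``, then swings to the next placement
    along a minimum-jerk Y profile with a sinusoidal vertical lift.
    """
    k = np.clip(np.searchsorted(landings, t, side="right") - 1,
                0, len(placements) - 1)
    y = placements[k]
    z = np.zeros_like(t)
    has_next = k < len(placements) - 1
    next_landing = landings[np.minimum(k + 1, len(landings) - 1)]
    swing_start = next_landing - swing_time
    in_swing = has_next & (t > swing_start)
    s = np.clip((t[in_swing] - swing_start[in_swing]) / swing_time, 0.0, 1.0)
    travel = placements[np.minimum(k + 1, len(placements) - 1)] - placements[k]
    y[in_swing] = (placements[k][in_swing]
                   + travel[in_swing] * _min_jerk(s))
    z[in_swing] = lift_height * np.sin(np.pi * s)
    return y, z + 0.03  # marker sits ~3 cm above ground


def synthesize_trial_trajectory(params: TrueTrialParams,
                                config: GeneratorConfig,
                                rng: Optional[np.random.Generator] = None,
                                noise_sd: Optional[float] = None,
                                hip_oscillation: Optional[float] = None,
                                faults: Sequence[str] = (),
                                ) -> MarkerTrajectory:
    """Synthesize hip and foot marker trajectories for one walking trial.

    The hip advances along Y at the trial's velocity with a small smooth
    oscillation at step frequency; the feet alternate stationary stance
    phases (spaced two step lengths apart within a foot, one step length
    between feet) and minimum-jerk swing phases. Isotropic Gaussian noise
    (default 1 mm, the capture calibration accuracy) is added to every
    sample. The returned trajectory spans the full capture space and
    carries the generating stance schedule in ``meta['truth']``.

    ``faults`` may inject walking inconsistencies for QC testing:
    ``overlong_step`` (the walk jumps forward mid-trial so exactly one
    step measures 1.35 m), ``same_foot_repeat`` (one right stance
    skipped) or
    ``missing_markers`` (0.3 s of NaNs on the right foot). A step length
    of 1.3 m or more is refused unless a fault is explicitly requested.
    """
    unknown = set(faults) - _KNOWN_FAULTS
    if unknown:
        raise ValueError(f"unknown faults: {sorted(unknown)}")
    if params.true_step_length >= 1.3 and not faults:
        raise ValueError(
            "step length >= 1.3 m violates the walking-consistency "
            "assumption; pass an explicit fault to generate it anyway"
        )
    rng = _rng(config, rng, stream=4)
    noise = config.noise_sd if noise_sd is None else noise_sd
    sway = (config.hip_sway_amplitude if hip_oscillation is None
            else hip_oscillation)

    v = params.true_velocity
    L = params.true_step_length
    T = params.true_stride_time
    fs = config.sampling_rate
    swing_time = config.swing_fraction * T
    duration = config.walkway_length / v
    t = np.arange(int(round(duration * fs)) + 1) / fs

    # stance placements: left at even multiples of L, right at odd;
    # a placement at Y=p lands at t=p/v (one stride period apart per foot)
    placements = {}
    landings = {}
    for foot, y0 in (("left_foot", 0.0), ("right_foot", L)):
        first = y0 - 2 * L * np.ceil((y0 + 2 * L) / (2 * L))
        p = np.arange(first, config.walkway_length + 2 * L, 2 * L)
        placements[foot] = p
        landings[foot] = p / v

    def _mid_placement(foot):
        p = placements[foot]
        inside = np.flatnonzero(
            (p > 0.3 * config.walkway_length)
            & (p < 0.6 * config.walkway_length))
        return inside[0]

    if FAULT_OVERLONG_STEP in faults:
        # shift the rest of the walk forward by delta without moving the
        # landing schedule: exactly one step then measures 1.35 m while
        # every other step keeps its normal length and order
        m = _mid_placement("left_foot")
        p_m = placements["left_foot"][m]
        delta = 1.35 - L
        placements["left_foot"][m:] += delta
        right = placements["right_foot"]
        right[right > p_m - L / 2] += delta
    if FAULT_SAME_FOOT_REPEAT in faults:
        # the right foot skips one swing and rests for a full extra stride
        drop = _mid_placement("right_foot")
        placements["right_foot"] = np.delete(placements["right_foot"], drop)
        landings["right_foot"] = np.delete(landings["right_foot"], drop)

    positions = {}
    hip_y = v * t + sway * np.sin(2.0 * np.pi * (2.0 / T) * t)
    hip = np.column_stack([
        np.zeros_like(t), hip_y, np.full_like(t, 1.0)
    ])
    positions["hip"] = hip

    truth = {"velocity": v, "step_length": L, "stride_time": T,
             "stances": []}
    for foot, x_off in (("left_foot", -0.1), ("right_foot", 0.1)):
        p = placements[foot]
        lands = landings[foot]
        y, z = _foot_track(t, p, lands, swing_time,
                           config.foot_lift_height)
        positions[foot] = np.column_stack([np.full_like(t, x_off), y, z])
        for idx, (pk, lk) in enumerate(zip(p, lands)):
            if idx + 1 < len(lands):
                lift = lands[idx + 1] - swing_time
            else:
                lift = lk + (T - swing_time)
            if lift < 0 or lk > duration:
                continue  # stance lies entirely outside the capture
            truth["stances"].append({
                "foot": foot.replace("_foot", ""),
                "position_y": float(pk),
                "landing_time": float(lk),
                "lifting_time": float(lift),
            })

    if noise > 0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(
                0.0, noise, size=positions[name].shape)

    if FAULT_MISSING_MARKERS in faults:
        mid = len(t) // 2
        gap = int(round(0.3 * fs))
        positions["right_foot"][mid:mid + gap] = np.nan

    return MarkerTrajectory(
        time=t,
        positions=positions,
        sampling_rate=fs,
        meta={
            "participant_id": params.participant_id,
            "trial_id": params.trial_id,
            "image_id": params.image_id,
            "truth": truth,
            "faults": list(faults),
        },
    )


# ---------------------------------------------------------------------------
# fractal fixtures
# ---------------------------------------------------------------------------

def generate_fractal_image(kind: str, depth: int,
                           rng: Optional[np.random.Generator] = None
                           ) -> np.ndarray:
    """Deterministic binary rasters with known box-counting dimension.

    kinds: ``filled_square`` and ``random_noise`` (dimension 2), ``line``
    (dimension 1), ``sierpinski_triangle`` (log 3 / log 2, side 2**depth)
    and ``sierpinski_carpet`` (log 8 / log 3, side 3**depth).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if kind == "filled_square":
        side = 2 ** depth
        return np.ones((side, side), dtype=bool)
    if kind == "line":
        side = 2 ** depth
        img = np.zeros((side, side), dtype=bool)
        img[side // 2, :] = True
        return img
    if kind == "sierpinski_triangle":
        side = 2 ** depth
        i, j = np.indices((side, side))
        return (i & j) == 0
    if kind == "sierpinski_carpet":
        side = 3 ** depth
        i, j = np.indices((side, side))
        keep = np.ones((side, side), dtype=bool)
        for _ in range(depth):
            keep &= ~((i % 3 == 1) & (j % 3 == 1))
            i = i // 3
            j = j // 3
        return keep
    if kind == "random_noise":
        if rng is None:
            rng = np.random.default_rng(0)
        side = 2 ** depth
        return rng.random((side, side)) > 0.5
    raise ValueError(f"unknown fractal kind {kind!r}")
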