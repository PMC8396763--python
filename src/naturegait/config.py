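"""Configuration dataclasses for the generator, the MCMC fit, and full
pipeline runs, with plain-text (YAML) round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic-data generator.

    Defaults reproduce the study conditions: 44 participants x 105 trials
    (50 liking-matched nature/urban pairs + 5 grey control images), liking
    scores uniform on [2.82, 5.61], a standardized-velocity model with a
    liking effect of 0.016 and variance components 0.904 (participant),
    0.002 (image), 0.157 (trial), discomfort ratings correlated with
    liking at r = -0.497, 100 Hz capture over a 12 m walkway with 1 mm
    marker noise.
    """

    # design
    n_participants: int = 44
    n_pairs: int = 50
    n_control: int = 5
    memory_fraction: float = 0.5
    sampling_rate: float = 100.0
    walkway_length: float = 12.0
    seed: int = 0

    # standardized-velocity model
    intercept: float = 0.0
    beta_liking: float = 0.016
    beta_environment: float = 0.0
    beta_task: float = 0.0
    beta_fractal: float = 0.0
    beta_discomfort: float = 0.0
    var_participant: float = 0.904
    var_image: float = 0.002
    var_trial: float = 0.157
    control_speed_offset: float = 0.05

    # stimulus metadata
    liking_low: float = 2.82
    liking_high: float = 5.61
    liking_jitter: float = 0.02
    pairing_tolerance: float = 0.1
    discomfort_liking_r: float = -0.497
    discomfort_mean: float = 2.85
    discomfort_sd: float = 0.84
    discomfort_trial_sd: float = 0.5
    fractal_nature_mean: float = 1.65
    fractal_nature_sd: float = 0.13
    fractal_urban_mean: float = 1.59
    fractal_urban_sd: float = 0.14

    # physical-velocity mapping and trajectory synthesis
    velocity_mean: float = 1.25
    velocity_sd: float = 0.12
    step_ratio_mean: float = 0.56   # step length per unit velocity (s/2)
    step_ratio_sd: float = 0.02
    noise_sd: float = 0.001         # 1 mm marker accuracy
    hip_sway_amplitude: float = 0.005
    swing_fraction: float = 0.38
    foot_lift_height: float = 0.08

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("var_participant", "var_image", "var_trial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sampling_rate <= 10.0:
            # must stay comfortably above twice the 5 Hz filter cutoff
            raise ValueError("sampling_rate must exceed 10 Hz")
        if not (0.0 <= self.memory_fraction <= 1.0):
            raise ValueError("memory_fraction must lie in [0, 1]")
        if self.liking_jitter > self.pairing_tolerance:
            raise ValueError("liking_jitter may not exceed pairing_tolerance")


@dataclass
class McmcConfig:
    """Gibbs-sampler settings: 500 burn-in iterations and a 10,000-draw
    chain by default, with diffuse Normal/inverse-Gamma priors."""

    burn_in: int = 500
    chain_length: int = 10000
    seed: int = 0
    prior_beta_variance: float = 1e6
    prior_var_shape: float = 0.001
    prior_var_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.chain_length <= 0:
            raise ValueError("chain_length must be positive")


@dataclass
class RunConfig:
    """End-to-end pipeline run description."""

    out_dir: str = "naturegait_out"
    seed: int = 0
    simulate: bool = True
    trajectory_dir: Optional[str] = None
    image_dir: Optional[str] = None
    metadata_csv: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    candidates: Sequence[str] = ("ENV", "LIK", "TK", "FR")
    filter_cutoff: float = 5.0
    filter_order: int = 2
    stationary_window_s: float = 0.1
    stationary_threshold_m: float = 0.05
    min_stationary_s: float = 0.15
    start_cut_m: float = 0.5
    end_margin_m: float = 2.0
    synthesize_trajectories: bool = True
    fractal_fixture_depth: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen = GeneratorConfig(**raw.pop("generator", {}))
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=gen, mcmc=mcmc, **raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )
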