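import warnings

import numpy as np
import pandas as pd
import pytest

from naturegait import GeneratorConfig, TrueTrialParams

# the short-chain warnings are expected at test-scale chain lengths
warnings.filterwarnings(
    "ignore", message="low effective sample size", category=RuntimeWarning
)


@pytest.fixture
def gen_config():
    return GeneratorConfig(seed=42)


@pytest.fixture
def reference_trial():
    """A typical adult self-paced walking trial: 1.25 m/s, 0.70 m steps,
    1.12 s strides."""
    return TrueTrialParams(
        participant_id="P01", image_id="n000", trial_id=1,
        true_velocity=1.25, true_step_length=0.70, true_stride_time=1.12,
        n_steps=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def group_orthogonal(x, pid, iid, rounds=6):
    """Remove participant- and image-group means by alternating
    projections, so partial pooling of the random intercepts cannot move
    the fixed-effect estimand away from plain OLS."""
    x = np.asarray(x, dtype=float).copy()
    df = pd.DataFrame({"x": x, "p": pid, "i": iid})
    for _ in range(rounds):
        df["x"] -= df.groupby("p")["x"].transform("mean")
        df["x"] -= df.groupby("i")["x"].transform("mean")
    return df["x"].to_numpy()


def flat_regression_table(seed=0, n=800, beta=0.5, sigma=0.1):
    """No participant/image variance: plain regression data with
    group-orthogonal covariates, so the posterior for beta must coincide
    with OLS."""
    rng = np.random.default_rng(seed)
    pid = [f"P{i % 20:02d}" for i in range(n)]
    iid = [f"i{i % 40:03d}" for i in range(n)]
    x = group_orthogonal(rng.standard_normal(n), pid, iid)
    y = beta * x + rng.normal(0.0, sigma, n)
    return pd.DataFrame({
        "participant_id": pid,
        "image_id": iid,
        "LIK": x,
        "z_velocity": y,
    })
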