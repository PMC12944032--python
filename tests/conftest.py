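import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drowsecg.pipeline import fixture_config, run_pipeline
from drowsecg.simulate import SimConfig, generate_session

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_session():
    """5 min artifact-free session with a mid-session drowsiness onset."""
    cfg = SimConfig(duration_s=300.0, drowsiness_onset_s=150.0, seed=3, artifact_rate=0.0)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """Full pipeline run on the small test cohort (3 participants x 2 x 10 min)."""
    out = tmp_path_factory.mktemp("run") / "r1"
    cfg = fixture_config(seed=3)
    run_pipeline(cfg, out)
    return cfg, out


def rng(seed=0):
    return np.random.default_rng(seed)
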