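import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmscreen.landmark_io import LandmarkEvent, LandmarkLabel, LandmarkStream
from lmscreen.synthetic_data import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_stream(rows, sample_id="s"):
    """Build a stream from (time, label, strength) triples."""
    return LandmarkStream.from_events(
        sample_id,
        [
            LandmarkEvent(time=t, label=LandmarkLabel.parse(lbl), strength=st)
            for t, lbl, st in rows
        ],
    )


def random_stream(rng, n_events, labels=("+g", "-g", "+b")):
    """A random (not grammar-valid) stream for brute-force oracles."""
    times = np.sort(rng.uniform(0, 2.0, size=n_events))
    rows = [
        (float(t), labels[int(rng.integers(len(labels)))], float(rng.uniform(0, 100)))
        for t in times
    ]
    return make_stream(rows)


@pytest.fixture(scope="session")
def null_cohort():
    """39/12 cohort with identical class-conditional distributions."""
    cfg = GeneratorConfig(seed=11, separation=0.0)
    return generate_dataset(39, 12, cfg)


@pytest.fixture(scope="session")
def separated_cohort():
    """39/12 cohort at the strongly separated study condition."""
    from lmscreen.synthetic_data import HIGH_SEPARATION

    cfg = GeneratorConfig(seed=11, separation=HIGH_SEPARATION)
    return generate_dataset(39, 12, cfg)
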