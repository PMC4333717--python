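import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imseg import CpGTrack, DetectionParams
from imseg.simulate import default_benchmark_config, simulate_counts, simulate_genome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # tracks passed into hypothesis tests are treated as read-only
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture
def small_track() -> CpGTrack:
    """Six CpGs on two chromosomes with mixed signal."""
    return CpGTrack.from_arrays(
        "s1",
        ["chr1", "chr1", "chr1", "chr1", "chr2", "chr2"],
        [100, 150, 300, 420, 50, 90],
        [5.0, 4.0, 0.0, 3.0, 8.0, 0.0],
        [3.0, 5.0, 6.0, 2.0, 0.0, 0.0],
    )


@pytest.fixture
def raw_scale_params():
    """Detection params whose normalization targets match a raw toy track.

    Keeps score_deltas quiet on tracks that are generated directly on the
    read-density scale.
    """

    def _make(track: CpGTrack) -> DetectionParams:
        return DetectionParams(
            medip_target=float(track.medip.sum()) or 1.0,
            mre_target=float(track.mre.sum()) or 1.0,
        )

    return _make


@pytest.fixture(scope="session")
def benchmark_sim():
    """Planted benchmark genome (seed 1): truth, track and matching params."""
    config = default_benchmark_config(seed=1)
    truth = simulate_genome(config)
    track = simulate_counts(truth, config)
    params = DetectionParams(
        medip_target=float(track.medip.sum()), mre_target=float(track.mre.sum())
    )
    return config, truth, track, params
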