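import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from lagopop.demography import AgeGroupSpec, NestConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_nest(initial_counts=(5, 5, 5, 5), thresholds=(0, 20, 75, 105),
              mortality=(0.77, 0.38, 0.11, 0.11),
              reproduction=(0.0, 0.0, 0.0, 4.0),
              season=("december", "january", "february",
                      "march", "april", "may"),
              sex_ratio_male=0.5, nest_id="test_nest"):
    groups = tuple(
        AgeGroupSpec(i, f"g{i}", thresholds[i], mortality[i], reproduction[i])
        for i in range(len(thresholds)))
    return NestConfig(
        nest_id=nest_id, location=(0.0, 0.0), species="rabbit",
        age_groups=groups, initial_counts=initial_counts,
        sex_ratio_male=sex_ratio_male,
        reproductive_season=frozenset(season) if any(
            r > 0 for r in reproduction) else frozenset(),
        feeding_radius=250.0)


@pytest.fixture
def nest_factory():
    return make_nest
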