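import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idhtrial.borrowing import GroupData
from idhtrial.simulate import moment_match_lognormal

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# printed per-arm summaries: label -> (evaluable n, arithmetic mean, s.d.), µg/g
STUDY_ARMS = {
    "VOR50": (11, 8.9, 4.1),
    "VOR10": (7, 67.5, 65.4),
    "IVO500": (10, 20.9, 30.7),
    "IVO250": (7, 16.8, 18.1),
    "CTRL_INTERNAL": (5, 154.9, 146.9),
    "CTRL_EXTERNAL": (61, 276.8, 231.4),
}


def make_study_groups(seed: int, arms: dict | None = None) -> list[GroupData]:
    """Moment-matched log10-scale samples for each study arm."""
    rng = np.random.default_rng(seed)
    groups = []
    for label, (n, mean, sd) in (arms or STUDY_ARMS).items():
        params = moment_match_lognormal(mean, sd)
        groups.append(
            GroupData(label, params.location + params.scale * rng.standard_normal(n))
        )
    return groups


@pytest.fixture
def study_groups() -> list[GroupData]:
    return make_study_groups(seed=2024)
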