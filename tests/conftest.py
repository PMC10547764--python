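import warnings

import pytest
from hypothesis import HealthCheck, settings

from kascape import LibraryDesign

settings.register_profile(
    "deterministic", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")

LEFT, RIGHT = "TTGGA", "CCAAT"


def small_design(n: int) -> LibraryDesign:
    """A design with n outside the assayed 4..7 range, warning silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LibraryDesign(LEFT, RIGHT, n)


@pytest.fixture
def design4() -> LibraryDesign:
    return LibraryDesign(LEFT, RIGHT, 4)


@pytest.fixture
def design5() -> LibraryDesign:
    return LibraryDesign(LEFT, RIGHT, 5)
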