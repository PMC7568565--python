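import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wolbmag.io import GenePresenceMatrix

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> GenePresenceMatrix:
    """Four genomes in two supergroups, two core-like and two patchy families."""
    values = pd.DataFrame(
        [[1, 1, 1, 0], [1, 1, 0, 0], [1, 1, 0, 1], [1, 1, 1, 1]],
        index=["A.g0", "A.g1", "B.g0", "B.g1"],
        columns=["fam1", "fam2", "fam3", "fam4"],
    )
    return GenePresenceMatrix(
        values,
        {"A.g0": "A", "A.g1": "A", "B.g0": "B", "B.g1": "B"},
        {"A.g0": "wMel", "A.g1": "wMel", "B.g0": "wPip", "B.g1": "wPip"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
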