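import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_data():
    """The frozen recovery scenario: matrix, labels, ground truth."""
    from scmrmr.simulate import default_recovery_scenario, generate

    return generate(default_recovery_scenario())


@pytest.fixture(scope="session")
def recovery_ranking(recovery_data):
    """mRMR ranking of the log1p-transformed recovery matrix (top 40)."""
    from scmrmr.mrmr import mrmr_rank

    matrix, labels, _ = recovery_data
    return mrmr_rank(matrix.log1p(), labels, n_select=40)


@pytest.fixture(scope="session")
def recovery_curve(recovery_data, recovery_ranking):
    """LOOCV IFS curve over the top 40 ranked genes (the expensive pass)."""
    from scmrmr.ifs import ifs_curve

    matrix, labels, _ = recovery_data
    return ifs_curve(matrix.log1p(), labels, recovery_ranking, K=40)


@pytest.fixture
def rng():
    return np.random.default_rng(20200305)
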