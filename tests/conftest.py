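"""Shared fixtures: expensive seeded experiments are computed once per run."""

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from anpca.experiments import convergence_experiment, make_session  # noqa: E402


@pytest.fixture(scope="session")
def session0():
    """One reference synthetic session (seed 0), band-passed, 7000-sample block."""
    return make_session(0)


@pytest.fixture(scope="session")
def convergence_runs():
    """Six-seed replayed-block convergence study with default parameters."""
    return convergence_experiment(seeds=range(6), epochs=10)


@pytest.fixture(scope="session")
def comparison_table():
    """ANPCA vs SOBI vs plain NPCA on six identical seeded sessions."""
    from anpca.baselines import compare

    return compare(seeds=tuple(range(6)), epochs=1)
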