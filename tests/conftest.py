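import pytest

from gazeskill import metrics, sim


@pytest.fixture(scope="session")
def small_cohort():
    """Six short mixed-archetype sessions, shared across test modules."""
    cfg = sim.SimConfig.fast(n_sessions=6, seed=11)
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_metrics(small_cohort):
    sessions, truth = small_cohort
    table = metrics.extract_cohort_metrics(sessions)
    return table, truth
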