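import pytest

from switchbox import CellSpec, CohortSpec, Condition, TaskConfig, generate_cohort


@pytest.fixture(scope="session")
def sparse():
    return TaskConfig(condition=Condition.SPARSE)


@pytest.fixture(scope="session")
def dense():
    return TaskConfig(condition=Condition.DENSE)


@pytest.fixture(scope="session")
def default_cohort(sparse):
    """The study-sized default synthetic cohort, fixed seed."""
    return generate_cohort(CohortSpec(seed=11), sparse)


def make_cohort(condition, n, mixture, noise=0.0, seed=5, age="kid"):
    """One-cell cohort helper used across test modules."""
    cells = (CellSpec(age, Condition(condition), n, mixture, noise),)
    cfg = TaskConfig(condition=Condition(condition))
    return generate_cohort(CohortSpec(cells=cells, seed=seed), cfg)
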