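import pytest

import tortuosity as tt


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced six-group cohort (3 tracks per group) for pipeline tests."""
    sizes = tuple((key, 3) for key in dict(tt.CohortConfig().group_sizes))
    cfg = tt.CohortConfig(group_sizes=sizes, seed=11)
    records, truth = tt.gen_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def full_cohort():
    """Default-size cohort (141 tracks) with ground truth."""
    cfg = tt.CohortConfig(seed=5)
    records, truth = tt.gen_cohort(cfg)
    return cfg, records, truth


@pytest.fixture
def circle_track():
    return tt.gen_circle(radius=4.7746, length=12.80, ds=0.04)


@pytest.fixture
def straight_track():
    return tt.gen_line(length=12.80, ds=0.04)
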