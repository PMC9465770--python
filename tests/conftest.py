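import numpy as np
import pytest

from vo2row import Cohort, CohortSpec, RowerRecord, generate_cohort


def make_record(i: int, sex: str = "male", **overrides) -> RowerRecord:
    base = dict(
        athlete_id=f"{sex}-{i:03d}",
        sex=sex,
        age=15.0 + 0.1 * i,
        body_mass=70.0 + i,
        height=178.0,
        fat_pct=16.0,
        lean_body_mass=55.0 + 0.5 * i,
        distance_4min=1150.0 + 2 * i,
        stroke_rate=32.0,
        mean_power=320.0,
        hr_max=188.0,
        vo2max_measured=3900.0 + 10 * i,
    )
    base.update(overrides)
    return RowerRecord(**base)


def make_cohort(n: int = 10, sex: str = "male", **overrides) -> Cohort:
    return Cohort(tuple(make_record(i, sex=sex, **overrides) for i in range(n)))


@pytest.fixture
def small_cohort() -> Cohort:
    return make_cohort(10)


@pytest.fixture(scope="session")
def boys_cohort_106() -> Cohort:
    """Development-sized synthetic boys cohort with calibrated noise."""
    return generate_cohort(CohortSpec(sex="male", n=106, seed=20_106))


@pytest.fixture(scope="session")
def girls_cohort_83() -> Cohort:
    return generate_cohort(CohortSpec(sex="female", n=83, seed=20_083))


@pytest.fixture(scope="session")
def boys_pool_119() -> Cohort:
    return generate_cohort(CohortSpec(sex="male", n=119, seed=20_119))
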