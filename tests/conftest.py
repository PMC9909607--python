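import pytest

from mstkit import (
    build_schedule,
    design_variant,
    make_synthetic_bank,
    young_adult_cohort,
)


@pytest.fixture(scope="session")
def bank():
    return make_synthetic_bank(seed=1)


@pytest.fixture(scope="session")
def full_st(bank):
    return build_schedule(design_variant("full-st", seed=11), bank.pairs_for_set(1))


@pytest.fixture(scope="session")
def full_cont(bank):
    return build_schedule(design_variant("full-cont", seed=12), bank.pairs_for_set(2))


@pytest.fixture(scope="session")
def reduced_st(bank):
    return build_schedule(design_variant("reduced-st", seed=13), bank.pairs_for_set(3))


@pytest.fixture(scope="session")
def reduced_cont(bank):
    return build_schedule(design_variant("reduced-cont", seed=14), bank.pairs_for_set(4))


@pytest.fixture(scope="session")
def cohort():
    return young_adult_cohort(seed=5)
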