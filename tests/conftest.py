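import pytest

from effortdisc import (
    DiscountModelSpec,
    GroundTruth,
    SharingClass,
    generate_schedule,
    simulate_choices,
    simulate_training,
)


@pytest.fixture(scope="session")
def winning_spec():
    """Separate-k/separate-beta, hyperbolic cognitive + parabolic physical."""
    return DiscountModelSpec(
        SharingClass.SEPARATE_K_SEPARATE_BETA, "hyperbolic", "parabolic"
    )


@pytest.fixture(scope="session")
def shared_hyperbolic():
    return DiscountModelSpec(SharingClass.SHARED_K_SHARED_BETA, "hyperbolic", "hyperbolic")


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(75, seed=101)


@pytest.fixture(scope="session")
def sim_truth(winning_spec):
    return GroundTruth(
        subject="s0",
        model=winning_spec,
        k_cog=1.2,
        k_phys=3.0,
        beta_cog=8.0,
        beta_phys=4.0,
    )


@pytest.fixture(scope="session")
def sim_choices(schedule, sim_truth):
    """One simulated subject's 150 choice trials."""
    return simulate_choices(schedule, sim_truth, seed=202)


@pytest.fixture(scope="session")
def sim_training(sim_truth):
    return simulate_training(sim_truth, seed=303)
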