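import pytest

from psdesign import BetaPrior, TrialDesign, flat_prior


@pytest.fixture
def table1_design_27() -> TrialDesign:
    """First-look monitoring setup: theta0=0.3, alpha=0.10, flat prior, N_max=27."""
    return TrialDesign(
        theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
        n_max=27, looks=(10, 27), prior=flat_prior(),
    )


@pytest.fixture
def two_stage_005() -> TrialDesign:
    """Two-stage design 25/50, theta0=0.3 vs 0.5, alpha=0.05, flat prior."""
    return TrialDesign(
        theta0=0.3, theta1=0.5, alpha=0.05, power_target=0.8, gamma=0.5,
        n_max=50, looks=(25, 50), prior=flat_prior(),
    )


@pytest.fixture
def informative_prior() -> BetaPrior:
    """Moment-matched prior for anticipated rate 0.5 with 10% coefficient of variation."""
    return BetaPrior(49.5, 49.5)
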