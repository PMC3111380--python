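import pytest

import injury_aaf as ia


@pytest.fixture(scope="session")
def curves():
    """Risk curves calibrated to the published per-occasion anchor grid."""
    return ia.published_anchor_curves()


@pytest.fixture(scope="session")
def metabolism():
    return ia.MetabolismModel()


@pytest.fixture()
def summary():
    """A generic stratum: 30% never/former drinkers, 20% binge drinkers."""
    return ia.ConsumptionSummary(
        age_group="15-29",
        sex="M",
        p_abstainer_former=0.3,
        p_current=0.7,
        raw_mean=12.0,
        raw_mean_se=1.0,
        binge_prevalence=0.2,
        binge_occasions_per_year=52.0,
    )


@pytest.fixture(scope="session")
def point_truth():
    return ia.default_truth(intake_model="point")


@pytest.fixture(scope="session")
def gamma_truth():
    return ia.default_truth(intake_model="gamma")
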