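import pytest

from popbenefit import (
    BenefitWeights,
    BinaryMarkerSpec,
    PopulationContext,
    calibrate_from_or,
    solve_two_by_two,
)


@pytest.fixture
def table_or20():
    """Population table for OR=20, marker prevalence 10%, disease prevalence 1%."""
    return solve_two_by_two(BinaryMarkerSpec(20.0, 0.10), PopulationContext(0.01))


@pytest.fixture
def weights_ea():
    """Esophageal-adenocarcinoma loss weights: f1=1, f2=0.03."""
    return BenefitWeights(1.0, 0.03)


@pytest.fixture
def pair_or50():
    """Binormal marker pair calibrated to a per-unit odds ratio of 50."""
    return calibrate_from_or(50.0)
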