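import numpy as np
import pytest

from virtualckd.model_core import CardiorenalModel, Interventions
from virtualckd.params import ParameterSet, ParameterSpace
from virtualckd.pharmacology import TherapySpec
from virtualckd.protocols import ProtocolSpec, induce_ckd


@pytest.fixture(scope="session")
def nominal_model() -> CardiorenalModel:
    return CardiorenalModel(ParameterSet.nominal(1))


@pytest.fixture(scope="session")
def nominal_steady(nominal_model):
    return nominal_model.steady_state()


@pytest.fixture(scope="session")
def ckd_state(nominal_model, nominal_steady):
    """Nominal patient after the 70% induction ramp (converged baseline)."""
    spec = ProtocolSpec.from_config(
        TherapySpec.from_name("control"), cadence_days=30
    )
    return induce_ckd(nominal_model, nominal_steady, np.array([0.70]), spec)


@pytest.fixture(scope="session")
def space() -> ParameterSpace:
    return ParameterSpace.from_config()


@pytest.fixture
def iv() -> Interventions:
    return Interventions()
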