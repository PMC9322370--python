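import numpy as np
import pytest

from xspeciespk import (
    DoseEvent,
    PKParameters,
    StructuralModelSpec,
    build_model,
)


@pytest.fixture
def iv_1cmt():
    spec = StructuralModelSpec(1, "iv_bolus")
    return spec, build_model(spec), PKParameters(CL=0.5, V1=5.0)


@pytest.fixture
def oral_1cmt():
    spec = StructuralModelSpec(1, "first_order")
    return spec, build_model(spec), PKParameters(CL=0.5, V1=5.0, ka1=1.2, F=0.8)


@pytest.fixture
def iv_2cmt():
    spec = StructuralModelSpec(2, "iv_bolus")
    return spec, build_model(spec), PKParameters(CL=1.0, V1=5.0, V2=10.0, Q=2.0)


@pytest.fixture
def grid_120h():
    return np.linspace(0.0, 120.0, 1201)


def oral_dose(amount=1.0, t=0.0, route="oral_solution"):
    return DoseEvent("s1", t, amount, route=route)


def iv_dose(amount=1.0, t=0.0):
    return DoseEvent("s1", t, amount, route="iv_bolus")
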