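import datetime

import numpy as np
import pytest

from csmig import ChainModel, FractionVector, Layer, PAPER_INIT, SoilProfile
from csmig.synthetic import default_sample_times


@pytest.fixture
def paper_init():
    return PAPER_INIT


@pytest.fixture
def equal_model():
    """The reference six-compartment chain with k = 0.024 y^-1."""
    return ChainModel.equal_rate(0.024)


@pytest.fixture
def study_times():
    """20 irregular sampling times spanning 1.2-37 y."""
    return default_sample_times(20)


def make_profile(activities, date=datetime.date(2023, 4, 20), density=1.3, thickness=5.0):
    layers = [
        Layer(top_cm=i * thickness, bottom_cm=(i + 1) * thickness, activity=float(a))
        for i, a in enumerate(activities)
    ]
    return SoilProfile(sample_date=date, layers=layers, density_g_cm3=density)


@pytest.fixture
def profile_factory():
    return make_profile
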