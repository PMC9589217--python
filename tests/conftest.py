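import numpy as np
import pytest

from femsgait.linkage import build_linkage
from femsgait.muscles import calibrate_slack, load_muscle_set
from femsgait.synth.gait import GaitTrialSpec, generate_gait_trial
from femsgait.synth.geometry import build_knee_geometry


@pytest.fixture(scope="session")
def linkage():
    return build_linkage(80.0, 1.75)


@pytest.fixture(scope="session")
def muscles(linkage):
    mus = load_muscle_set(subject_height=linkage.subject_height)
    calibrate_slack(mus, linkage)
    return mus


@pytest.fixture(scope="session")
def trial():
    return generate_gait_trial(GaitTrialSpec())


@pytest.fixture(scope="session")
def short_trial():
    return generate_gait_trial(GaitTrialSpec(stance_duration=0.2))


@pytest.fixture(scope="session")
def knee_model():
    return build_knee_geometry()
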