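import numpy as np
import pytest

from pkbridge import ConcTimeProfile, OneCompartmentParams, concentration
from pkbridge.synthetic import DELAYED_PARAMS, DELAYED_SCHEDULE


@pytest.fixture
def mono_exp_profile():
    """10*exp(-0.1 t) sampled hourly on [0, 48]."""
    t = np.arange(0.0, 49.0)
    return ConcTimeProfile(
        subject_id="S1",
        treatment="A",
        period=1,
        sequence="AB",
        times=tuple(t),
        concentrations=tuple(10.0 * np.exp(-0.1 * t)),
    )


@pytest.fixture
def delayed_noiseless_profile():
    """Noiseless 100-mg population curve on the dense sampling schedule."""
    t = np.asarray(DELAYED_SCHEDULE, dtype=float)
    c = np.asarray(concentration(DELAYED_PARAMS, 100.0, t))
    return ConcTimeProfile(
        subject_id="S1",
        treatment="DR100",
        period=1,
        sequence="DR100-DR20",
        times=tuple(t),
        concentrations=tuple(c),
    )


def make_profile(times, conc, **kw):
    defaults = dict(subject_id="S1", treatment="A", period=1, sequence="AB")
    defaults.update(kw)
    return ConcTimeProfile(times=tuple(times), concentrations=tuple(conc), **defaults)
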