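import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivimfit import PROTOCOL_B_VALUES, DecayCurve, FitBounds, IVIMParams, ivim_signal

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Typical resting paraspinal-muscle parameters (generator settings in tests).
MUSCLE_F, MUSCLE_DSTAR, MUSCLE_D = 0.11, 28.4e-3, 1.36e-3


@pytest.fixture(scope="session")
def b_protocol():
    return PROTOCOL_B_VALUES


@pytest.fixture(scope="session")
def bounds():
    return FitBounds()


@pytest.fixture(scope="session")
def muscle_params():
    return IVIMParams(f=MUSCLE_F, Dstar=MUSCLE_DSTAR, D=MUSCLE_D)


def noiseless_curve(params: IVIMParams, b=PROTOCOL_B_VALUES) -> DecayCurve:
    return DecayCurve(b, ivim_signal(params, b))


@pytest.fixture(scope="session")
def muscle_curve(muscle_params):
    return noiseless_curve(muscle_params)


def interior_truths(n, bounds, rng, margin=0.05, f_min=0.02, sep=10.0):
    """Uniform interior truths with f >= f_min and D* >= sep * D.

    'Interior' means a ``margin``-of-range distance inside every bound, which
    also guarantees the time-scale separation the segmented fits assume.
    """
    lo = bounds.lower + margin * (bounds.upper - bounds.lower)
    hi = bounds.upper - margin * (bounds.upper - bounds.lower)
    out = []
    while len(out) < n:
        f, ds, d = rng.uniform(lo, hi)
        if f < f_min or ds < sep * d:
            continue
        out.append(IVIMParams(f, ds, d))
    return out
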