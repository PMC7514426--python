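import numpy as np
import pytest

from wavetf.synthetic import CurveSpec, SimSpec, generate_tvtf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tv_dataset():
    """One seeded time-varying dataset: smooth delta_1 and omega_0 curves, AR(1) input."""
    spec = SimSpec(
        T_train=512,
        T_test=76,
        delta=[CurveSpec("cosine", a=0.4, b=0.2)],
        omega=[CurveSpec("linear", a=0.8, b=-0.4)],
        input_ar=[0.5],
        noise_sd=0.1,
        seed=99,
    )
    y, x, curves = generate_tvtf(spec)
    return spec, y, x, curves
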