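import numpy as np
import pytest

from fibrilmech import synthetic


@pytest.fixture(scope="session")
def pbs_curve_spec():
    """Hydrated-fibril indentation conditions: soft lever, 50 nm indent."""
    return synthetic.CurveSimSpec(
        modulus_true_pa=16.2e6,
        spring_constant_n_per_m=0.24,
        max_indentation_nm=50.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_fibril_image():
    """Noiseless D-banded fibril, 2 nm/px, ≥ 8 periods along the axis."""
    spec = synthetic.FibrilImageSpec(
        substrate_roughness_sd_nm=0.0, image_shape=(96, 320), seed=1
    )
    return synthetic.generate_fibril_image(spec, state="dry"), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
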