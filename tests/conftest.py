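import numpy as np
import pytest

from glymphdti.synth import PhantomSpec, make_gradient_table

# common slab tensor sets (mm^2/s)
ANISO = dict(
    proj_evals=(1.7e-3, 0.2e-3, 0.2e-3),
    assoc_evals=(1.7e-3, 0.2e-3, 0.2e-3),
    background_evals=(1.7e-3, 0.2e-3, 0.2e-3),
)
ALPS_SLABS = dict(
    proj_evals=(1.2e-3, 0.6e-3, 1.7e-3),
    assoc_evals=(1.2e-3, 1.7e-3, 0.6e-3),
)


@pytest.fixture(scope="session")
def gtab():
    """The default b0 + 32-direction b=1000 scheme."""
    return make_gradient_table(32, 1000.0, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def uniform_f_spec(f_true: float, shape=(8, 8, 4), noise="none", **kw) -> PhantomSpec:
    """Anisotropic-everywhere phantom with a single true free-water fraction."""
    return PhantomSpec(
        shape=shape,
        noise_model=noise,
        proj_f=f_true,
        assoc_f=f_true,
        background_f=f_true,
        **{**ANISO, **kw},
    )
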