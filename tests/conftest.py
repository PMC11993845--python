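import os

# single-threaded BLAS keeps numerical results and timings reproducible
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from mammoseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def midrange_bundle():
    """Noise-free phantom at a mid gland content, shared across tests."""
    spec = PhantomSpec(
        height=128, width=92, target_content_ratio=0.65, noise_sd=0.0, seed=5
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
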