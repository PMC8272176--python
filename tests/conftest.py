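import numpy as np
import pytest

from casenet.data_io import normalize_intensity
from casenet.phantom import PhantomConfig, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_samples(image_size=32, n_patients=4, slices=3, seed=7, **kw):
    """Small normalized phantom cohort for fast pipeline tests."""
    cfg = PhantomConfig(
        image_size=image_size,
        n_patients=n_patients,
        slices_per_patient=slices,
        seed=seed,
        **kw,
    )
    samples = []
    for i in range(n_patients):
        ss = generate_patient(cfg, i)
        vol = normalize_intensity(np.stack([s.image for s in ss]))
        for j, s in enumerate(ss):
            s.image = vol[j].astype(np.float32)
        samples.extend(ss)
    return samples


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_samples()
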