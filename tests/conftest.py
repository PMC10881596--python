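import numpy as np
import pytest
from hypothesis import settings

from edemaseg import fit_prior, generate_training_pairs
from edemaseg.phantoms import PhantomSpec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def prior(default_spec):
    """Adipose density prior fitted on ten edema-free phantom mask pairs."""
    return fit_prior(generate_training_pairs(default_spec, 10, seed=7))


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean arrays, as a fraction."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
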