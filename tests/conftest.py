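import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from utrfold.energy import load_default_model

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def planted():
    """A designed ~100-nt three-hairpin RNA with its ground-truth structure."""
    from utrfold.synthetic import planted_structure

    record, structure = planted_structure(
        n_hairpins=3, stem=9, loop=6, linker=7, seed=0
    )
    return record, structure
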