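import pytest

from lvfix import ModelSpec, solve_psi

BASE = dict(M=100, beta=0.6, gamma=0.1)


def make_spec(a, b, c, d, **kw):
    return ModelSpec.create(a=a, b=b, c=c, d=d, **{**BASE, **kw})


@pytest.fixture(scope="session")
def neutral_spec():
    return make_spec(1, 1, 1, 1)


@pytest.fixture(scope="session")
def coexistence_spec():
    # symmetric coexistence game: a = d = 1, b = c = 1.1
    return make_spec(1, 1.1, 1.1, 1)


@pytest.fixture(scope="session")
def coordination_spec():
    return make_spec(1, 0.9, 0.9, 1)


@pytest.fixture(scope="session")
def dominance_spec():
    # frequency-independent dominant mutant: a = b = 1, c = d = 0.975
    return make_spec(1, 1, 0.975, 0.975)


@pytest.fixture(scope="session")
def psi_internal(neutral_spec):
    return solve_psi(neutral_spec, regime="internal")


@pytest.fixture(scope="session")
def psi_dominance(dominance_spec):
    return solve_psi(dominance_spec, regime="dominance")
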