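import pytest

from rflp import fixtures as fx


@pytest.fixture(scope="session")
def reference():
    return fx.make_reference_template(seed=1)


@pytest.fixture(scope="session")
def alpha(reference):
    return fx.make_variant(reference, "alpha")


@pytest.fixture(scope="session")
def beta(reference):
    return fx.make_variant(reference, "beta")


@pytest.fixture(scope="session")
def decoy():
    return fx.make_decoy(seed=1)


@pytest.fixture(scope="session")
def alignment():
    return fx.make_alignment(seed=1)


@pytest.fixture(scope="session")
def lineage_templates(alpha, beta, reference):
    return [(alpha, "alpha"), (beta, "beta"), (reference, "other")]
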