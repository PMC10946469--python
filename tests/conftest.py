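import pytest

from bonevar import build_example_cohort, load_gene_panel


@pytest.fixture(scope="session")
def panel():
    return load_gene_panel()


@pytest.fixture(scope="session")
def example_fixture():
    return build_example_cohort()
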