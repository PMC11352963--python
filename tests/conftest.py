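import pytest

import lettura as L


@pytest.fixture(scope="session")
def lexicon():
    return L.synth_lexicon(seed=1, size=1200)


@pytest.fixture(scope="session")
def battery(lexicon):
    return L.assemble_battery(lexicon, seed=1)


@pytest.fixture(scope="session")
def resources(lexicon, battery):
    return L.CodingResources(lexicon=lexicon, semantic_table=battery.semantic_table)


@pytest.fixture(scope="session")
def embedded_norms():
    return L.load_embedded_norms()
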