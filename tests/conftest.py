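import pytest

from gofeat import fixtures, parse_obo
from gofeat.workflows import planted_rule_experiment

#: single-domain chain ontology: leaf is_a mid is_a root
CHAIN_OBO = """\
format-version: 1.2
ontology: synthetic-go

[Term]
id: GO:0000001
name: chain root
namespace: molecular_function

[Term]
id: GO:0000002
name: chain mid
namespace: molecular_function
is_a: GO:0000001 ! chain root

[Term]
id: GO:0000003
name: chain leaf
namespace: molecular_function
is_a: GO:0000002 ! chain mid
"""


@pytest.fixture(scope="session")
def chain_onto():
    return parse_obo(CHAIN_OBO)


@pytest.fixture(scope="session")
def toy():
    """30-term, three-domain toy ontology: (obo text, manifest, Ontology)."""
    obo, manifest = fixtures.make_toy_ontology(30, seed=1)
    return obo, manifest, parse_obo(obo)


@pytest.fixture(scope="session")
def planted():
    """The planted disorder-rule experiment (trained once per session)."""
    return planted_rule_experiment(seed=1)
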