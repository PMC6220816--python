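"""Shared fixtures: small hand-built ontologies and annotation corpora."""

import io

import pytest

from genefunc import ontology as onto_mod


FIVE_TERM_OBO = """\
format-version: 1.2

[Term]
id: T:0000001
name: root process
namespace: biological_process

[Term]
id: T:0000002
name: child one
namespace: biological_process
is_a: T:0000001

[Term]
id: T:0000003
name: child two
namespace: biological_process
is_a: T:0000001

[Term]
id: T:0000004
name: grandchild one
namespace: biological_process
is_a: T:0000002

[Term]
id: T:0000005
name: grandchild two
namespace: biological_process
is_a: T:0000003
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: A
name: apex

[Term]
id: B
name: left
is_a: A

[Term]
id: C
name: right
is_a: A

[Term]
id: D
name: bottom
is_a: B
is_a: C
"""


@pytest.fixture
def five_term_ontology():
    return onto_mod.parse_obo(io.StringIO(FIVE_TERM_OBO))


@pytest.fixture
def diamond_ontology():
    return onto_mod.parse_obo(io.StringIO(DIAMOND_OBO), namespace=None)


@pytest.fixture
def small_store(five_term_ontology):
    """Three genes annotated into the five-term tree."""
    tsv = "g1\tT:0000004\ng2\tT:0000005\ng3\tT:0000002\ng3\tT:0000003\n"
    return onto_mod.load_annotations(io.StringIO(tsv), five_term_ontology)
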