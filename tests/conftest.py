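import io

import pytest

from ppitype import ontology as onto
from ppitype import synthetic as syn

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: A
name: root term

[Term]
id: B
name: middle term
is_a: A

[Term]
id: C
name: leaf term
is_a: B
"""

# A <- B, A <- C, {B,C} <- D
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: A
name: root

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
def chain():
    return onto.load_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond():
    return onto.load_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture(scope="session")
def method_ontology():
    return onto.load_obo(io.StringIO(syn.method_ontology_obo()))


@pytest.fixture(scope="session")
def type_ontology():
    return onto.load_obo(io.StringIO(syn.type_ontology_obo()))


@pytest.fixture(scope="session")
def standard_fixture(method_ontology, type_ontology):
    """The standard planted-signal dataset, propagated and with the assay
    map applied: 5,000 interactions, 12 methods, 3 types, log-odds 3.0."""
    from ppitype import interactions as ia

    cfg = syn.GeneratorConfig(seed=20240313)
    mitab, truth = syn.generate_interactions(cfg)
    records = ia.read_mitab(io.StringIO(mitab))
    inter = ia.deduplicate(records)
    inter = ia.propagate(method_ontology, type_ontology, inter)
    inter = ia.map_assay_types(inter, syn.DEFAULT_ASSAY_MAP,
                               method_ontology, type_ontology)
    return cfg, inter, truth


@pytest.fixture(scope="session")
def standard_matrix(standard_fixture, method_ontology):
    from ppitype import features as feat

    _, inter, _ = standard_fixture
    return feat.build_feature_matrix(
        inter, exclusion_root=syn.ENZYMATIC_STUDY, min_count=200,
        ontology_methods=method_ontology,
    )
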