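import textwrap

import pandas as pd
import pytest

from degscope.deg_classify import classify_table
from degscope.expression_io import ExpressionTable
from degscope.go_annotations import AnnotationSet
from degscope.go_ontology import parse_obo
from degscope.synthetic_fixtures import SyntheticConfig, make_toy_ontology


CHAIN_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: GO:0000003
    name: child
    namespace: biological_process
    is_a: GO:0000002 ! mid

    [Term]
    id: GO:0000002
    name: mid
    namespace: biological_process
    is_a: GO:0000001 ! root
    alt_id: GO:0000099

    [Term]
    id: GO:0000001
    name: root
    namespace: biological_process
    """
)

DIAMOND_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: GO:0000001
    name: a
    namespace: molecular_function
    is_a: GO:0000002 ! b
    is_a: GO:0000003 ! c

    [Term]
    id: GO:0000002
    name: b
    namespace: molecular_function
    is_a: GO:0000004 ! d

    [Term]
    id: GO:0000003
    name: c
    namespace: molecular_function
    is_a: GO:0000004 ! d

    [Term]
    id: GO:0000004
    name: d
    namespace: molecular_function
    """
)


def make_table(rows, label="test") -> ExpressionTable:
    """Build an ExpressionTable from (gene_id, log_fc, p_value) triples."""
    frame = pd.DataFrame(rows, columns=["gene_id", "log_fc", "p_value"])
    frame["gene_id"] = frame["gene_id"].astype(str)
    return ExpressionTable(frame=frame, source_label=label)


def make_classified(rows, alpha=0.05):
    return classify_table(make_table(rows), alpha=alpha)


@pytest.fixture
def chain_dag(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return parse_obo(path)


@pytest.fixture
def diamond_dag(tmp_path):
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return parse_obo(path)


@pytest.fixture
def toy_ontology():
    return make_toy_ontology(SyntheticConfig(seed=7, n_genes=50, n_terms_per_namespace=8))


@pytest.fixture
def simple_annotations():
    return AnnotationSet(
        gene_to_terms={
            "g1": {"GO:0000003"},
            "g2": {"GO:0000003", "GO:0000002"},
            "g3": {"GO:0000001"},
        },
        propagated=False,
        taxon=9606,
    )
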