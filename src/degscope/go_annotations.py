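"""Gene-to-term annotations in NCBI gene2go format.

The gene2go file is tab-separated with one annotation per row
(``#tax_id  GeneID  GO_ID  Evidence  Qualifier  GO_term  PubMed  Category``,
optionally gzip-compressed).  Reading filters to a single taxon and drops
``NOT``-qualified rows; propagation closes each gene's annotations over the
ontology's ancestor relation so counts respect the true-path rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from degscope.go_ontology import OntologyDAG, ancestors, resolve_term

logger = logging.getLogger(__name__)

GENE2GO_COLUMNS = [
    "tax_id",
    "GeneID",
    "GO_ID",
    "Evidence",
    "Qualifier",
    "GO_term",
    "PubMed",
    "Category",
]

#: gene2go Category label per ontology namespace
CATEGORY_BY_NAMESPACE = {
    "biological_process": "Process",
    "molecular_function": "Function",
    "cellular_component": "Component",
}

DEFAULT_TAXON = 9606  # human


@dataclass
class AnnotationSet:
    """Bidirectional gene <-> term mapping for one taxon.

    ``gene_to_terms`` and ``term_to_genes`` are exact inverses;
    ``propagated`` records whether annotations have been closed over
    ontology ancestors.
    """

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    propagated: bool = False
    taxon: int = DEFAULT_TAXON

    def __post_init__(self):
        if not self.term_to_genes:
            self.term_to_genes = _invert(self.gene_to_terms)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def n_annotations(self) -> int:
        return sum(len(ts) for ts in self.gene_to_terms.values())


def _invert(mapping: dict[str, set[str]]) -> dict[str, set[str]]:
    inverse: dict[str, set[str]] = {}
    for key, values in mapping.items():
        for value in values:
            inverse.setdefault(value, set()).add(key)
    return inverse


def read_gene2go(path, taxon: int = DEFAULT_TAXON) -> AnnotationSet:
    """Read a gene2go file, keeping one taxon and positive annotations.

    Rows whose Qualifier contains ``NOT`` are excluded (negated annotations
    are not evidence of association); duplicate (gene, term) pairs collapse
    to one mapping entry.  Raises if the required columns are absent or no
    row matches the taxon.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    frame.columns = [c.lstrip("#") for c in frame.columns]
    missing = [c for c in ("tax_id", "GeneID", "GO_ID", "Qualifier") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: gene2go file missing column(s) {missing}")

    frame = frame[pd.to_numeric(frame["tax_id"], errors="coerce") == taxon]
    if frame.empty:
        raise ValueError(f"{path}: no annotation rows for taxon {taxon}")
    qualifier = frame["Qualifier"].fillna("")
    frame = frame[~qualifier.str.contains("NOT", case=True)]

    gene_to_terms: dict[str, set[str]] = {}
    for gene, term in zip(frame["GeneID"].astype(str), frame["GO_ID"].astype(str)):
        gene_to_terms.setdefault(gene, set()).add(term)
    return AnnotationSet(gene_to_terms=gene_to_terms, propagated=False, taxon=taxon)


def propagate_annotations(
    ann: AnnotationSet, dag: OntologyDAG, include_part_of: bool = False
) -> AnnotationSet:
    """Close every gene's annotations over ontology ancestors.

    Each gene becomes annotated to all ancestors (``is_a``; plus
    ``part_of`` when requested) of its directly annotated terms.  The gene
    set is unchanged and the operation is idempotent.  Alternate ids are
    canonicalized; an unresolvable term id raises ``KeyError``.
    """
    if ann.propagated:
        logger.warning("annotation set already propagated; re-closing is a no-op")
    relations = {"is_a", "part_of"} if include_part_of else {"is_a"}

    # cache ancestor sets per term: annotation files repeat terms heavily
    closure_cache: dict[str, set[str]] = {}

    def closed(term_id: str) -> set[str]:
        canonical = resolve_term(dag, term_id)
        if canonical not in closure_cache:
            closure_cache[canonical] = {canonical} | ancestors(dag, canonical, relations)
        return closure_cache[canonical]

    gene_to_terms = {
        gene: set().union(*(closed(t) for t in terms)) if terms else set()
        for gene, terms in ann.gene_to_terms.items()
    }
    return AnnotationSet(
        gene_to_terms=gene_to_terms, propagated=True, taxon=ann.taxon
    )


def genes_for_term(ann: AnnotationSet, term_id: str, universe: set[str]) -> set[str]:
    """Genes annotated to ``term_id``, restricted to ``universe``.

    Unknown terms yield the empty set.
    """
    return ann.term_to_genes.get(term_id, set()) & universe


def annotation_coverage(ann: AnnotationSet, gene_ids) -> float:
    """Fraction of ``gene_ids`` that carry at least one annotation.

    Used to warn when expression-table identifiers do not live in the same
    id space as the annotation file (e.g. symbols vs Entrez GeneIDs).
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        return 0.0
    return sum(1 for g in gene_ids if g in ann.gene_to_terms) / len(gene_ids)
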