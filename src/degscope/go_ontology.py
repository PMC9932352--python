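"""Gene Ontology DAG loaded from an OBO flat file.

The ontology is a directed acyclic graph of terms in three disjoint
namespaces (biological_process, molecular_function, cellular_component),
with child-to-parent ``is_a`` edges and, separately, ``part_of``
relationships.  Parsing is delegated to :mod:`obonet`; this module layers
validation (well-formed ids, resolvable parents, acyclicity, alt-id
uniqueness) and ancestor queries on top.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

_TERM_ID_RE = re.compile(r"^GO:\d{7}$")


class OntologyError(ValueError):
    """Malformed or inconsistent ontology input."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str
    is_a_parents: frozenset[str] = frozenset()
    part_of_parents: frozenset[str] = frozenset()
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """All non-obsolete terms plus an alternate-id index.

    ``terms`` maps canonical id -> :class:`OntologyTerm`; obsolete term ids
    are kept in ``obsolete_ids`` so they can be recognized but are excluded
    from ancestor queries and resolution.
    """

    terms: dict[str, OntologyTerm]
    alt_id_index: dict[str, str] = field(default_factory=dict)
    obsolete_ids: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.terms)

    def terms_in_namespace(self, namespace: str) -> set[str]:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace: {namespace!r}")
        return {t for t, term in self.terms.items() if term.namespace == namespace}

    def namespace_of(self, term_id: str) -> str:
        return self.terms[resolve_term(self, term_id)].namespace


def _parse_relationship(entries) -> frozenset[str]:
    part_of = set()
    for entry in entries or ():
        fields = entry.split()
        if len(fields) >= 2 and fields[0] == "part_of":
            part_of.add(fields[1])
    return frozenset(part_of)


def parse_obo(path) -> OntologyDAG:
    """Load an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Honors the ``id``, ``name``, ``namespace``, ``is_a``,
    ``relationship: part_of``, ``alt_id`` and ``is_obsolete`` tags; other
    tags and ``[Typedef]`` stanzas are ignored.  Raises
    :class:`OntologyError` on dangling parent references, is_a cycles,
    malformed ids, or alternate ids claimed by two terms.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)

    terms: dict[str, OntologyTerm] = {}
    alt_index: dict[str, str] = {}
    obsolete: set[str] = set()

    for node, data in graph.nodes(data=True):
        if "name" not in data and "namespace" not in data:
            # node created implicitly by an edge: a parent that has no stanza
            raise OntologyError(f"dangling parent reference: {node}")
        if not _TERM_ID_RE.match(node):
            raise OntologyError(f"malformed term id: {node!r}")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        namespace = data.get("namespace")
        if namespace not in NAMESPACES:
            raise OntologyError(f"{node}: missing or unknown namespace {namespace!r}")
        is_a = frozenset(data.get("is_a", ()))
        part_of = _parse_relationship(data.get("relationship"))
        alt_ids = frozenset(data.get("alt_id", ()))
        for alt in alt_ids:
            if alt in alt_index and alt_index[alt] != node:
                raise OntologyError(
                    f"alt_id {alt} claimed by both {alt_index[alt]} and {node}"
                )
            alt_index[alt] = node
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", node),
            namespace=namespace,
            is_a_parents=is_a,
            part_of_parents=part_of,
            alt_ids=alt_ids,
        )

    for term in terms.values():
        for parent in term.is_a_parents | term.part_of_parents:
            if parent not in terms and parent not in obsolete:
                raise OntologyError(f"{term.term_id}: unknown parent {parent}")

    is_a_graph = nx.DiGraph(
        (t.term_id, p) for t in terms.values() for p in t.is_a_parents
    )
    if not nx.is_directed_acyclic_graph(is_a_graph):
        cycle = nx.find_cycle(is_a_graph)
        raise OntologyError(f"is_a cycle detected: {cycle}")

    return OntologyDAG(terms=terms, alt_id_index=alt_index, obsolete_ids=frozenset(obsolete))


def resolve_term(dag: OntologyDAG, any_id: str) -> str:
    """Canonical term id for a primary or alternate id; error otherwise."""
    if any_id in dag.terms:
        return any_id
    if any_id in dag.alt_id_index:
        return dag.alt_id_index[any_id]
    if any_id in dag.obsolete_ids:
        raise KeyError(f"term {any_id} is obsolete")
    raise KeyError(f"unknown term id: {any_id}")


def ancestors(
    dag: OntologyDAG, term_id: str, relations: frozenset[str] | set[str] = frozenset({"is_a"})
) -> set[str]:
    """Transitive closure of parents over the selected relations.

    The query term itself is excluded.  ``relations`` may contain ``is_a``
    and/or ``part_of``; parents that are obsolete terms are skipped.
    """
    bad = set(relations) - {"is_a", "part_of"}
    if bad:
        raise ValueError(f"unknown relation(s): {sorted(bad)}")
    start = resolve_term(dag, term_id)
    seen: set[str] = set()
    stack = [start]
    while stack:
        current = stack.pop()
        term = dag.terms[current]
        parents: set[str] = set()
        if "is_a" in relations:
            parents |= term.is_a_parents
        if "part_of" in relations:
            parents |= term.part_of_parents
        for parent in parents:
            if parent in dag.obsolete_ids or parent in seen:
                continue
            seen.add(parent)
            stack.append(parent)
    seen.discard(start)
    return seen
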