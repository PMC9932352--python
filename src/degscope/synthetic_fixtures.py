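"""Deterministic toy fixtures: ontology, annotations, expression tables.

Everything downstream of a real differential-expression analysis can be
exercised offline with these generators:

* a three-namespace mini gene ontology (one rooted tree per namespace plus
  a few extra ``is_a`` edges forming a DAG), serialized as valid OBO;
* gene2go-format annotations over a configurable gene universe, with one
  or more *planted* terms whose genes preferentially land in an up- or
  down-regulated set;
* expression tables in which planted up/down genes receive small p-values
  and signed fold changes, and background genes draw p uniformly from
  [0, 1].

A single integer seed drives one named pseudorandom stream per generator,
so regenerating one artifact never perturbs the others, and a fixed seed
reproduces byte-identical files.  Truth labels go to a sidecar CSV so the
expression files look exactly like real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from degscope.go_annotations import (
    CATEGORY_BY_NAMESPACE,
    GENE2GO_COLUMNS,
    AnnotationSet,
)
from degscope.go_ontology import NAMESPACES, OntologyDAG, parse_obo

# stream tags: independent child sequences of the master seed
_STREAM_ONTOLOGY = 1
_STREAM_ANNOTATIONS = 2
_STREAM_EXPR1 = 3
_STREAM_EXPR2 = 4


@dataclass(frozen=True)
class PlantedTerm:
    """A term whose annotations are concentrated in one DE direction."""

    term_id: str
    direction: str  # "up" or "down"
    annotation_rate_in_de: float = 0.8
    background_rate: float = 0.1

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down'; got {self.direction!r}")
        if not (0 <= self.background_rate <= 1 and 0 <= self.annotation_rate_in_de <= 1):
            raise ValueError("annotation rates must lie in [0, 1]")
        if self.annotation_rate_in_de <= self.background_rate:
            raise ValueError("planted terms need annotation_rate_in_de > background_rate")


@dataclass
class SyntheticConfig:
    """Study conditions for the toy data.

    Defaults give 1000 genes, 10% planted up- and 10% planted
    down-regulated, DE p-values uniform on [1e-6, alpha/2] (always
    significant at alpha = 0.05), fold-change magnitudes around 2, and one
    planted biological_process term annotated to 80% of the up-regulated
    genes against a 10% background rate.
    """

    seed: int = 0
    n_genes: int = 1000
    n_terms_per_namespace: int = 10
    frac_up: float = 0.1
    frac_down: float = 0.1
    de_p_low: float = 1e-6
    de_p_high: float = 0.025
    lfc_effect: float = 2.0
    background_rate: float = 0.1
    planted_terms: list[PlantedTerm] | None = None  # None -> one auto BP/up term
    taxon: int = 9606
    overlap_fraction: float = 0.8  # shared gene ids between the two tables

    def __post_init__(self):
        if not (0 <= self.frac_up and 0 <= self.frac_down and self.frac_up + self.frac_down < 1):
            raise ValueError("frac_up + frac_down must be < 1")
        if self.n_terms_per_namespace < 2:
            raise ValueError("need at least 2 terms per namespace")
        if not (0 < self.de_p_low < self.de_p_high <= 1):
            raise ValueError("DE p-value range must satisfy 0 < low < high <= 1")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _term_id(ns_index: int, offset: int) -> str:
    # namespace blocks: BP 0000001.., MF 0100001.., CC 0200001..
    return f"GO:{ns_index * 100000 + offset + 1:07d}"


@dataclass
class ToyOntology:
    obo_text: str
    dag: OntologyDAG
    leaves_by_namespace: dict[str, list[str]]

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.obo_text, encoding="utf-8")
        return path


def make_toy_ontology(config: SyntheticConfig) -> ToyOntology:
    """Build three rooted term trees (one per namespace) with extra edges.

    Term i (i >= 1) of a namespace gets a uniformly random parent among
    terms 0..i-1, guaranteeing a connected DAG rooted at term 0; about a
    quarter of the terms gain a second random ``is_a`` parent (still
    earlier in the order, so acyclicity is preserved by construction).
    """
    rng = _rng(config, _STREAM_ONTOLOGY)
    m = config.n_terms_per_namespace
    stanzas: list[str] = []
    leaves: dict[str, list[str]] = {}
    for ns_index, namespace in enumerate(NAMESPACES):
        ids = [_term_id(ns_index, i) for i in range(m)]
        parents: dict[str, list[str]] = {ids[0]: []}
        for i in range(1, m):
            parents[ids[i]] = [ids[int(rng.integers(0, i))]]
        n_extra = m // 4
        for _ in range(n_extra):
            i = int(rng.integers(2, m))
            j = int(rng.integers(0, i))
            if ids[j] not in parents[ids[i]]:
                parents[ids[i]].append(ids[j])
        has_child = {p for plist in parents.values() for p in plist}
        leaves[namespace] = [t for t in ids if t not in has_child]
        tag = namespace.split("_")[1]
        for i, term in enumerate(ids):
            lines = [
                "[Term]",
                f"id: {term}",
                f"name: toy {tag} term {i}",
                f"namespace: {namespace}",
            ]
            lines += [f"is_a: {p} ! parent" for p in sorted(parents[term])]
            stanzas.append("\n".join(lines))
    obo_text = "format-version: 1.2\nontology: degscope-toy\n\n" + "\n\n".join(stanzas) + "\n"

    import io

    # round-trip through the serialized text so the returned DAG is exactly
    # what a consumer of the written file would see
    dag = parse_obo(io.StringIO(obo_text))
    return ToyOntology(obo_text=obo_text, dag=dag, leaves_by_namespace=leaves)


def gene_ids(config: SyntheticConfig) -> list[str]:
    """Entrez-style numeric gene identifiers, ``"1001"`` onwards."""
    return [str(1001 + i) for i in range(config.n_genes)]


def gene_partition(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic split of the gene universe into up/down/null blocks.

    The first ``frac_up * n`` genes are destined to be up-regulated, the
    next ``frac_down * n`` down-regulated; annotation and expression
    generators share this partition so planted enrichment is coherent.
    """
    ids = gene_ids(config)
    n_up = int(round(config.frac_up * config.n_genes))
    n_down = int(round(config.frac_down * config.n_genes))
    return {
        "up": ids[:n_up],
        "down": ids[n_up : n_up + n_down],
        "null": ids[n_up + n_down :],
    }


def default_planted_terms(config: SyntheticConfig, ontology: ToyOntology) -> list[PlantedTerm]:
    if config.planted_terms is not None:
        return list(config.planted_terms)
    leaf = sorted(ontology.leaves_by_namespace["biological_process"])[0]
    return [PlantedTerm(term_id=leaf, direction="up", background_rate=config.background_rate)]


@dataclass
class ToyAnnotations:
    tsv_text: str
    annotations: AnnotationSet
    planted: list[PlantedTerm]

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.tsv_text, encoding="utf-8")
        return path


def make_toy_annotations(ontology: ToyOntology, config: SyntheticConfig) -> ToyAnnotations:
    """Annotate genes to leaf terms; concentrate planted terms in DE genes.

    Every gene is annotated to each leaf term independently at
    ``background_rate``; for each planted term, the genes of its direction
    block are (re-)annotated at ``annotation_rate_in_de`` instead.  Output
    is a valid gene2go TSV for the configured taxon.
    """
    rng = _rng(config, _STREAM_ANNOTATIONS)
    partition = gene_partition(config)
    planted = default_planted_terms(config, ontology)
    planted_by_term = {p.term_id: p for p in planted}
    ids = gene_ids(config)

    all_leaves = [t for ns in NAMESPACES for t in sorted(ontology.leaves_by_namespace[ns])]
    gene_to_terms: dict[str, set[str]] = {g: set() for g in ids}
    for term in all_leaves:
        draws = rng.random(len(ids))
        plant = planted_by_term.get(term)
        de_block = set(partition[plant.direction]) if plant else set()
        for gene, u in zip(ids, draws):
            rate = (
                plant.annotation_rate_in_de
                if plant and gene in de_block
                else (plant.background_rate if plant else config.background_rate)
            )
            if u < rate:
                gene_to_terms[gene].add(term)

    rows = []
    for gene in ids:
        for term in sorted(gene_to_terms[gene]):
            namespace = ontology.dag.terms[term].namespace
            rows.append(
                (
                    str(config.taxon),
                    gene,
                    term,
                    "IEA",
                    "-",
                    ontology.dag.terms[term].name,
                    "-",
                    CATEGORY_BY_NAMESPACE[namespace],
                )
            )
    header = "#" + "\t".join(GENE2GO_COLUMNS)
    tsv_text = header + "\n" + "\n".join("\t".join(r) for r in rows) + "\n"
    ann = AnnotationSet(
        gene_to_terms={g: set(ts) for g, ts in gene_to_terms.items() if ts},
        propagated=False,
        taxon=config.taxon,
    )
    return ToyAnnotations(tsv_text=tsv_text, annotations=ann, planted=planted)


def _draw_expression(
    rng: np.random.Generator, config: SyntheticConfig, ids: list[str], partition
) -> pd.DataFrame:
    up, down = set(partition["up"]), set(partition["down"])
    records = []
    for gene in ids:
        if gene in up or gene in down:
            p = rng.uniform(config.de_p_low, config.de_p_high)
            magnitude = abs(rng.normal(config.lfc_effect, 0.2 * config.lfc_effect))
            lfc = magnitude if gene in up else -magnitude
            label = "Upregulated" if gene in up else "Downregulated"
        else:
            p = rng.uniform(0.0, 1.0)
            lfc = rng.normal(0.0, 0.3)
            label = "Not differentially expressed"
        records.append((gene, lfc, p, label))
    return pd.DataFrame(records, columns=["GeneID", "log2FC", "pvalue", "true_class"])


@dataclass
class SimulatedExpression:
    tables: list[pd.DataFrame]  # CSV-ready frames (GeneID, log2FC, pvalue)
    truth: pd.DataFrame  # (dataset, GeneID, true_class)


def simulate_expression(config: SyntheticConfig, two_datasets: bool = False) -> SimulatedExpression:
    """Expression table(s) with planted up/down genes and known truth.

    Planted genes draw p uniformly below alpha/2 and a signed fold change
    of mean magnitude ``lfc_effect``; background genes draw p uniformly on
    [0, 1] and a near-zero fold change.  In two-dataset mode the second
    table keeps the first ``overlap_fraction`` of the gene ids and replaces
    the rest with fresh ids, redrawing all values independently.
    """
    ids = gene_ids(config)
    partition = gene_partition(config)
    frame1 = _draw_expression(_rng(config, _STREAM_EXPR1), config, ids, partition)

    tables = [frame1[["GeneID", "log2FC", "pvalue"]]]
    truth_frames = [frame1[["GeneID", "true_class"]].assign(dataset=1)]

    if two_datasets:
        n_shared = int(round(config.overlap_fraction * config.n_genes))
        ids2 = ids[:n_shared] + [str(900001 + i) for i in range(config.n_genes - n_shared)]
        # dataset 2 reuses the same truth partition for shared genes
        part2 = {
            k: [g for g in v if g in set(ids2)] for k, v in partition.items()
        }
        part2["null"] = part2["null"] + [g for g in ids2 if g.startswith("9000")]
        frame2 = _draw_expression(_rng(config, _STREAM_EXPR2), config, ids2, part2)
        tables.append(frame2[["GeneID", "log2FC", "pvalue"]])
        truth_frames.append(frame2[["GeneID", "true_class"]].assign(dataset=2))

    truth = pd.concat(truth_frames, ignore_index=True)[["dataset", "GeneID", "true_class"]]
    return SimulatedExpression(tables=tables, truth=truth)


def simulate(outdir, config: SyntheticConfig | None = None) -> dict[str, Path]:
    """Write the full fixture bundle into ``outdir``.

    Produces ``expr1.csv``, ``expr2.csv``, ``toy.obo``, ``toy_gene2go.tsv``
    and the truth sidecar ``truth.csv``; returns the written paths.
    """
    config = config or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ontology = make_toy_ontology(config)
    annotations = make_toy_annotations(ontology, config)
    expression = simulate_expression(config, two_datasets=True)

    paths = {
        "obo": ontology.write(outdir / "toy.obo"),
        "gene2go": annotations.write(outdir / "toy_gene2go.tsv"),
        "expr1": outdir / "expr1.csv",
        "expr2": outdir / "expr2.csv",
        "truth": outdir / "truth.csv",
    }
    expression.tables[0].to_csv(paths["expr1"], index=False, float_format="%.10g")
    expression.tables[1].to_csv(paths["expr2"], index=False, float_format="%.10g")
    expression.truth.to_csv(paths["truth"], index=False)
    return paths
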