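"""GO over-representation analysis with hypergeometric tests and BH FDR.

For each direction of regulation (up, down) and each ontology namespace,
every term annotated to at least one study gene is tested: the number of
study genes k carrying the term is compared against a hypergeometric null
in which n study genes are drawn without replacement from a universe of N
background genes, K of which carry the term.  The reported p-value is the
upper tail P(X >= k), computed in log space; Benjamini-Hochberg correction
is applied independently within each (direction, namespace) family, giving
up to six corrected result groups — one per barplot.

The default universe for a namespace is the set of genes from the input
expression table that carry at least one propagated annotation in that
namespace: the measured-and-annotated genes are the natural background for
an array or RNA-seq experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from degscope.go_annotations import AnnotationSet
from degscope.go_ontology import NAMESPACES, OntologyDAG

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_FDR = 0.05

#: column order of the tab-separated results file
RESULT_COLUMNS = [
    "term_id",
    "name",
    "namespace",
    "direction",
    "k",
    "n",
    "K",
    "N",
    "p_value",
    "fdr",
    "fold",
    "percent",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation statistics for one term in one analysis.

    k of n study genes carry the term, against K of N universe genes.
    ``fold`` = (k/n)/(K/N); ``percent`` = 100*k / (number of genes in the
    direction's study set), the bar length in the ontology barplots.
    """

    term_id: str
    term_name: str
    namespace: str
    direction: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fdr: float
    fold: float
    percent: float


@dataclass
class EnrichmentRun:
    """Results grouped by (direction, namespace), each sorted by p-value."""

    groups: dict[tuple[str, str], list[EnrichmentResult]] = field(default_factory=dict)
    alpha_fdr: float = DEFAULT_ALPHA_FDR
    universe_size: int = 0

    def all_results(self) -> list[EnrichmentResult]:
        return [r for group in self.groups.values() for r in group]

    def group(self, direction: str, namespace: str) -> list[EnrichmentResult]:
        return self.groups.get((direction, namespace), [])


def _log_choose(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the draw
    size, k the observed count of marked items drawn.  Summation runs over
    the log-pmf for numerical stability; the result lies in (0, 1].
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    log_pmf = (
        _log_choose(K, support)
        + _log_choose(N - K, n - support)
        - _log_choose(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j : p_j >= p_i-rank} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted


def enrich(
    study: set[str],
    direction: str,
    ann: AnnotationSet,
    dag: OntologyDAG,
    universe: set[str],
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
) -> EnrichmentRun:
    """Test every annotated term for over-representation in ``study``.

    ``study`` must be a subset of ``universe`` and ``ann`` must be
    propagated.  Per namespace, the background is restricted to universe
    genes with at least one annotation in that namespace; each term with
    k >= 1 study genes is tested and BH correction is applied within the
    (direction, namespace) family.  An empty or fully unannotated study
    set yields an empty group with a warning.
    """
    if not ann.propagated:
        raise ValueError("annotation set must be propagated before enrichment")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down'; got {direction!r}")

    run = EnrichmentRun(alpha_fdr=alpha_fdr, universe_size=len(universe))
    direction_total = len(study)
    if direction_total == 0:
        logger.warning("empty %s study set; nothing to test", direction)
        for namespace in NAMESPACES:
            run.groups[(direction, namespace)] = []
        return run

    for namespace in NAMESPACES:
        ns_terms = dag.terms_in_namespace(namespace)
        annotated_universe = {
            g for g in universe if ann.gene_to_terms.get(g, set()) & ns_terms
        }
        study_ns = study & annotated_universe
        N = len(annotated_universe)
        n = len(study_ns)
        if n == 0:
            logger.warning(
                "no %s study gene annotated in %s; empty result group", direction, namespace
            )
            run.groups[(direction, namespace)] = []
            continue

        testable = sorted(
            {t for g in study_ns for t in ann.gene_to_terms[g] if t in ns_terms}
        )
        ks = np.array(
            [len(ann.term_to_genes[t] & study_ns) for t in testable], dtype=int
        )
        Ks = np.array(
            [len(ann.term_to_genes[t] & annotated_universe) for t in testable], dtype=int
        )
        pvals = np.array(
            [hypergeom_upper_tail(int(k), n, int(K), N) for k, K in zip(ks, Ks)]
        )
        fdrs = bh_adjust(pvals)

        results = [
            EnrichmentResult(
                term_id=t,
                term_name=dag.terms[t].name,
                namespace=namespace,
                direction=direction,
                k=int(k),
                n=n,
                K=int(K),
                N=N,
                p_value=float(p),
                fdr=float(q),
                fold=(k / n) / (K / N),
                percent=term_percentage(int(k), direction_total),
            )
            for t, k, K, p, q in zip(testable, ks, Ks, pvals, fdrs)
        ]
        results.sort(key=lambda r: (r.p_value, r.term_id))
        run.groups[(direction, namespace)] = results
    return run


def significant_terms(run: EnrichmentRun, alpha_fdr: float | None = None) -> EnrichmentRun:
    """Keep over-represented terms with FDR below threshold.

    Depleted terms (fold <= 1) are filtered out even when nominally
    significant: the barplots describe genes associated with ontologies,
    not the absence of association.  Grouping and sort order are preserved.
    """
    threshold = run.alpha_fdr if alpha_fdr is None else alpha_fdr
    filtered = EnrichmentRun(alpha_fdr=threshold, universe_size=run.universe_size)
    for key, results in run.groups.items():
        filtered.groups[key] = [
            r for r in results if r.fdr < threshold and r.fold > 1
        ]
    return filtered


def term_percentage(k: int, direction_total: int) -> float:
    """Percentage of the direction's genes annotated to a term: 100*k/total."""
    if direction_total < 1:
        raise ValueError("direction_total must be >= 1")
    if not (0 <= k <= direction_total):
        raise ValueError(f"k={k} outside [0, {direction_total}]")
    return 100.0 * k / direction_total


def run_to_frame(run: EnrichmentRun):
    """Flatten a run into a DataFrame with :data:`RESULT_COLUMNS`."""
    import pandas as pd

    rows = [
        {
            "term_id": r.term_id,
            "name": r.term_name,
            "namespace": r.namespace,
            "direction": r.direction,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "fold": r.fold,
            "percent": r.percent,
        }
        for key in sorted(run.groups)
        for r in run.groups[key]
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_enrichment_tsv(run: EnrichmentRun, path) -> None:
    """Write all result groups as a single tab-separated file."""
    run_to_frame(run).to_csv(path, sep="\t", index=False, float_format="%.10g")
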