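# Methods

## Scope and model

`degscope` operates on *processed* differential-expression results: one row
per gene with an identifier, a log2 fold change (logFC), and a p-value from
an upstream case-vs-control test. It performs no normalization and no
re-testing of raw intensities; the input p-values are taken as-is (raw or
adjusted — the package does not distinguish, and documents that the choice
is the caller's).

### Expression classification

A gene is called differentially expressed (DE) when `p < alpha` (default
`alpha = 0.05`); the sign of logFC splits DE calls into **Upregulated**
(`logFC > 0`) and **Downregulated** (`logFC < 0`); everything else is **Not
differentially expressed**. Two boundary cases are undefined by the
strict-inequality rules and are resolved conservatively:

* `p == alpha` is *not* significant (significance requires strict `p < alpha`);
* `p < alpha` with `logFC == 0` has no direction and is classed as not DE,
  with a logged warning.

These choices keep the three classes a total partition of any table. The
volcano plot shows `logFC` against `-log10 p`; p-values of exactly zero are
clipped to `1e-300` for the y-coordinate only (classification always uses
the raw p), so every point has finite coordinates.

### Ontology and annotations

The Gene Ontology is read from an OBO flat file (go-basic dialect) into a
DAG of terms across the three namespaces (biological_process,
molecular_function, cellular_component). Only the `id`, `name`,
`namespace`, `is_a`, `relationship: part_of`, `alt_id`, and `is_obsolete`
tags are honored; `[Typedef]` stanzas and other tags are ignored. Load-time
validation rejects dangling parent references, `is_a` cycles, and alternate
ids claimed by two terms; obsolete terms are recognized but excluded from
queries. Stanza parsing is delegated to `obonet`; the DAG container,
validation, and ancestor queries are this package's.

Annotations come from an NCBI gene2go-format TSV, filtered to one taxon
(default 9606, human). Rows whose Qualifier contains `NOT` are excluded
rather than treated as negative evidence — standard over-representation
practice. Before testing, each gene's annotations are closed over `is_a`
ancestors (the true-path rule); `part_of` can be added with a flag but is
off by default, as `is_a` is the one universally safe relation. Gene
identifiers are matched verbatim between the expression table and the
annotation file — no symbol/Entrez translation is attempted; when fewer
than half the table's genes carry annotations, the CLI emits a prominent
warning that the id spaces probably differ.

### Over-representation test

For each direction (up, down) and namespace, every term annotated to at
least one study gene is tested against the hypergeometric null: drawing
`n` study genes from `N` background genes of which `K` carry the term, the
reported p-value is the upper tail

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

computed by summing the log-pmf (log-gamma binomials + log-sum-exp) for
stability at large counts. Benjamini–Hochberg step-up correction is applied
*within each (direction, namespace) family* — six independent corrections,
mirroring the six analyses/barplots. Bonferroni is available via
`--mt bonferroni`.

The default background ("universe") for a namespace is the set of genes
present in the input table that carry at least one propagated annotation in
that namespace: the measured-and-annotated genes are the natural background
for an array or RNA-seq experiment. `--universe annotated-genome` switches
to all annotated genes of the taxon.

Significant terms are those with `fdr < 0.05` **and** fold enrichment
`(k/n)/(K/N) > 1`; depleted terms are computed but never plotted, since the
barplots describe genes *associated with* ontologies. The bar length is
`100 * k / |direction study set|` — the percentage of the direction's genes
annotated to the term, where the study set is the direction's genes within
the enrichment universe. The test's `n` is the namespace-annotated subset
of that study set; the two differ when a DE gene is annotated only in
other namespaces. Barplots cap at the top 20 terms by
p-value for readability (`--max-terms`); the full table is always written
as TSV.

### Two-dataset comparison

Both tables are classified with one shared alpha, then inner-joined on
exact, case-sensitive gene-id equality (`--normalize-ids upper` opts into
case folding; silent case folding across id systems is dangerous, so it is
never the default). The common genes are cross-tabulated into a 3×3
contingency table with rows = dataset-1 class and columns = dataset-2
class, both in the fixed order Downregulated / Not differentially
expressed / Upregulated. Row sums equal dataset-1 class counts over the
common genes, column sums dataset-2's, and the grand total the number of
common genes — these conservation identities are enforced by tests.

## Synthetic fixtures

The generator emulates the three inputs at toy scale so the whole pipeline
is testable offline:

* **Ontology** — one rooted random tree per namespace (term *i* attaches to
  a uniform earlier term, guaranteeing a connected DAG) plus extra `is_a`
  edges to earlier terms (~1 per 4 terms), serialized as valid OBO.
  Default 10 terms per namespace.
* **Annotations** — every gene is annotated to each leaf term independently
  at a background rate (default 0.10). *Planted* terms are instead
  annotated at a high rate (default 0.80) among the genes destined for one
  DE direction. Default: one planted biological_process leaf, up-regulated.
* **Expression** — 1000 genes by default, 10% planted up and 10% planted
  down. DE genes draw `p ~ U(1e-6, 0.025)` (always significant at
  alpha = 0.05) and logFC `±|N(2.0, 0.4)|`; background genes draw
  `p ~ U(0,1)` and `logFC ~ N(0, 0.3)`. Two-dataset mode keeps 80% of the
  gene ids and redraws all values independently. Truth labels go to a
  sidecar CSV so the expression files are indistinguishable from real
  inputs.

One integer seed feeds a named pseudorandom stream per generator
(`numpy` `default_rng([seed, stream])`), so fixed seeds reproduce
byte-identical files and adding a generator never perturbs the others.

What the fixtures do **not** emulate: microarray probe effects,
intensity-level noise, correlated p-values, realistic GO DAG depth/fan-out,
or symbol/Entrez id mismatches. Passing tests on fixtures therefore
demonstrate correctness of the counting, testing, and plumbing — not
robustness to the noise structure of real platform data.

## Numerical and degenerate-case choices

* Hypergeometric tail in log space; `k = 0` returns exactly 1.0. Agreement
  with exhaustive subset enumeration is ≤ 2.2e-15 over the full small-grid.
* BH adjustment is the step-up suffix minimum, capped at 1, stable under
  permutation of the input.
* Enrichment results sort by (p-value, term id); after true-path
  propagation an ancestor covering no other annotated leaf carries exactly
  the same gene set as its child and hence an identical p-value — such ties
  are real, and consumers should treat tied terms as jointly top-ranked.
* Empty study sets, studies with no annotated gene, and empty dataset
  intersections yield empty results with warnings, never crashes.
* Duplicate gene ids in an input CSV are a hard error by default
  (`--dedupe keep-min-p` aggregates by minimum p), because silent
  duplicates corrupt both the study set and the universe.

## Problem sizes

The test suite and the acceptance script use 1000-gene tables, 30–60-term
ontologies, 100-replicate recovery experiments, and exhaustive
hypergeometric grids up to N = 12; the full suite runs in well under a
minute. These sizes were chosen as the smallest at which every tested
property is non-trivial.

## Known limitations

* No GSEA or rank-based enrichment; no KEGG; no term redundancy reduction.
* No identifier translation; expression tables must share the annotation
  file's id space.
* `regulates` and cross-namespace relations are not modeled; OWL is not
  supported.
* Reported p-values test over-representation only; depletion is flagged via
  fold < 1 but not separately tested.
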