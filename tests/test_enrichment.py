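import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from degscope.enrichment import (
    EnrichmentRun,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    significant_terms,
    term_percentage,
)
from degscope.go_annotations import AnnotationSet, propagate_annotations


def enumerate_upper_tail(k, n, K, N):
    """Oracle: count draws of size n with >= k marked items, exhaustively.

    Items 0..K-1 are marked; every C(N, n) subset is enumerated.
    """
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for item in draw if item < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpperTail:
    def test_zero_successes_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_fully_annotated_population_gives_one(self):
        assert hypergeom_upper_tail(3, 3, 5, 5) == 1.0

    def test_small_case_equals_enumeration(self):
        # N=10, K=4, n=5, k=3: 11/42 by exhaustive enumeration of all 252 draws
        expected = enumerate_upper_tail(3, 5, 4, 10)
        assert expected == pytest.approx(11 / 42)
        assert hypergeom_upper_tail(3, 5, 4, 10) == pytest.approx(expected, abs=1e-14)

    def test_matches_scipy_survival_function(self):
        """Independent cross-check against scipy's hypergeometric tail."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            ours = hypergeom_upper_tail(k, n, K, N)
            ref = hypergeom.sf(k - 1, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 4, 10)  # k > n
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 3, 11, 10)  # K > N


def bh_oracle(p):
    """Step-up oracle straight from the definition: adj_(i) = min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
            ([0.3], [0.3]),
        ],
    )
    def test_known_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)
        assert bh_oracle(p) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), rtol=1e-12)

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def build_annotations(dag, mapping):
    return propagate_annotations(AnnotationSet(gene_to_terms=mapping), dag)


class TestEnrich:
    def test_concentrated_term_has_smallest_p(self, chain_dag):
        """A term carried by every study gene and nothing else wins its namespace."""
        universe = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(5)}
        mapping = {g: {"GO:0000003"} for g in study}
        # scatter an unrelated mid-level annotation over some background genes
        mapping.update({f"g{i}": {"GO:0000002"} for i in range(50, 80)})
        ann = build_annotations(chain_dag, mapping)
        run = enrich(study, "up", ann, chain_dag, universe)
        results = run.group("up", "biological_process")
        assert results[0].term_id == "GO:0000003"
        assert results[0].k == 5
        # direct hypergeometric evaluation over each tested term agrees
        for r in results:
            assert r.p_value == pytest.approx(
                hypergeom_upper_tail(r.k, r.n, r.K, r.N), rel=1e-12
            )

    def test_unannotated_study_yields_empty_groups(self, chain_dag, caplog):
        ann = build_annotations(chain_dag, {"g1": {"GO:0000003"}})
        with caplog.at_level("WARNING"):
            run = enrich({"gX"}, "up", ann, chain_dag, {"g1", "gX"})
        assert all(len(g) == 0 for g in run.groups.values())

    def test_study_equals_universe_gives_p_one(self, chain_dag):
        genes = {f"g{i}" for i in range(10)}
        ann = build_annotations(chain_dag, {g: {"GO:0000003"} for g in genes})
        run = enrich(genes, "down", ann, chain_dag, genes)
        for r in run.group("down", "biological_process"):
            assert r.p_value == pytest.approx(1.0)

    def test_requires_propagated_annotations(self, chain_dag):
        raw = AnnotationSet(gene_to_terms={"g1": {"GO:0000003"}})
        with pytest.raises(ValueError, match="propagated"):
            enrich({"g1"}, "up", raw, chain_dag, {"g1"})

    def test_study_must_be_subset_of_universe(self, chain_dag):
        ann = build_annotations(chain_dag, {"g1": {"GO:0000003"}})
        with pytest.raises(ValueError, match="subset"):
            enrich({"g2"}, "up", ann, chain_dag, {"g1"})

    def test_parent_dominance(self, chain_dag):
        """Under propagation an ancestor's k and K dominate its descendant's."""
        universe = {f"g{i}" for i in range(20)}
        mapping = {f"g{i}": {"GO:0000003"} for i in range(4)}
        mapping.update({f"g{i}": {"GO:0000002"} for i in range(4, 8)})
        ann = build_annotations(chain_dag, mapping)
        run = enrich(set(mapping), "up", ann, chain_dag, universe)
        by_id = {r.term_id: r for r in run.group("up", "biological_process")}
        assert by_id["GO:0000002"].k >= by_id["GO:0000003"].k
        assert by_id["GO:0000001"].K >= by_id["GO:0000002"].K >= by_id["GO:0000003"].K


class TestSignificantTermsAndPercent:
    def _run_with(self, fdr, fold):
        from degscope.enrichment import EnrichmentResult

        r = EnrichmentResult(
            term_id="GO:0000001", term_name="t", namespace="biological_process",
            direction="up", k=2, n=10, K=4, N=100, p_value=fdr / 2, fdr=fdr,
            fold=fold, percent=20.0,
        )
        return EnrichmentRun(groups={("up", "biological_process"): [r]}, alpha_fdr=0.05)

    @pytest.mark.parametrize(
        "fdr,fold,kept",
        [(0.001, 3.0, True), (0.2, 3.0, False), (0.01, 0.5, False)],
    )
    def test_filter_keeps_enriched_significant_only(self, fdr, fold, kept):
        filtered = significant_terms(self._run_with(fdr, fold))
        assert bool(filtered.group("up", "biological_process")) is kept

    @pytest.mark.parametrize("k,total,expected", [(4, 10, 40.0), (0, 7, 0.0), (9, 9, 100.0)])
    def test_term_percentage(self, k, total, expected):
        assert term_percentage(k, total) == expected

    def test_term_percentage_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            term_percentage(1, 0)
        with pytest.raises(ValueError):
            term_percentage(5, 4)
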