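"""The over-representation statistic, Bonferroni correction, and bootstrap null."""

import itertools

import pytest

from clannot import (
    AnnotationRecord,
    Cluster,
    Namespace,
    TermCatalog,
    bonferroni,
    bootstrap_null,
    hypergeom_tail,
    validate_cluster,
)


def enumerated_tail(k: int, n: int, K: int, N: int) -> float:
    """Oracle: P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    population = list(range(N))
    for draw in itertools.combinations(population, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 3, 5, 10) == 1.0

    def test_small_closed_forms(self):
        # C(2,2)C(2,0)/C(4,2) = 1/6 ; all-three-of-three out of ten: 1/C(10,3)
        assert hypergeom_tail(2, 2, 2, 4) == pytest.approx(1 / 6)
        assert hypergeom_tail(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_agrees_with_enumeration_small_grid(self):
        for N in range(1, 9):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(n, K) + 1):
                        assert hypergeom_tail(k, n, K, N) == pytest.approx(
                            enumerated_tail(k, n, K, N), abs=1e-12
                        ), (k, n, K, N)

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_tail(k, 6, 5, 12) for k in range(6)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_background_and_bad_args_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            hypergeom_tail(0, 0, 0, 0)
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_tail(3, 2, 5, 10)  # k > n


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.005, 3, 0.015), (0.5, 10, 1.0), (0.123, 1, 0.123)]
    )
    def test_correction(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def make_cluster(member_terms: dict[str, list[str]], ns=Namespace.MFO) -> Cluster:
    cl = Cluster(id="C1", members=frozenset(member_terms))
    counts: dict = {}
    annotated = set()
    for member, terms in member_terms.items():
        for t in terms:
            counts[(ns, t)] = counts.get((ns, t), 0) + 1
        if terms:
            annotated.add(member)
    cl.term_counts = counts
    cl.n_annotated = {ns: len(annotated)} if annotated else {}
    return cl


class TestValidateCluster:
    def test_strong_enrichment_validated(self):
        # 5 members all carrying GO:1; the term occurs 5 times in a background of 100
        cl = make_cluster({f"s{i}": ["GO:1"] for i in range(5)})
        cat = TermCatalog(Namespace.MFO, N=100, K={"GO:1": 5})
        (v,) = validate_cluster(cl, cat)
        assert v.p_raw == pytest.approx(1 / 75287520, rel=1e-9)  # 1 / C(100,5)
        assert v.p_corrected == v.p_raw and v.validated

    def test_common_term_not_validated(self):
        # one of two annotated members carries a term present in half the background
        cl = make_cluster({"a": ["GO:2"], "b": ["GO:3"]})
        cat = TermCatalog(Namespace.MFO, N=100, K={"GO:2": 50, "GO:3": 50})
        v = {x.term_id: x for x in validate_cluster(cl, cat)}
        # P(X >= 1), n=2, K=50, N=100 = 1 - C(50,2)/C(100,2)
        assert v["GO:2"].p_raw == pytest.approx(0.7525252525, rel=1e-9)
        assert v["GO:2"].p_corrected == 1.0  # min(1, 2 * 0.7525)
        assert not v["GO:2"].validated

    def test_bonferroni_factor_is_terms_in_cluster(self):
        cl = make_cluster({"a": ["GO:1", "GO:2", "GO:3"], "b": ["GO:1"]})
        cat = TermCatalog(Namespace.MFO, N=50, K={"GO:1": 2, "GO:2": 10, "GO:3": 10})
        vals = validate_cluster(cl, cat)
        assert all(v.p_corrected == pytest.approx(min(1.0, 3 * v.p_raw)) for v in vals)

    def test_no_terms_in_namespace_gives_empty_list(self):
        cl = make_cluster({"a": ["GO:1"]})
        assert validate_cluster(cl, TermCatalog(Namespace.PFAM, N=10, K={"PF1": 3})) == []

    def test_term_missing_from_background_raises(self):
        cl = make_cluster({"a": ["GO:1"], "b": ["GO:1"]})
        cat = TermCatalog(Namespace.MFO, N=10, K={"GO:9": 3})
        with pytest.raises(ValueError, match="missing from MFO background"):
            validate_cluster(cl, cat)

    def test_invariants_on_outputs(self):
        cl = make_cluster({"a": ["GO:1", "GO:2"], "b": ["GO:1"], "c": []})
        cat = TermCatalog(Namespace.MFO, N=30, K={"GO:1": 4, "GO:2": 15})
        for v in validate_cluster(cl, cat):
            assert v.k <= v.n <= v.N and v.k <= v.K <= v.N
            assert v.p_raw <= v.p_corrected <= 1.0
            assert v.validated == (v.p_corrected < 0.01)


def uniform_annotations(n_seqs=200, n_terms=10, rate=0.15, seed=11):
    import numpy as np

    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_seqs):
        for t in range(n_terms):
            if rng.random() < rate:
                recs.append(AnnotationRecord(f"s{i:03d}", f"GO:{t:07d}", Namespace.MFO))
    return recs


class TestBootstrapNull:
    def test_seeded_determinism(self):
        from clannot import background_counts

        ann = uniform_annotations()
        cat = background_counts(ann, Namespace.MFO)
        a = bootstrap_null(cat, ann, cluster_size=8, replicates=5, seed=3)
        b = bootstrap_null(cat, ann, cluster_size=8, replicates=5, seed=3)
        assert a.min_corrected_p == b.min_corrected_p
        c = bootstrap_null(cat, ann, cluster_size=8, replicates=5, seed=4)
        assert a.min_corrected_p != c.min_corrected_p

    def test_universal_term_gives_p_one(self):
        ann = [AnnotationRecord(f"s{i}", "GO:1", Namespace.MFO) for i in range(20)]
        from clannot import background_counts

        cat = background_counts(ann, Namespace.MFO)
        null = bootstrap_null(cat, ann, cluster_size=5, replicates=10, seed=0)
        assert all(p == 1.0 for p in null.min_corrected_p)
        assert null.null_validation_rate == 0.0

    def test_oversized_draw_rejected(self):
        ann = [AnnotationRecord("s0", "GO:1", Namespace.MFO)]
        from clannot import background_counts

        cat = background_counts(ann, Namespace.MFO)
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_null(cat, ann, cluster_size=2, replicates=1, seed=0)
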