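"""Alignment parsing, the identity/coverage edge rule, and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clannot import (
    AlignmentPair,
    FormatError,
    build_clusters,
    edge_filter,
    parse_alignment_table,
)


def row(q, s, pident, length, qs=1, qe=None, ss=1, se=None, evalue=1e-20, bits=100.0):
    qe = qe if qe is not None else length
    se = se if se is not None else length
    return f"{q}\t{s}\t{pident}\t{length}\t0\t0\t{qs}\t{qe}\t{ss}\t{se}\t{evalue}\t{bits}"


class TestParseAlignmentTable:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(row("A", "B", 40.0, 90, 1, 90, 1, 90) + "\n")
        (pair,) = parse_alignment_table(p, {"A": 100, "B": 100})
        assert pair.identity == pytest.approx(0.40)
        assert (pair.q_span, pair.s_span, pair.aln_length) == (90, 90, 90)

    def test_reverse_subject_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(row("A", "B", 50.0, 90, 1, 90, 90, 1) + "\n")
        (pair,) = parse_alignment_table(p, {"A": 100, "B": 100})
        assert pair.s_span == 90

    def test_best_hsp_kept(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            row("A", "B", 40.0, 90, evalue=1e-5) + "\n" + row("A", "B", 60.0, 95, evalue=1e-20) + "\n"
        )
        (pair,) = parse_alignment_table(p, {"A": 100, "B": 100})
        assert pair.evalue == 1e-20 and pair.identity == pytest.approx(0.60)

    def test_hsp_evalue_tie_broken_by_bitscore(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            row("A", "B", 40.0, 90, evalue=1e-5, bits=50.0) + "\n"
            + row("A", "B", 60.0, 95, evalue=1e-5, bits=90.0) + "\n"
        )
        (pair,) = parse_alignment_table(p, {"A": 100, "B": 100})
        assert pair.bitscore == 90.0

    def test_self_hits_dropped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(row("A", "A", 100.0, 100) + "\n")
        assert parse_alignment_table(p, {"A": 100}) == []

    def test_unknown_id_and_malformed_row_errors(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(row("A", "Z", 40.0, 90) + "\n")
        with pytest.raises(FormatError, match="'Z'"):
            parse_alignment_table(p, {"A": 100})
        p.write_text("A\tB\tnot_a_number\t90\t0\t0\t1\t90\t1\t90\t1e-5\t50\n")
        with pytest.raises(FormatError, match=":1:"):
            parse_alignment_table(p, {"A": 100, "B": 100})

    def test_optional_evalue_ceiling(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(row("A", "B", 90.0, 100, evalue=1.0) + "\n")
        assert parse_alignment_table(p, {"A": 100, "B": 100}, max_evalue=1e-3) == []


class TestEdgeFilter:
    @staticmethod
    def pair(identity, q_span, s_span, length=100):
        return AlignmentPair("A", "B", identity, max(q_span, s_span), q_span, s_span, 1e-20)

    @pytest.mark.parametrize(
        "identity,q_span,s_span,expected",
        [
            (0.40, 90, 90, True),    # both bounds exactly met, inclusive
            (0.399, 100, 100, False),  # identity just below
            (0.40, 89, 90, False),   # query coverage just below
            (0.40, 90, 89, False),   # subject coverage just below
            (0.95, 95, 80, False),   # symmetric rule: one side at 0.80
            (1.0, 100, 100, True),
        ],
    )
    def test_inclusive_boundaries_and_symmetric_coverage(
        self, identity, q_span, s_span, expected
    ):
        assert edge_filter(self.pair(identity, q_span, s_span), 100, 100) is expected

    def test_custom_thresholds(self):
        p = self.pair(0.45, 80, 80)
        assert not edge_filter(p, 100, 100)
        assert edge_filter(p, 100, 100, cov_min=0.70)


def brute_force_components(n_nodes: int, edges: set[tuple[int, int]]) -> set[frozenset[int]]:
    """Transitive closure by repeated boolean matrix multiplication."""
    reach = np.eye(n_nodes, dtype=bool)
    for a, b in edges:
        reach[a, b] = reach[b, a] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    return {frozenset(np.nonzero(reach[i])[0].tolist()) for i in range(n_nodes)}


def pairs_from_edges(edges, identity=0.9):
    return [
        AlignmentPair(f"n{a}", f"n{b}", identity, 100, 100, 100, 1e-30)
        for a, b in edges
    ]


class TestBuildClusters:
    LENGTHS = {f"n{i}": 100 for i in range(300)}

    def test_chain_component_and_singleton(self):
        pairs = pairs_from_edges([(0, 1), (1, 2)])
        clusters, singles = build_clusters(pairs, [f"n{i}" for i in range(4)], self.LENGTHS)
        assert [sorted(c.members) for c in clusters] == [["n0", "n1", "n2"]]
        assert singles == {"n3"}

    def test_no_passing_edges_all_singletons(self):
        pairs = pairs_from_edges([(0, 1)], identity=0.2)
        clusters, singles = build_clusters(pairs, ["n0", "n1"], self.LENGTHS)
        assert clusters == [] and singles == {"n0", "n1"}

    def test_one_passing_direction_creates_undirected_edge(self):
        # A->B fails coverage, B->A passes: the undirected link exists
        bad = AlignmentPair("n0", "n1", 0.9, 50, 50, 50, 1e-10)
        good = AlignmentPair("n1", "n0", 0.9, 100, 100, 100, 1e-30)
        clusters, singles = build_clusters([bad, good], ["n0", "n1"], self.LENGTHS)
        assert len(clusters) == 1 and singles == set()

    def test_deterministic_ids_sorted_by_size_then_member(self):
        pairs = pairs_from_edges([(5, 6), (0, 1), (1, 2)])
        clusters, _ = build_clusters(pairs, [f"n{i}" for i in range(7)], self.LENGTHS)
        assert [c.id for c in clusters] == ["C1", "C2"]
        assert sorted(clusters[0].members) == ["n0", "n1", "n2"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_components_match_brute_force_closure(self, data):
        n = data.draw(st.integers(min_value=2, max_value=40))
        edges = data.draw(
            st.sets(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] < e[1]
                ),
                max_size=2 * n,
            )
        )
        ids = [f"n{i}" for i in range(n)]
        clusters, singles = build_clusters(pairs_from_edges(edges), ids, self.LENGTHS)
        got = {frozenset(int(m[1:]) for m in c.members) for c in clusters}
        got |= {frozenset({int(s[1:])}) for s in singles}
        assert got == brute_force_components(n, edges)
        # partition property: disjoint and covering
        assert sum(len(c.members) for c in clusters) + len(singles) == n

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        ids = [f"n{i}" for i in range(30)]
        pairs = [
            AlignmentPair(
                f"n{a}", f"n{b}",
                identity=float(rng.uniform(0.2, 1.0)),
                aln_length=100,
                q_span=int(rng.integers(60, 101)),
                s_span=int(rng.integers(60, 101)),
                evalue=1e-10,
            )
            for a, b in rng.integers(0, 30, size=(80, 2))
            if a != b
        ]
        strict, s_sing = build_clusters(pairs, ids, self.LENGTHS, 0.40, 0.90)
        loose, l_sing = build_clusters(pairs, ids, self.LENGTHS, 0.40, 0.70)
        assert len(l_sing) <= len(s_sing)
        # every strict cluster is contained in some loose cluster
        for sc in strict:
            assert any(sc.members <= lc.members for lc in loose)
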