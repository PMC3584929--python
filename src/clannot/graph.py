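"""Similarity-graph construction and connected-component clustering.

Pairwise BLAST hits become undirected edges when the hit satisfies the
identity/coverage rule — sequence identity at least 40% over at least 90% of
each sequence's length by default — and clusters are the connected components
of size >= 2 of the resulting graph. Sequences with no passing edge are
singletons.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import networkx as nx

from .io import FormatError
from .types import AlignmentPair, Cluster

#: Default edge thresholds: identity >= 40% over >= 90% of both sequences.
DEFAULT_SI_MIN = 0.40
DEFAULT_COV_MIN = 0.90


def parse_alignment_table(
    path: str | os.PathLike,
    lengths: Mapping[str, int],
    max_evalue: float | None = None,
) -> list[AlignmentPair]:
    """Parse 12-column BLAST tabular (outfmt 6) hits.

    Percent identity is converted to a fraction; spans are computed from the
    start/end coordinates (subject coordinates may be reversed). Self-hits
    are dropped. Multiple HSPs for the same (query, subject) pair are reduced
    to the one with the lowest e-value (ties: highest bitscore, then first
    seen). ``max_evalue``, when given, drops hits above the ceiling before
    reduction.
    """
    best: dict[tuple[str, str], AlignmentPair] = {}
    order: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                query_id, subject_id = fields[0], fields[1]
                pident = float(fields[2])
                aln_length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from None
            if query_id == subject_id:
                continue
            for sid in (query_id, subject_id):
                if sid not in lengths:
                    raise FormatError(f"{path}:{lineno}: unknown sequence id {sid!r}")
            if max_evalue is not None and evalue > max_evalue:
                continue
            pair = AlignmentPair(
                query_id=query_id,
                subject_id=subject_id,
                identity=pident / 100.0,
                aln_length=aln_length,
                q_span=qend - qstart + 1,
                s_span=abs(send - sstart) + 1,
                evalue=evalue,
                bitscore=bitscore,
            )
            key = (query_id, subject_id)
            prev = best.get(key)
            if prev is None:
                best[key] = pair
                order.append(key)
            elif (pair.evalue, -pair.bitscore) < (prev.evalue, -prev.bitscore):
                best[key] = pair
    return [best[k] for k in order]


def edge_filter(
    pair: AlignmentPair,
    q_len: int,
    s_len: int,
    si_min: float = DEFAULT_SI_MIN,
    cov_min: float = DEFAULT_COV_MIN,
) -> bool:
    """True when the hit passes the identity/coverage rule (inclusive bounds).

    Coverage is enforced on both sequences: the aligned span must cover at
    least ``cov_min`` of the query length and of the subject length. This
    symmetric reading keeps clustered sequences at near-identical lengths.
    """
    return (
        pair.identity >= si_min
        and pair.q_span / q_len >= cov_min
        and pair.s_span / s_len >= cov_min
    )


def build_clusters(
    pairs: Iterable[AlignmentPair],
    all_ids: Iterable[str],
    lengths: Mapping[str, int],
    si_min: float = DEFAULT_SI_MIN,
    cov_min: float = DEFAULT_COV_MIN,
) -> tuple[list[Cluster], set[str]]:
    """Cluster sequences as connected components under the edge rule.

    A hit in either direction that passes :func:`edge_filter` creates the
    undirected edge. Components of size >= 2 become clusters; everything
    else is a singleton. Cluster ids are deterministic: ``C`` plus the
    zero-padded rank after sorting components by descending size, then by
    lexicographically smallest member.
    """
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for pair in pairs:
        if pair.query_id not in g or pair.subject_id not in g:
            raise FormatError(
                f"alignment references id outside the sequence universe: "
                f"{pair.query_id!r}/{pair.subject_id!r}"
            )
        if edge_filter(pair, lengths[pair.query_id], lengths[pair.subject_id], si_min, cov_min):
            g.add_edge(pair.query_id, pair.subject_id)

    components = [frozenset(c) for c in nx.connected_components(g) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), min(c)))
    width = max(1, len(str(len(components))))
    clusters = [
        Cluster(id=f"C{rank:0{width}d}", members=members)
        for rank, members in enumerate(components, start=1)
    ]
    clustered = set().union(*components) if components else set()
    singletons = set(g.nodes) - clustered
    return clusters, singletons
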