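"""Pooling of member annotations into clusters and background frequencies.

A cluster inherits every member's annotations: GO and Pfam terms are counted
per distinct member (the inputs to the over-representation test), PDB chains
become structural templates, and SCOP labels ride along as metadata. The
background for the test is the whole loaded sequence universe, clustered or
not, restricted per namespace to sequences with at least one term in it.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Mapping

from .types import (
    AnnotationRecord,
    Category,
    Cluster,
    FUNCTIONAL_NAMESPACES,
    GO_NAMESPACES,
    Namespace,
    TermCatalog,
)

logger = logging.getLogger(__name__)


def attach_annotations(
    clusters: list[Cluster], annotations: Iterable[AnnotationRecord]
) -> list[Cluster]:
    """Pool annotations into each cluster and classify it; returns the input list.

    ``term_counts[(ns, t)]`` is the number of distinct members carrying term
    ``t``; ``n_annotated[ns]`` the number of members with any term in ``ns``;
    ``templates`` the sorted (pdb_chain, member) pairs. Annotations of
    sequences in no cluster are ignored (a count is logged).
    """
    by_seq: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for rec in annotations:
        by_seq[rec.seq_id].append(rec)

    clustered_ids = set().union(*(cl.members for cl in clusters)) if clusters else set()
    n_outside = sum(1 for sid in by_seq if sid not in clustered_ids)
    if n_outside:
        logger.info("%d annotated sequences fall outside all clusters", n_outside)

    for cl in clusters:
        counts: dict[tuple[Namespace, str], int] = defaultdict(int)
        annotated: dict[Namespace, set[str]] = defaultdict(set)
        templates: list[tuple[str, str]] = []
        for member in cl.members:
            for rec in by_seq.get(member, ()):
                counts[(rec.namespace, rec.term_id)] += 1
                annotated[rec.namespace].add(member)
                if rec.namespace is Namespace.PDB:
                    templates.append((rec.term_id, member))
        cl.term_counts = dict(counts)
        cl.n_annotated = {ns: len(ids) for ns, ids in annotated.items()}
        cl.templates = sorted(templates)
        cl.category = classify_cluster(cl)
    return clusters


def background_counts(
    annotations: Iterable[AnnotationRecord], namespace: Namespace
) -> TermCatalog:
    """Background frequencies of one namespace over the whole loaded universe.

    ``N`` counts sequences with >= 1 annotation in the namespace; ``K[t]``
    counts sequences carrying each term. An empty namespace yields ``N = 0``
    (validation refuses it).
    """
    carriers: set[str] = set()
    K: dict[str, set[str]] = defaultdict(set)
    for rec in annotations:
        if rec.namespace is namespace:
            carriers.add(rec.seq_id)
            K[rec.term_id].add(rec.seq_id)
    return TermCatalog(namespace=namespace, N=len(carriers), K={t: len(s) for t, s in K.items()})


def classify_cluster(cluster: Cluster) -> Category:
    """Annotation category: PDB and/or functional (GO or Pfam) content.

    SCOP labels do not affect the category — a PDB cluster may carry them or
    not; only PDB presence and GO/Pfam presence are tested.
    """
    has_pdb = bool(cluster.templates) or any(
        ns is Namespace.PDB for ns, _ in cluster.term_counts
    )
    has_func = any(ns in FUNCTIONAL_NAMESPACES for ns, _ in cluster.term_counts)
    if has_pdb and has_func:
        return Category.PDB_AND_FUNC
    if has_pdb:
        return Category.PDB_ONLY
    if has_func:
        return Category.FUNC_ONLY
    return Category.NONE


def length_dispersion(cluster: Cluster, lengths: Mapping[str, int]) -> float:
    """Population standard deviation of member lengths, in residues."""
    try:
        vals = [lengths[m] for m in cluster.members]
    except KeyError as exc:
        raise KeyError(f"missing length for cluster member {exc.args[0]!r}") from None
    mean = sum(vals) / len(vals)
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))


def go_term_counts(cluster: Cluster) -> dict[str, int]:
    """Convenience: the cluster's GO term counts pooled across the three roots."""
    return {
        term: count
        for (ns, term), count in cluster.term_counts.items()
        if ns in GO_NAMESPACES
    }
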