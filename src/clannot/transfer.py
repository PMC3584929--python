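"""Annotation transfer to external query sequences.

A query maps into a cluster when one of its hits against the clustered
database passes the same identity/coverage rule used for clustering
(SI >= 40% over >= 90% of both sequences; a relaxed mode lowers coverage to
70%). The query then inherits the cluster's terms — validated ones with
their statistics, the rest flagged non-validated — and, when the cluster
carries PDB templates, a template report with a remote-homology flag at
query-to-template identity < 30%. A query whose best passing hit is a
singleton inherits only that singleton's own terms, never validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping

from .graph import DEFAULT_COV_MIN, DEFAULT_SI_MIN, edge_filter
from .io import FormatError
from .types import (
    AlignmentPair,
    Cluster,
    InheritedAnnotation,
    Namespace,
    SingletonSource,
    Source,
    TemplateHit,
    TermValidation,
)

RELAXED_COV_MIN = 0.70
REMOTE_IDENTITY = 0.30


@dataclass(frozen=True)
class QueryMapping:
    """Where a query landed: a cluster, a singleton, or nowhere (None kind)."""

    query_id: str
    kind: Source | None
    target_id: str | None  # cluster id or singleton seq id
    best_subject: str | None
    n_other_clusters: int = 0  # passing hits pointing at other clusters


def _passing_hits(
    query_id: str,
    hits: Iterable[AlignmentPair],
    lengths: Mapping[str, int],
    si_min: float,
    cov_min: float,
) -> list[AlignmentPair]:
    passing = []
    for hit in hits:
        if hit.query_id != query_id:
            continue
        if hit.subject_id not in lengths:
            raise FormatError(f"hit references unknown subject {hit.subject_id!r}")
        if hit.query_id not in lengths:
            raise FormatError(f"hit references unknown query {hit.query_id!r}")
        if edge_filter(hit, lengths[hit.query_id], lengths[hit.subject_id], si_min, cov_min):
            passing.append(hit)
    return passing


def map_query(
    query_id: str,
    hits: Iterable[AlignmentPair],
    lengths: Mapping[str, int],
    membership: Mapping[str, str],
    si_min: float = DEFAULT_SI_MIN,
    cov_min: float = DEFAULT_COV_MIN,
) -> QueryMapping:
    """Assign the query to the cluster (or singleton) of its best passing hit.

    Best hit: lowest e-value, ties broken by highest identity then
    lexicographic subject id. Subjects absent from ``membership`` are
    singletons. Returns a mapping with ``kind=None`` when no hit passes.
    """
    passing = _passing_hits(query_id, hits, lengths, si_min, cov_min)
    if not passing:
        return QueryMapping(query_id, None, None, None)
    best = min(passing, key=lambda h: (h.evalue, -h.identity, h.subject_id))
    clusters_hit = {membership[h.subject_id] for h in passing if h.subject_id in membership}
    if best.subject_id in membership:
        cluster_id = membership[best.subject_id]
        return QueryMapping(
            query_id, Source.CLUSTER, cluster_id, best.subject_id,
            n_other_clusters=len(clusters_hit - {cluster_id}),
        )
    return QueryMapping(
        query_id, Source.SINGLETON, best.subject_id, best.subject_id,
        n_other_clusters=len(clusters_hit),
    )


def map_query_relaxed(
    query_id: str,
    hits: Iterable[AlignmentPair],
    lengths: Mapping[str, int],
    membership: Mapping[str, str],
    si_min: float = DEFAULT_SI_MIN,
    cov_min: float = RELAXED_COV_MIN,
) -> QueryMapping:
    """Relaxed-coverage mapping: same contract with coverage >= 70%."""
    return map_query(query_id, hits, lengths, membership, si_min, cov_min)


def inherit(
    query_id: str,
    source: Cluster | SingletonSource,
    validations: Iterable[TermValidation] = (),
) -> list[InheritedAnnotation]:
    """Transfer the source's terms to the query.

    From a cluster, every pooled term is emitted with its validated flag and
    corrected P (terms of never-validated namespaces such as PDB/SCOP carry
    ``validated=False`` and no P). From a singleton, its own terms are
    emitted with ``validated=False`` and SINGLETON provenance. The source is
    never mutated.
    """
    out: list[InheritedAnnotation] = []
    if isinstance(source, SingletonSource):
        for ns, term in sorted(source.terms, key=lambda t: (t[0].value, t[1])):
            out.append(
                InheritedAnnotation(
                    query_id=query_id,
                    cluster_id=source.seq_id,
                    namespace=ns,
                    term_id=term,
                    validated=False,
                    p_corrected=None,
                    source=Source.SINGLETON,
                )
            )
        return out

    by_term: dict[tuple[Namespace, str], TermValidation] = {
        (v.namespace, v.term_id): v for v in validations if v.cluster_id == source.id
    }
    for ns, term in sorted(source.term_counts, key=lambda t: (t[0].value, t[1])):
        val = by_term.get((ns, term))
        out.append(
            InheritedAnnotation(
                query_id=query_id,
                cluster_id=source.id,
                namespace=ns,
                term_id=term,
                validated=val.validated if val else False,
                p_corrected=val.p_corrected if val else None,
                source=Source.CLUSTER,
            )
        )
    return out


def template_report(
    query_id: str,
    cluster: Cluster,
    hits: Iterable[AlignmentPair],
) -> list[TemplateHit]:
    """Report every template of the cluster with the query's identity to it.

    Identity comes from the query's direct hit to the template-carrying
    member when one exists; otherwise the query's best (highest-identity)
    hit into the cluster serves as a proxy, flagged as such. Remote homology
    is identity strictly below 0.30. Empty when the cluster has no templates.
    """
    if not cluster.templates:
        return []
    direct: dict[str, float] = {}
    best_in_cluster: float | None = None
    for hit in hits:
        if hit.query_id != query_id or hit.subject_id not in cluster.members:
            continue
        prev = direct.get(hit.subject_id)
        if prev is None or hit.identity > prev:
            direct[hit.subject_id] = hit.identity
        if best_in_cluster is None or hit.identity > best_in_cluster:
            best_in_cluster = hit.identity
    out: list[TemplateHit] = []
    for template_id, member_id in cluster.templates:
        if member_id in direct:
            identity, proxy = direct[member_id], False
        elif best_in_cluster is not None:
            identity, proxy = best_in_cluster, True
        else:
            continue  # query has no hit into this cluster at all
        out.append(
            TemplateHit(
                query_id=query_id,
                template_id=template_id,
                template_seq_id=member_id,
                identity_to_template=identity,
                remote=identity < REMOTE_IDENTITY,
                proxy=proxy,
            )
        )
    return out
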