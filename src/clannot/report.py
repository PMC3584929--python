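"""Summary views over a clustered, validated, transferred dataset.

Covers the standard readouts of the method: how many clusters carry a
validated term per namespace (and the histogram of minimum corrected P
behind that count), GO first-branch rollups and Pfam clan rollups of
transferred annotation split by organism group, and overall coverage
fractions (queries mapped, queries with validated terms, template and
remote-homology rates, cluster length dispersion).
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

from .annotate import length_dispersion
from .io import NO_CLAN, UNMAPPED
from .transfer import QueryMapping
from .types import (
    Cluster,
    GO_NAMESPACES,
    InheritedAnnotation,
    Namespace,
    TemplateHit,
    TermValidation,
)

UNKNOWN_GROUP = "UNKNOWN"


def min_corrected_p_per_cluster(
    validations: Iterable[TermValidation], namespace: Namespace
) -> dict[str, float]:
    """Each cluster's minimum Bonferroni-corrected P in one namespace."""
    best: dict[str, float] = {}
    for v in validations:
        if v.namespace is namespace:
            best[v.cluster_id] = min(best.get(v.cluster_id, 1.0), v.p_corrected)
    return best


def validation_curve(
    validations: Iterable[TermValidation],
    namespace: Namespace,
    bins: Sequence[float],
) -> list[int]:
    """Histogram of clusters over corrected-P bins (half-open [lo, hi)).

    Each cluster enters once, at its minimum corrected P in the namespace; a
    cluster is validated exactly when that minimum falls left of alpha.
    Returns one count per bin; values >= the last edge land in the last bin
    (the cap at 1.0 makes an inclusive top edge the natural convention).
    """
    mins = min_corrected_p_per_cluster(validations, namespace)
    counts = [0] * (len(bins) - 1)
    for p in mins.values():
        for i in range(len(bins) - 1):
            last = i == len(bins) - 2
            if bins[i] <= p < bins[i + 1] or (last and p == bins[i + 1]):
                counts[i] += 1
                break
    return counts


def rollup_go(
    inherited: Iterable[InheritedAnnotation],
    categories: Mapping[str, frozenset[str]],
    organism_groups: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], int]:
    """Count distinct sequences per (GO first-branch category, organism group).

    A sequence counts once per category it touches; multi-parent terms count
    in every category; terms absent from the mapping fall under UNMAPPED;
    queries without group metadata fall under UNKNOWN.
    """
    groups = organism_groups or {}
    seqs: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in inherited:
        if rec.namespace not in GO_NAMESPACES:
            continue
        group = groups.get(rec.query_id, UNKNOWN_GROUP)
        for cat in categories.get(rec.term_id, frozenset({UNMAPPED})):
            seqs[(cat, group)].add(rec.query_id)
    return {key: len(ids) for key, ids in seqs.items()}


def rollup_clans(
    inherited: Iterable[InheritedAnnotation],
    clan_map: Mapping[str, str],
) -> dict[str, int]:
    """Count distinct sequences per Pfam clan; unmapped Pfam ids under NO_CLAN."""
    seqs: dict[str, set[str]] = defaultdict(set)
    for rec in inherited:
        if rec.namespace is not Namespace.PFAM:
            continue
        clan = clan_map.get(rec.term_id, NO_CLAN)
        seqs[clan].add(rec.query_id)
    return {clan: len(ids) for clan, ids in seqs.items()}


def summarize(
    clusters: Sequence[Cluster],
    validations: Sequence[TermValidation],
    mappings: Sequence[QueryMapping],
    inherited: Sequence[InheritedAnnotation],
    template_hits: Sequence[TemplateHit] = (),
    lengths: Mapping[str, int] | None = None,
    alpha: float = 0.01,
) -> dict[str, float | int | dict[str, int]]:
    """Headline fractions of a full pipeline run.

    Reports the fraction of queries mapped (to a cluster or singleton), the
    fraction inheriting >= 1 validated term, per-namespace validated-cluster
    counts, template coverage among mapped queries, the remote fraction of
    template-bearing queries, and the fraction of clusters with length
    standard deviation <= 5 residues.
    """
    n_queries = len(mappings)
    mapped = [m for m in mappings if m.kind is not None]
    validated_queries = {r.query_id for r in inherited if r.validated}
    template_queries = {h.query_id for h in template_hits}
    remote_queries = {h.query_id for h in template_hits if h.remote}

    per_ns_validated: dict[str, int] = {}
    for ns in Namespace:
        clusters_with_terms = {v.cluster_id for v in validations if v.namespace is ns}
        if not clusters_with_terms:
            continue
        validated = {v.cluster_id for v in validations if v.namespace is ns and v.validated}
        per_ns_validated[ns.value] = len(validated)

    any_validated = {v.cluster_id for v in validations if v.validated}

    summary: dict[str, float | int | dict[str, int]] = {
        "n_queries": n_queries,
        "n_clusters": len(clusters),
        "fraction_queries_mapped": len(mapped) / n_queries if n_queries else 0.0,
        "fraction_queries_validated": (
            len(validated_queries) / n_queries if n_queries else 0.0
        ),
        "validated_clusters_per_namespace": per_ns_validated,
        "n_clusters_with_validated_term": len(any_validated),
        "fraction_mapped_with_template": (
            len(template_queries) / len(mapped) if mapped else 0.0
        ),
        "fraction_templates_remote": (
            len(remote_queries) / len(template_queries) if template_queries else 0.0
        ),
    }
    if lengths is not None and clusters:
        tight = sum(1 for cl in clusters if length_dispersion(cl, lengths) <= 5.0)
        summary["fraction_clusters_length_sd_le_5"] = tight / len(clusters)
    elif clusters:
        summary["fraction_clusters_length_sd_le_5"] = 0.0
    else:
        summary["fraction_clusters_length_sd_le_5"] = 0.0
    return summary
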