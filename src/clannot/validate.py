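"""Statistical validation of cluster terms.

Each GO/Pfam term pooled in a cluster is tested for over-representation
against the background frequency of the term with an exact hypergeometric
upper tail, Bonferroni-corrected over the distinct terms of the same
namespace in the cluster. A term is validated when the corrected P-value is
strictly below alpha (default 0.01). A bootstrap over random pseudo-clusters
drawn from the background provides the null distribution of the minimum
corrected P, supporting the threshold choice.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable

import numpy as np
from scipy.stats import hypergeom

from .types import (
    AnnotationRecord,
    Cluster,
    NullDistribution,
    TermCatalog,
    TermValidation,
)

DEFAULT_ALPHA = 0.01


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background population, K the background carriers of the term,
    n the draw (annotated cluster members), k the carriers observed in the
    draw. Exact survival function, evaluated in log space by scipy.
    """
    if N == 0:
        raise ValueError("empty background (N = 0)")
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    # scipy's parameterization: M=population, n=successes, N=draws
    return float(hypergeom.sf(k - 1, M=N, n=K, N=n))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected P-value: min(1, m * p_raw) over m tests."""
    if m < 1:
        raise ValueError(f"Bonferroni factor must be >= 1, got {m}")
    if not (0.0 < p_raw <= 1.0):
        raise ValueError(f"p_raw must be in (0, 1], got {p_raw}")
    return min(1.0, m * p_raw)


def validate_cluster(
    cluster: Cluster, catalog: TermCatalog, alpha: float = DEFAULT_ALPHA
) -> list[TermValidation]:
    """Test every term of the catalog's namespace present in the cluster.

    The draw size n is the number of cluster members with >= 1 annotation in
    the namespace; the Bonferroni factor m is the number of distinct terms of
    the namespace in the cluster. Returns one record per term, sorted by
    term id; empty when the cluster has no terms in the namespace.
    Raises when a cluster term is missing from the background catalog.
    """
    ns = catalog.namespace
    terms = sorted(
        (term, count) for (t_ns, term), count in cluster.term_counts.items() if t_ns is ns
    )
    if not terms:
        return []
    if catalog.N == 0:
        raise ValueError(f"empty background catalog for namespace {ns.value}")
    n = cluster.n_annotated.get(ns, 0)
    m = len(terms)
    out: list[TermValidation] = []
    for term, k in terms:
        if term not in catalog.K:
            raise ValueError(
                f"term {term!r} in cluster {cluster.id} missing from {ns.value} background"
            )
        K = catalog.K[term]
        p_raw = hypergeom_tail(k, n, K, catalog.N)
        p_corr = bonferroni(p_raw, m)
        out.append(
            TermValidation(
                cluster_id=cluster.id,
                namespace=ns,
                term_id=term,
                k=k,
                n=n,
                K=K,
                N=catalog.N,
                p_raw=p_raw,
                p_corrected=p_corr,
                validated=p_corr < alpha,
            )
        )
    return out


def validate_all(
    clusters: Iterable[Cluster],
    catalogs: Iterable[TermCatalog],
    alpha: float = DEFAULT_ALPHA,
) -> list[TermValidation]:
    """Validate every cluster against every (non-empty) namespace catalog."""
    out: list[TermValidation] = []
    for cluster in clusters:
        for catalog in catalogs:
            if catalog.N == 0:
                continue
            out.extend(validate_cluster(cluster, catalog, alpha))
    return out


def bootstrap_null(
    catalog: TermCatalog,
    annotations: Iterable[AnnotationRecord],
    cluster_size: int,
    replicates: int,
    seed: int,
    alpha: float = DEFAULT_ALPHA,
) -> NullDistribution:
    """Null distribution of the minimum corrected P over random pseudo-clusters.

    Each replicate draws ``cluster_size`` sequences uniformly without
    replacement from the annotated background of the catalog's namespace,
    keeping each sequence's full term set (term co-occurrence is part of the
    null), validates the pseudo-cluster, and records its minimum corrected P
    (1.0 when the draw carries no terms — impossible here since every drawn
    sequence is annotated). Deterministic under ``seed``.
    """
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ns = catalog.namespace
    terms_by_seq: dict[str, list[str]] = defaultdict(list)
    for rec in annotations:
        if rec.namespace is ns:
            terms_by_seq[rec.seq_id].append(rec.term_id)
    universe = sorted(terms_by_seq)
    if cluster_size > len(universe):
        raise ValueError(
            f"cluster_size {cluster_size} exceeds the {len(universe)} annotated sequences"
        )
    rng = np.random.default_rng(seed)
    mins: list[float] = []
    for _ in range(replicates):
        draw = rng.choice(len(universe), size=cluster_size, replace=False)
        counts: dict[tuple, int] = defaultdict(int)
        for idx in draw:
            for term in terms_by_seq[universe[idx]]:
                counts[(ns, term)] += 1
        pseudo = Cluster(
            id="BOOT",
            members=frozenset(universe[i] for i in draw),
            term_counts=dict(counts),
            n_annotated={ns: cluster_size},
        )
        validations = validate_cluster(pseudo, catalog, alpha)
        mins.append(min((v.p_corrected for v in validations), default=1.0))
    return NullDistribution(
        namespace=ns,
        cluster_size=cluster_size,
        replicates=replicates,
        min_corrected_p=tuple(mins),
        seed=seed,
        alpha=alpha,
    )
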