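"""Statistically validate GO/Pfam terms pooled within clusters.

Each term's over-representation is tested with an exact hypergeometric upper
tail against the background frequency over all loaded sequences, Bonferroni-
corrected over the terms of the same namespace in the cluster, and validated
at corrected P < 0.01. A bootstrap over random pseudo-clusters shows the
threshold is conservative under the null.
"""

from clannot import Namespace, bootstrap_null, generate_world, run_pipeline

world = generate_world(n_families=5, members_per_family=6, n_decoys=40, seed=42)
res = run_pipeline(world.sequences, world.alignment_rows, world.annotations)

print(f"{len(res.validations)} term tests across {len(res.clusters)} clusters")
for v in res.validations[:6]:
    flag = "validated" if v.validated else "not validated"
    print(
        f"  {v.cluster_id} {v.namespace.value} {v.term_id}: "
        f"k={v.k}/{v.n}, background {v.K}/{v.N}, "
        f"corrected P = {v.p_corrected:.2e} -> {flag}"
    )
# Planted family terms reach tiny corrected P (nearly all members carry them,
# the background rarely does); decoy terms carried at random stay above 0.01.

null = bootstrap_null(
    res.catalogs["MFO"], world.annotations, cluster_size=6, replicates=200, seed=0
)
print(f"bootstrap null validation rate (random size-6 clusters): "
      f"{null.null_validation_rate:.3f}")
# Under random membership almost no pseudo-cluster yields a corrected P below
# 0.01 — the empirical support for using that threshold.
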