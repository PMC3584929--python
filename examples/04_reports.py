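"""Summary reports: validation curve, GO first-branch and Pfam clan rollups.

Reproduces the standard readouts on synthetic data: the histogram of
clusters over corrected P (everything left of 0.01 is validated), rollups of
transferred annotation by GO first-branch category and Pfam clan, and the
headline coverage fractions.
"""

from clannot import (
    InheritedAnnotation,
    Namespace,
    Source,
    generate_world,
    rollup_clans,
    rollup_go,
    run_pipeline,
    validation_curve,
)

world = generate_world(n_families=5, members_per_family=6, n_decoys=40, seed=42)
res = run_pipeline(world.sequences, world.alignment_rows, world.annotations)

bins = [0.0, 1e-6, 1e-3, 0.01, 0.1, 1.0]
counts = validation_curve(res.validations, Namespace.MFO, bins)
print("clusters per corrected-P bin (MFO):")
for (lo, hi), c in zip(zip(bins, bins[1:]), counts):
    marker = " <- validated side" if hi <= 0.01 and c else ""
    print(f"  [{lo:g}, {hi:g}): {c}{marker}")

# pretend every validated term was transferred to one query per cluster
inherited = [
    InheritedAnnotation(f"query_{v.cluster_id}", v.cluster_id, v.namespace,
                        v.term_id, v.validated, v.p_corrected, Source.CLUSTER)
    for v in res.validations if v.validated
]
categories = {t: frozenset({"binding"}) for fam in world.planted_terms
              for ns, t in fam if ns == "MFO"}
groups = {f"query_{cl.id}": "EUKARYOTE" for cl in res.clusters}
print("GO rollup:", rollup_go(inherited, categories, groups))
clan_map = {t: "CL0023" for fam in world.planted_terms for ns, t in fam if ns == "PFAM"}
print("clan rollup:", rollup_clans(inherited, clan_map))
# Counts are distinct sequences per category/clan; a sequence with two Pfam
# terms of the same clan counts once.
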