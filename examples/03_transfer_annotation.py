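"""Transfer validated annotation and templates to a query sequence.

A query maps into a cluster when one of its hits passes the same
SI >= 40% / Cov >= 90% rule; it then inherits the cluster's terms with their
validation status, and a template report flags remote homology when the
query-to-template identity is below 30%.
"""

from clannot import (
    AnnotationRecord,
    Namespace,
    SequenceRecord,
    generate_world,
    inherit,
    map_query,
    map_query_relaxed,
    parse_rows,
    run_pipeline,
    template_report,
)
from clannot.simulate import _row

world = generate_world(n_families=5, members_per_family=6, n_decoys=40, seed=42)
# give the first family a PDB template on its first member
annotations = world.annotations + [
    AnnotationRecord(world.families[0][0], "1abc_A", Namespace.PDB)
]
res = run_pipeline(world.sequences, world.alignment_rows, annotations)
membership = res.membership

# the query hits one ordinary member closely and the template member remotely
anchor, template_member = world.families[0][1], world.families[0][0]
by_id = {r.id: r for r in world.sequences}
query = SequenceRecord("QUERY1", by_id[anchor].sequence)
rows = [
    _row(query, by_id[anchor], 0.62, query.length),
    _row(query, by_id[template_member], 0.25, query.length),
]
lengths = world.lengths | {query.id: query.length}
hits = parse_rows(rows, lengths)

mapping = map_query(query.id, hits, lengths, membership)
print(f"query maps to {mapping.target_id} via {mapping.best_subject} ({mapping.kind.value})")

cluster = next(cl for cl in res.clusters if cl.id == mapping.target_id)
for rec in inherit(query.id, cluster, res.validations):
    p = "-" if rec.p_corrected is None else f"{rec.p_corrected:.1e}"
    print(f"  inherits {rec.namespace.value} {rec.term_id}: "
          f"validated={rec.validated}, corrected P={p}")
for th in template_report(query.id, cluster, hits):
    print(f"  template {th.template_id} (member {th.template_seq_id}): "
          f"identity {th.identity_to_template:.2f}, remote={th.remote}")
# The query inherits the cluster's validated terms through its close hit even
# though it shares only 25% identity with the structural template — a
# remote-homology structural assignment.

relaxed = map_query_relaxed(query.id, hits, lengths, membership)
print(f"relaxed coverage (>= 70%) maps to: {relaxed.target_id}")
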