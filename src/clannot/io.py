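"""Readers and writers for the external formats the pipeline consumes.

Sequences arrive as FASTA; annotations as a 3-column TSV
(``seq_id<TAB>term_id<TAB>namespace``), with a thin GAF convenience reader;
the GO graph as OBO (``is_a`` edges only are used); Pfam clan membership as a
2-column TSV. All outputs are plain TSV written with fixed formatting so that
identical inputs give byte-identical files.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AnnotationRecord,
    Cluster,
    InheritedAnnotation,
    Namespace,
    SequenceRecord,
    TemplateHit,
    TermValidation,
)

UNMAPPED = "UNMAPPED"
NO_CLAN = "NO_CLAN"


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`FormatError` on an empty file, a non-FASTA first byte, or
    a duplicate id.
    """
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FormatError(f"{path}: no sequences (empty file)")
        if first != ">":
            raise FormatError(f"{path}: not FASTA (first byte {first!r}, expected '>')")
        handle.seek(0)
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA (60-column wrapped); round-trips with read_fasta."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta")


# ---------------------------------------------------------------------------
# annotations


def _check_term_namespace(term_id: str, ns: Namespace, where: str) -> None:
    if term_id.startswith("GO:") and ns not in (Namespace.MFO, Namespace.BPO, Namespace.CCO):
        raise FormatError(f"{where}: GO term {term_id} under non-GO namespace {ns.value}")
    if term_id.startswith("PF") and term_id[2:7].isdigit() and ns is not Namespace.PFAM:
        raise FormatError(f"{where}: Pfam term {term_id} under namespace {ns.value}")


def read_annotations(path: str | os.PathLike) -> list[AnnotationRecord]:
    """Read the 3-column annotation TSV; '#' lines skipped, duplicates collapsed.

    Raises :class:`FormatError` (with the line number) on an unknown
    namespace token or a GO/Pfam id filed under the wrong namespace.
    """
    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            seq_id, term_id, ns_token = fields[0], fields[1], fields[2]
            try:
                ns = Namespace(ns_token)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown namespace {ns_token!r}"
                ) from None
            _check_term_namespace(term_id, ns, f"{path}:{lineno}")
            if (seq_id, term_id) in seen:
                continue
            seen.add((seq_id, term_id))
            out.append(AnnotationRecord(seq_id=seq_id, term_id=term_id, namespace=ns))
    return out


def write_annotations(records: Iterable[AnnotationRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(f"{r.seq_id}\t{r.term_id}\t{r.namespace.value}\n")


_GAF_ASPECT = {"F": Namespace.MFO, "P": Namespace.BPO, "C": Namespace.CCO}


def read_gaf(path: str | os.PathLike) -> list[AnnotationRecord]:
    """Convenience reader for GAF 2.x: keeps object id, GO id and aspect only.

    Evidence codes and qualifiers are ignored; duplicates collapsed.
    """
    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GAF row has {len(fields)} columns, need >=9")
            seq_id, term_id, aspect = fields[1], fields[4], fields[8]
            if aspect not in _GAF_ASPECT:
                raise FormatError(f"{path}:{lineno}: unknown GAF aspect {aspect!r}")
            if (seq_id, term_id) in seen:
                continue
            seen.add((seq_id, term_id))
            out.append(AnnotationRecord(seq_id, term_id, _GAF_ASPECT[aspect]))
    return out


# ---------------------------------------------------------------------------
# GO ontology


def _isa_graph(obo_path: str | os.PathLike) -> nx.DiGraph:
    multi = obonet.read_obo(obo_path)
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"{obo_path}: cyclic is_a relation involving {cycle[0][0]}")
    return g


def load_go_categories(obo_path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Map every ontology term to its first-branch categories.

    A first branch is a depth-1 child of a root (a node with no ``is_a``
    parent) on some ``is_a`` path. Multi-parent terms map to every first
    branch they reach; roots map to themselves. Terms not in the returned
    map should be reported under the :data:`UNMAPPED` sentinel.
    """
    g = _isa_graph(obo_path)  # edges child -> parent
    roots = {n for n in g.nodes if g.out_degree(n) == 0}
    first_branches = {n for n in g.nodes if any(p in roots for p in g.successors(n))}
    mapping: dict[str, frozenset[str]] = {}
    for term in g.nodes:
        if term in roots:
            mapping[term] = frozenset({term})
            continue
        ancestors = nx.descendants(g, term) | {term}  # is_a ancestors incl. self
        cats = frozenset(a for a in ancestors if a in first_branches)
        mapping[term] = cats if cats else frozenset({UNMAPPED})
    return mapping


def load_go_ancestors(obo_path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Map every term to its full set of ``is_a`` ancestors (excluding itself).

    Used by the optional GO ancestor-propagation mode before term counting.
    """
    g = _isa_graph(obo_path)
    return {term: frozenset(nx.descendants(g, term)) for term in g.nodes}


def propagate_go(
    annotations: Iterable[AnnotationRecord],
    ancestors: Mapping[str, frozenset[str]],
) -> list[AnnotationRecord]:
    """Add every is_a ancestor of each GO annotation, preserving the namespace.

    Non-GO records pass through unchanged; duplicates are collapsed.
    """
    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in annotations:
        terms = [rec.term_id]
        if rec.namespace in (Namespace.MFO, Namespace.BPO, Namespace.CCO):
            terms.extend(sorted(ancestors.get(rec.term_id, ())))
        for t in terms:
            if (rec.seq_id, t) in seen:
                continue
            seen.add((rec.seq_id, t))
            out.append(AnnotationRecord(rec.seq_id, t, rec.namespace))
    return out


# ---------------------------------------------------------------------------
# Pfam clans


def read_clan_map(path: str | os.PathLike) -> dict[str, str]:
    """Read the 2-column ``pfam_id<TAB>clan_id`` table.

    Raises :class:`FormatError` when the same Pfam id is assigned two clans.
    Pfam ids absent from the map roll up to :data:`NO_CLAN` downstream.
    """
    clan_map: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pfam_id, clan_id = fields[0], fields[1]
            if pfam_id in clan_map and clan_map[pfam_id] != clan_id:
                raise FormatError(
                    f"{path}:{lineno}: conflicting clan for {pfam_id}: "
                    f"{clan_map[pfam_id]} vs {clan_id}"
                )
            clan_map[pfam_id] = clan_id
    return clan_map


# ---------------------------------------------------------------------------
# TSV writers for pipeline outputs


def write_membership_tsv(clusters: Iterable[Cluster], path: str | os.PathLike) -> None:
    """Write ``cluster_id<TAB>seq_id`` membership rows in deterministic order."""
    with open(path, "w") as handle:
        for cl in clusters:
            for member in sorted(cl.members):
                handle.write(f"{cl.id}\t{member}\n")


def read_membership_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read membership rows back as a seq_id -> cluster_id map."""
    membership: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            cluster_id, seq_id = line.split("\t")[:2]
            membership[seq_id] = cluster_id
    return membership


def write_singletons(singletons: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for seq_id in sorted(singletons):
            handle.write(f"{seq_id}\n")


def write_validations_tsv(
    validations: Iterable[TermValidation], path: str | os.PathLike
) -> None:
    with open(path, "w") as handle:
        handle.write(
            "cluster_id\tnamespace\tterm_id\tk\tn\tK\tN\tp_raw\tp_corrected\tvalidated\n"
        )
        for v in validations:
            handle.write(
                f"{v.cluster_id}\t{v.namespace.value}\t{v.term_id}\t{v.k}\t{v.n}"
                f"\t{v.K}\t{v.N}\t{v.p_raw:.6e}\t{v.p_corrected:.6e}\t{int(v.validated)}\n"
            )


def read_validations_tsv(path: str | os.PathLike) -> list[TermValidation]:
    out: list[TermValidation] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("cluster_id\t"):
            raise FormatError(f"{path}: missing validation header")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            out.append(
                TermValidation(
                    cluster_id=f[0],
                    namespace=Namespace(f[1]),
                    term_id=f[2],
                    k=int(f[3]),
                    n=int(f[4]),
                    K=int(f[5]),
                    N=int(f[6]),
                    p_raw=float(f[7]),
                    p_corrected=float(f[8]),
                    validated=bool(int(f[9])),
                )
            )
    return out


def write_inherited_tsv(
    inherited: Iterable[InheritedAnnotation], path: str | os.PathLike
) -> None:
    with open(path, "w") as handle:
        handle.write("query_id\tcluster_id\tnamespace\tterm_id\tvalidated\tp_corrected\tsource\n")
        for r in inherited:
            p = "NA" if r.p_corrected is None else f"{r.p_corrected:.6e}"
            handle.write(
                f"{r.query_id}\t{r.cluster_id}\t{r.namespace.value}\t{r.term_id}"
                f"\t{int(r.validated)}\t{p}\t{r.source.value}\n"
            )


def write_templates_tsv(hits: Iterable[TemplateHit], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("query_id\ttemplate_id\ttemplate_seq_id\tidentity\tremote\tproxy\n")
        for h in hits:
            handle.write(
                f"{h.query_id}\t{h.template_id}\t{h.template_seq_id}"
                f"\t{h.identity_to_template:.4f}\t{int(h.remote)}\t{int(h.proxy)}\n"
            )


def write_cluster_summary_tsv(
    clusters: Iterable[Cluster],
    length_sds: Mapping[str, float],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tsize\tcategory\tn_templates\tlength_sd\n")
        for cl in clusters:
            handle.write(
                f"{cl.id}\t{cl.size}\t{cl.category.value}\t{len(cl.templates)}"
                f"\t{length_sds[cl.id]:.4f}\n"
            )


def write_term_counts_tsv(clusters: Iterable[Cluster], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tnamespace\tterm_id\tcount\n")
        for cl in clusters:
            for (ns, term), count in sorted(
                cl.term_counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
            ):
                handle.write(f"{cl.id}\t{ns.value}\t{term}\t{count}\n")
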