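"""Self-contained synthetic test worlds.

Generates protein families by independent substitution from a random
ancestor (so member-to-ancestor identity is the controlled quantity and
member-to-member identity follows t**2 + (1-t)**2/19 per position), plants
enriched GO/Pfam terms on family members over a uniform decoy-term
background, and emits the matching all-against-all alignment table with the
TRUE fraction of identical positions — no aligner needed because the
no-indel model keeps positions aligned by construction.
"""

from __future__ import annotations

import json
import math
import os
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationRecord, FamilySpec, Namespace, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Minimum true identity at which a cross-family or decoy pair is written to
#: the alignment table (below-threshold noise edges for filter testing).
NOISE_IDENTITY_MIN = 0.25

#: Probability that a family member actually carries each planted term.
PLANT_CARRIER_PROB = 0.9


def expected_member_identity(target_identity: float) -> float:
    """Expected member-to-member identity under the substitution model.

    Each member mutates each position independently with probability
    1 - t to one of the 19 other residues, so two members match at a
    position with probability t**2 + (1 - t)**2 / 19.
    """
    t = target_identity
    return t * t + (1.0 - t) ** 2 / 19.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def simulate_family(
    spec: FamilySpec, seed: int, id_prefix: str = "FAM"
) -> list[SequenceRecord]:
    """Draw a random ancestor and mutate each member independently from it.

    Each position substitutes with probability 1 - target_identity to a
    uniformly chosen different residue. Deterministic under ``seed``.
    """
    if not (0.0 < spec.target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    if spec.ancestor_length < 10:
        raise ValueError("ancestor_length must be >= 10 (identity estimates unstable)")
    if spec.indel_rate != 0.0:
        raise ValueError("indel_rate > 0 is not supported by the exact-row emitter")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_AA_CODES, size=spec.ancestor_length)
    members: list[SequenceRecord] = []
    for i in range(spec.n_members):
        seq = ancestor.copy()
        mutate = rng.random(spec.ancestor_length) < (1.0 - spec.target_identity)
        n_mut = int(mutate.sum())
        if n_mut:
            # draw from the 19 residues different from the current one
            offsets = rng.integers(1, len(_AA_CODES), size=n_mut)
            current_idx = np.searchsorted(_AA_CODES, seq[mutate])
            seq[mutate] = _AA_CODES[(current_idx + offsets) % len(_AA_CODES)]
        members.append(
            SequenceRecord(id=f"{id_prefix}_{i:03d}", sequence=seq.tobytes().decode())
        )
    return members


def simulate_decoys(
    n: int, length: int, seed: int, id_prefix: str = "DEC", length_jitter: int = 0
) -> list[SequenceRecord]:
    """Unrelated random sequences; lengths uniform in length +/- jitter."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = length if length_jitter == 0 else int(rng.integers(length - length_jitter, length + length_jitter + 1))
        seq = rng.choice(_AA_CODES, size=L)
        out.append(SequenceRecord(id=f"{id_prefix}_{i:04d}", sequence=seq.tobytes().decode()))
    return out


def _true_identity(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Fraction of identical positions over the ungapped overlap (min length)."""
    L = min(len(a), len(b))
    matches = int((a[:L] == b[:L]).sum())
    return matches / L, L


def _row(
    q: SequenceRecord, s: SequenceRecord, identity: float, aln_len: int
) -> str:
    mismatch = aln_len - round(identity * aln_len)
    # synthetic e-value, strictly decreasing in identity and length
    log10_e = -max(0.0, identity - 0.20) * aln_len / 2.0
    evalue = 10.0 ** max(log10_e, -180.0)
    bitscore = round(2.0 * identity * aln_len, 1)
    return (
        f"{q.id}\t{s.id}\t{identity * 100:.2f}\t{aln_len}\t{mismatch}\t0"
        f"\t1\t{aln_len}\t1\t{aln_len}\t{evalue:.3e}\t{bitscore}"
    )


def emit_alignment_table(
    families: Sequence[Sequence[SequenceRecord]],
    decoys: Sequence[SequenceRecord] = (),
) -> list[str]:
    """Exact 12-column alignment rows for the synthetic world.

    Every intra-family pair gets one row (one direction) with its true
    identity over the full length. Cross-family and decoy pairs appear only
    when their true identity reaches ``NOISE_IDENTITY_MIN`` — noise edges
    that exercise the edge filter without joining families.
    """
    rows: list[str] = []
    for fam in families:
        enc = [_encode(r.sequence) for r in fam]
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                identity, L = _true_identity(enc[i], enc[j])
                rows.append(_row(fam[i], fam[j], identity, L))

    # cross pairs: family vs other-family/decoy members, vectorized by length
    others: list[SequenceRecord] = [r for fam in families for r in fam] + list(decoys)
    fam_index: dict[str, int] = {}
    for fid, fam in enumerate(families):
        for r in fam:
            fam_index[r.id] = fid
    by_len: dict[int, list[int]] = {}
    for idx, r in enumerate(others):
        by_len.setdefault(r.length, []).append(idx)
    enc_all = [_encode(r.sequence) for r in others]

    for L, idxs in sorted(by_len.items()):
        if len(idxs) < 2:
            continue
        mat = np.stack([enc_all[i] for i in idxs])
        n = len(idxs)
        chunk = max(1, int(2e7) // (n * L) + 1)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            sims = (mat[start:stop, None, :] == mat[None, :, :]).mean(axis=2)
            for a in range(start, stop):
                ia = idxs[a]
                for b in np.nonzero(sims[a - start] >= NOISE_IDENTITY_MIN)[0]:
                    ib = idxs[int(b)]
                    if ib <= ia:
                        continue
                    fa, fb = fam_index.get(others[ia].id, -1 - ia), fam_index.get(
                        others[ib].id, -1 - ib
                    )
                    if fa == fb and fa >= 0:
                        continue  # intra-family rows already emitted exactly
                    rows.append(
                        _row(others[ia], others[ib], float(sims[a - start, int(b)]), L)
                    )
    return rows


def plant_annotations(
    families: Sequence[Sequence[SequenceRecord]],
    specs: Sequence[FamilySpec],
    decoys: Sequence[SequenceRecord],
    background_terms: int,
    background_rate: float,
    seed: int,
) -> list[AnnotationRecord]:
    """Planted enriched terms per family plus uniform decoy-term noise.

    Each family member carries each of its family's planted terms with
    probability ``PLANT_CARRIER_PROB``; every sequence (family member or
    decoy) carries each of the ``background_terms`` decoy terms independently
    with probability ``background_rate``. Decoy terms alternate between the
    MFO and PFAM namespaces. Deterministic under ``seed``.
    """
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError("background_rate must be in [0, 1]")
    if len(families) != len(specs):
        raise ValueError("one FamilySpec per family required")
    rng = np.random.default_rng(seed)
    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()

    planted_seen: set[tuple[Namespace, str]] = set()
    for fam, spec in zip(families, specs):
        for ns, term in spec.planted_terms:
            if (ns, term) in planted_seen:
                # shared planted term across families is allowed; background K
                # becomes the union count
                pass
            planted_seen.add((ns, term))
            for rec in fam:
                if rng.random() < PLANT_CARRIER_PROB:
                    if (rec.id, term) not in seen:
                        seen.add((rec.id, term))
                        out.append(AnnotationRecord(rec.id, term, ns))

    decoy_terms = [
        (Namespace.MFO, f"GO:99{i:05d}") if i % 2 == 0 else (Namespace.PFAM, f"PF99{i:03d}")
        for i in range(background_terms)
    ]
    everyone = [r for fam in families for r in fam] + list(decoys)
    for rec in everyone:
        hits = rng.random(background_terms) < background_rate
        for (ns, term), hit in zip(decoy_terms, hits):
            if hit and (rec.id, term) not in seen:
                seen.add((rec.id, term))
                out.append(AnnotationRecord(rec.id, term, ns))
    return out


@dataclass
class SyntheticWorld:
    """A complete generated dataset plus its ground truth."""

    sequences: list[SequenceRecord]
    alignment_rows: list[str]
    annotations: list[AnnotationRecord]
    families: list[list[str]] = field(default_factory=list)  # member ids per family
    planted_terms: list[list[tuple[str, str]]] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.sequences}

    def truth_json(self) -> str:
        return json.dumps(
            {
                "families": self.families,
                "planted_terms": [
                    [[ns, term] for ns, term in fam] for fam in self.planted_terms
                ],
            },
            indent=2,
            sort_keys=True,
        )


def generate_world(
    n_families: int = 50,
    members_per_family: int = 10,
    target_identity: float = 0.7,
    ancestor_length: int = 300,
    n_decoys: int = 1000,
    background_terms: int = 20,
    background_rate: float = 0.05,
    seed: int = 42,
) -> SyntheticWorld:
    """Generate the standard study conditions end to end.

    Defaults: 50 families of 10 members at ancestor identity 0.7 over 1000
    unrelated decoys, one planted GO (MFO) and one planted Pfam term per
    family, 20 uniform decoy terms at carrier rate 0.05.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_families + 2)
    specs, families = [], []
    for fid in range(n_families):
        spec = FamilySpec(
            n_members=members_per_family,
            ancestor_length=ancestor_length,
            target_identity=target_identity,
            planted_terms=(
                (Namespace.MFO, f"GO:00{fid:05d}"),
                (Namespace.PFAM, f"PF{fid:05d}"),
            ),
        )
        specs.append(spec)
        families.append(simulate_family(spec, int(child_seeds[fid]), id_prefix=f"F{fid:03d}"))
    decoys = simulate_decoys(
        n_decoys, ancestor_length, int(child_seeds[n_families]), length_jitter=ancestor_length // 5
    )
    rows = emit_alignment_table(families, decoys)
    annotations = plant_annotations(
        families, specs, decoys, background_terms, background_rate,
        int(child_seeds[n_families + 1]),
    )
    return SyntheticWorld(
        sequences=[r for fam in families for r in fam] + decoys,
        alignment_rows=rows,
        annotations=annotations,
        families=[[r.id for r in fam] for fam in families],
        planted_terms=[[(ns.value, t) for ns, t in s.planted_terms] for s in specs],
    )


def write_world(world: SyntheticWorld, outdir: str | os.PathLike) -> None:
    """Write FASTA, hits TSV, annotations TSV and truth JSON for a world."""
    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    _io.write_fasta(world.sequences, os.path.join(outdir, "sequences.fasta"))
    with open(os.path.join(outdir, "hits.tsv"), "w") as handle:
        for row in world.alignment_rows:
            handle.write(row + "\n")
    _io.write_annotations(world.annotations, os.path.join(outdir, "annotations.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w") as handle:
        handle.write(world.truth_json() + "\n")
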