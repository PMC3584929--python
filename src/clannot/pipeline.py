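"""One-call orchestration of the clustering + validation stages.

Convenience layer for in-memory runs (synthetic worlds, notebooks, the
examples). The CLI drives the same underlying functions file-to-file.
"""

from __future__ import annotations

import tempfile
import os
from dataclasses import dataclass
from collections.abc import Sequence

from .annotate import attach_annotations, background_counts
from .graph import DEFAULT_COV_MIN, DEFAULT_SI_MIN, build_clusters, parse_alignment_table
from .types import (
    AlignmentPair,
    AnnotationRecord,
    Cluster,
    FUNCTIONAL_NAMESPACES,
    SequenceRecord,
    TermCatalog,
    TermValidation,
)
from .validate import DEFAULT_ALPHA, validate_all


@dataclass
class PipelineResult:
    clusters: list[Cluster]
    singletons: set[str]
    catalogs: dict[str, TermCatalog]  # keyed by namespace value
    validations: list[TermValidation]
    pairs: list[AlignmentPair]

    @property
    def membership(self) -> dict[str, str]:
        return {m: cl.id for cl in self.clusters for m in cl.members}


def parse_rows(rows: Sequence[str], lengths: dict[str, int]) -> list[AlignmentPair]:
    """Parse in-memory 12-column alignment rows through the table parser."""
    fd, path = tempfile.mkstemp(suffix=".tsv")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write("\n".join(rows) + ("\n" if rows else ""))
        return parse_alignment_table(path, lengths)
    finally:
        os.unlink(path)


def run_pipeline(
    sequences: Sequence[SequenceRecord],
    alignment_rows: Sequence[str],
    annotations: Sequence[AnnotationRecord],
    si_min: float = DEFAULT_SI_MIN,
    cov_min: float = DEFAULT_COV_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> PipelineResult:
    """Cluster, pool annotations, and validate terms in one pass."""
    lengths = {r.id: r.length for r in sequences}
    pairs = parse_rows(alignment_rows, lengths)
    clusters, singletons = build_clusters(pairs, lengths, lengths, si_min, cov_min)
    attach_annotations(clusters, annotations)
    catalogs = {ns.value: background_counts(annotations, ns) for ns in FUNCTIONAL_NAMESPACES}
    validations = validate_all(clusters, catalogs.values(), alpha)
    return PipelineResult(clusters, singletons, catalogs, validations, pairs)
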