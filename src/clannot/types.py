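"""Core domain types shared across the pipeline.

The pipeline moves protein sequences through four stages: graph clustering
under an identity/coverage edge rule, pooling of member annotations into
clusters, statistical validation of the pooled GO/Pfam terms, and transfer
of (validated) annotation to external query sequences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Namespace(str, enum.Enum):
    """Annotation namespaces: the three GO roots, Pfam, and structural labels."""

    MFO = "MFO"  # GO molecular function
    BPO = "BPO"  # GO biological process
    CCO = "CCO"  # GO cellular component
    PFAM = "PFAM"
    PDB = "PDB"
    SCOP = "SCOP"


#: Namespaces whose terms are subject to statistical validation.
FUNCTIONAL_NAMESPACES = (Namespace.MFO, Namespace.BPO, Namespace.CCO, Namespace.PFAM)
GO_NAMESPACES = (Namespace.MFO, Namespace.BPO, Namespace.CCO)


class Category(str, enum.Enum):
    """Cluster annotation category: structural and/or functional content."""

    PDB_AND_FUNC = "PDB_AND_FUNC"
    PDB_ONLY = "PDB_ONLY"
    FUNC_ONLY = "FUNC_ONLY"
    NONE = "NONE"


class Source(str, enum.Enum):
    """Origin of an inherited annotation."""

    CLUSTER = "CLUSTER"
    SINGLETON = "SINGLETON"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """One sequence -> term assignment in a namespace."""

    seq_id: str
    term_id: str
    namespace: Namespace


@dataclass(frozen=True)
class AlignmentPair:
    """A single pairwise alignment hit (best HSP of a query/subject pair).

    ``identity`` is the fraction of identical positions over the alignment
    length; ``q_span``/``s_span`` are the number of aligned residues on each
    sequence, used to compute per-sequence coverage.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    q_span: int
    s_span: int
    evalue: float
    bitscore: float = 0.0


@dataclass
class Cluster:
    """A connected component of the similarity graph, with pooled annotation.

    ``term_counts`` maps (namespace, term_id) to the number of distinct
    members carrying the term. ``n_annotated`` maps a namespace to the number
    of members with at least one term in it (the draw size of the
    over-representation test). ``templates`` lists (pdb_chain, member_id)
    pairs for members carrying a PDB label.
    """

    id: str
    members: frozenset[str]
    term_counts: dict[tuple[Namespace, str], int] = field(default_factory=dict)
    n_annotated: dict[Namespace, int] = field(default_factory=dict)
    category: Category = Category.NONE
    templates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TermCatalog:
    """Background term frequencies for one namespace.

    ``N`` counts sequences carrying at least one term in the namespace over
    the whole loaded universe; ``K[t]`` counts sequences carrying term ``t``.
    """

    namespace: Namespace
    N: int
    K: dict[str, int]


@dataclass(frozen=True)
class TermValidation:
    """Over-representation test result for one (cluster, term) pair."""

    cluster_id: str
    namespace: Namespace
    term_id: str
    k: int  # cluster members with the term
    n: int  # cluster members annotated in the namespace
    K: int  # background sequences with the term
    N: int  # background sequences annotated in the namespace
    p_raw: float
    p_corrected: float
    validated: bool


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap null of the minimum corrected P over random pseudo-clusters."""

    namespace: Namespace
    cluster_size: int
    replicates: int
    min_corrected_p: tuple[float, ...]
    seed: int
    alpha: float

    @property
    def null_validation_rate(self) -> float:
        """Fraction of replicates whose best term would be called validated."""
        return sum(p < self.alpha for p in self.min_corrected_p) / self.replicates


@dataclass(frozen=True)
class SingletonSource:
    """A singleton sequence acting as a (never-validated) annotation donor."""

    seq_id: str
    terms: tuple[tuple[Namespace, str], ...]


@dataclass(frozen=True)
class InheritedAnnotation:
    """A term transferred to a query, with provenance and validation status."""

    query_id: str
    cluster_id: str  # singleton seq_id when source is SINGLETON
    namespace: Namespace
    term_id: str
    validated: bool
    p_corrected: float | None
    source: Source


@dataclass(frozen=True)
class TemplateHit:
    """A structural template offered to a query by its cluster.

    ``remote`` flags remote homology: query-to-template identity strictly
    below 0.30. ``proxy`` marks identities taken from the query's best
    in-cluster hit because no direct hit to the template member exists.
    """

    query_id: str
    template_id: str
    template_seq_id: str
    identity_to_template: float
    remote: bool
    proxy: bool = False


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic sequence family.

    ``target_identity`` is each member's expected identity to the common
    ancestor; member-to-member identity is lower (independent mutations),
    with per-position match probability t**2 + (1-t)**2/19.
    """

    n_members: int
    ancestor_length: int
    target_identity: float
    planted_terms: tuple[tuple[Namespace, str], ...] = ()
    indel_rate: float = 0.0
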