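# Methods

## Model and procedure

`clannot` implements cluster-mediated annotation transfer in three stages.

**Similarity graph and clusters.** Pairwise hits (12-column BLAST tabular)
become undirected edges when sequence identity — identical positions over the
alignment length, i.e. BLAST `pident` — is ≥ `si_min` (default 0.40) and the
aligned span covers ≥ `cov_min` (default 0.90) of **both** the query and the
subject length. Both bounds are inclusive. Multiple HSPs for a pair reduce to
the single HSP with the lowest e-value (ties: highest bitscore, then first
seen); HSPs are never tiled, since tiling would silently inflate coverage. A
hit passing in either direction creates the edge (alignment asymmetry is
tolerated because the graph is undirected by construction). Clusters are
connected components of size ≥ 2; sequences with no passing edge are
singletons. The symmetric coverage reading was chosen over a one-sided or
alignment-length-relative one because it forces clustered sequences to have
near-identical lengths, the regime in which whole-protein function transfer
is defensible; the package reports the per-cluster length standard deviation
as a diagnostic. No e-value ceiling is applied before the identity/coverage
filter by default (`--max-evalue` exists but is off), since the filter itself
is far stricter than any conventional ceiling.

Cluster ids are deterministic: components sorted by (descending size,
lexicographically smallest member) and named `C<rank>` with zero padding, so
identical inputs yield byte-identical output files.

**Term pooling and background.** A cluster inherits every member's
annotations. For each namespace (MFO, BPO, CCO, Pfam) the cluster records
`k(t)` = distinct members carrying term `t` and `n` = members with ≥ 1 term
in the namespace. A member with several terms counts once per (member, term);
no down-weighting of multi-annotated sequences is applied. The background is
the **whole loaded sequence universe** — clustered sequences and singletons
alike — restricted per namespace to annotated sequences: `N` sequences with
≥ 1 term, `K(t)` carrying `t`. This is the central statistical decision of
the implementation: the background population determines every P-value, and
using the full universe (rather than clustered sequences only) makes the test
measure enrichment relative to what annotation looks like overall.

**Validation statistic.** Each cluster term is tested with the exact
hypergeometric upper tail `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` (scipy's
survival function, evaluated stably in log space), i.e. the standard exact
over-representation test. The statistic sits behind a single function so an
alternative (e.g. binomial approximation) could be swapped in. The Bonferroni
factor is `m` = distinct terms of the same namespace within the cluster — a
per-cluster, per-namespace correction, matching the fact that the validated
flag is a per-cluster statement, not a dataset-wide discovery claim. A term
is validated when corrected P `< 0.01` (strict inequality). GO annotations
are **not** ancestor-propagated before testing by default; an opt-in
propagation mode (`propagate_go` / `--propagate-go`) adds all `is_a`
ancestors before counting, which makes shallow terms much more frequent in
both cluster and background and generally weakens specific-term enrichment.

**Bootstrap null.** For a namespace and cluster size `s`, each replicate
draws `s` sequences uniformly without replacement from the annotated
background, keeping each sequence's full term set (so term co-occurrence is
part of the null), validates the pseudo-cluster, and records the minimum
corrected P. The fraction of replicates with minimum corrected P < alpha is
the null validation rate — with Bonferroni correction it stays at or below
alpha (measured ≈ 0.002 at alpha 0.01 on a uniform background of 600
sequences × 20 terms, 1000 replicates). Sequences (not individual
annotations) are resampled because the unit of clustering is the sequence.

**Transfer.** Query-to-cluster assignment is best-hit (lowest e-value among
hits passing the edge rule; ties by highest identity, then subject id), with
the count of passing hits into *other* clusters reported alongside, since a
query aligned post hoc may legitimately touch several clusters. Voting
schemes were considered and rejected as under-specified; best-hit is
deterministic and auditable. Inherited records carry the cluster's validated
flag and corrected P per term; structural-label namespaces (PDB, SCOP) pass
through with `validated=False` and no P since they are never tested. Template
identity uses the query's direct pairwise hit to the template-carrying
member when available; otherwise the query's best in-cluster hit identity is
used as a proxy and flagged `proxy` so downstream filters can drop it.
Remote homology is identity strictly `< 0.30`. The relaxed mapping mode keeps
SI ≥ 0.40 and lowers both coverage bounds to 0.70; by construction its mapped
query set is a superset of the strict set.

## Synthetic data generator

The generator emulates the statistical structure the method assumes: tight
sequence families over an unrelated background, family-coherent annotation,
and uniform annotation noise.

- **Families:** a random ancestor over the 20-residue alphabet; each member
  substitutes each position independently with probability `1 − t`
  (`t = target_identity`, default 0.7) to a uniformly chosen different
  residue. Member-to-ancestor identity concentrates at `t`; member-to-member
  identity at `t² + (1 − t)²/19` (≈ 0.495 at t = 0.7), comfortably above the
  0.40 edge threshold at the default. No indels, so true pairwise identities
  and full-length spans can be written to the alignment table exactly,
  without running an aligner; an indel mode is deliberately out of scope
  (users run a real aligner and parse its tabular output).
- **Alignment table:** every intra-family pair gets one row with its true
  identity; cross-family and decoy pairs are emitted only at true identity
  ≥ 0.25 — noise edges that exercise the filter but (at the default lengths,
  ≥ 16 standard deviations above random expectation ≈ 0.05) never occur
  between unrelated sequences, keeping planted families exactly recoverable.
  Synthetic e-values decrease monotonically in identity × length.
- **Annotations:** each family plants one GO (MFO) and one Pfam term carried
  by each member with probability 0.9 (annotation in real databases is
  incomplete even within a family); every sequence carries each of 20 decoy
  terms independently at rate 0.05.
- **Defaults** (50 families × 10 members, length 300, 1000 decoys with ± 20%
  length jitter) give backgrounds of ~900 annotated sequences per namespace —
  large enough that a planted term with k ≥ 3 carriers in a cluster is
  validated while decoy terms at k ≤ 4 are not.

What passing these tests does **not** show about real data: real families
have indels, domain architecture (partial-length homology), phylogenetic
correlation between annotation and identity, biased annotation (hub terms),
and inter-family homology at intermediate identity. The generator omits all
of these on purpose; the package's claims on real data rest on the method,
not on these fixtures.

## Numerical and edge-case choices

- Threshold comparisons: SI and coverage bounds inclusive (`≥`); validation
  strict (`< 0.01`); remote homology strict (`< 0.30`).
- `P(X ≥ 0) = 1` exactly; an empty background (`N = 0`) is an error rather
  than a silent 1.0.
- Corrected P capped at 1; the validation-curve histogram therefore treats
  its last bin edge (1.0) as inclusive.
- Population (not sample) standard deviation for cluster length dispersion —
  the cluster is the whole population of interest.
- Degenerate inputs: clusters with no terms in a namespace yield an empty
  validation list; clusters without templates yield an empty template
  report; a term carried by every background sequence yields corrected P = 1
  in every bootstrap replicate.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical serialized outputs.

## Problem sizes

Tests and the acceptance script run the standard conditions (50 × 10 + 1000
sequences, ~1500 × 1500 implicit comparisons done vectorized per length
class) in a few seconds per seed; the recovery property is checked over 20
seeds. The bootstrap null uses 1000 replicates.

## Known limitations

- Best-hit cluster assignment ignores secondary clusters beyond a count.
- Proxy template identities can understate or overstate the true
  query-template identity; they are flagged, not resolved (cluster-level
  profile alignment is out of scope).
- Bonferroni is the only correction offered; no FDR alternative.
- The GO rollup uses `is_a` edges only; `part_of` and regulatory
  relationships are ignored.
- SCOP labels are pass-through metadata; no hierarchy logic.
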