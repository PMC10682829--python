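# Methods

This note records the models, parameter choices and numerical
conventions behind `fmo-roadmap`, and what the synthetic fixtures do and
do not establish about real data.

## Fingerprint model

Fingerprints are compiled from PROSITE-style strings into ordered
elements: literal residue, wildcard (`x`), or an alternative class
`(A/B)`. Scanning slides the pattern over every window; a mismatch is
counted at each non-wildcard element whose residue is not allowed.
Overlapping hits are all reported, and the vetting verdict uses
existence of hits, not their count.

Two deliberate semantics:

* An `X` (unknown residue) in a **sequence** matches only wildcard
  elements. Low-quality sequence therefore can never satisfy a
  fingerprint, only miss one — the conservative direction for a
  screening step.
* "Partially conserved" fingerprint is defined **count-based**: a hit
  with at most `partial_max_mismatches` (default 1) mismatches over the
  informative elements. A positional definition (which elements may
  vary) would be equally defensible; the count threshold is exposed so
  users can tighten it to 0 (exact-only) or relax it. The family
  verdict treats full and partial FMO hits alike, but a partial hit
  only earns half the fingerprint evidence weight downstream.

The Rossmann `GXGXXG` count (non-overlapping, greedy left-to-right) is
reported descriptively; fewer than two raises a warning flag but never
changes the verdict, since a single mutated glycine would otherwise veto
an obvious family member.

## Anchor mapping and diagnostics

All diagnostic coordinates are anchor-relative: site 56 means "the query
column aligned to anchor position 56", regardless of the query's own
numbering. User-facing coordinates are 1-based inclusive on ungapped
sequences; internal column indices are 0-based half-open. Queries are
aligned to the anchor with biopython's global affine-gap aligner
(BLOSUM62, gap open 11, gap extend 1 — conventional protein defaults;
nothing in the classification is sensitive to ±2 on either penalty at
fixture divergences). Among co-optimal alignments the aligner's first
traceback is used; it is deterministic for fixed inputs, which is what
the reproducibility guarantee needs — the specific tie policy is not
load-bearing.

Diagnostic sites falling in deletions are excluded from the scored count
(with a warning) instead of being counted as mismatches: a missing
column says nothing about which clade's residue would have been there.
Sparse dyad-2 variants (Thr/His/Val) score 0.5 for clades I–III —
observed in the family, but not diagnostic. The gatekeeper position
(375) is mapped and reported but never scored, because its identity is
clade-variable. BVMO/NMO profiles carry full-alphabet sets at positions
where no diagnostic residue is established (back-door for both, dyad-1
for NMO); those sets are deliberately uninformative and the outgroup
length ranges (500–620 and 400–500) are soft package defaults.

An NTF2-like N-terminal extension is flagged when a clade III call has
≥100 residues (configurable) before the first exact Rossmann motif.
This is a flag, not evidence: the extension does not change catalytic
identity.

## Distance trees and support

Maximum-likelihood inference is intentionally out of scope; the tree
stage is a desk-scale stack chosen to be exactly testable:

* **Distance**: Poisson correction −ln(1−p) with pairwise deletion of
  gap/`X` columns. Pairs at p ≥ 0.95 are saturated — an error in the
  library API; capped at −ln(0.05) with a warning inside the pipeline,
  which must tolerate arbitrary query sets. An externally inferred
  Newick tree can be supplied to the support/rooting machinery instead.
* **Neighbor-joining**: canonical Q-criterion; ties broken by the
  lexicographically smallest label pair; negative branch-length
  estimates clamped to zero with a warning. On additive matrices NJ is
  exact (verified to 1e-9 against random tree metrics, n ≤ 8).
* **Midpoint rooting**: scikit-bio's implementation, wrapped with a
  two-leaf special case and a balance assertion (the two deepest leaves
  must be equidistant from the root within 1e-9). All-zero branch
  lengths are an error.
* **Bootstrap**: column resampling with replacement, one seeded
  generator per run.
* **Support**: classical support is the fraction of replicates
  containing the branch exactly. TBE per replicate is
  1 − δ/(p−1) where δ is the minimum Hamming distance between the
  branch's bipartition and any bipartition of the replicate (both
  orientations, trivial splits included — which bounds δ ≤ p−1); TBE is
  the mean over replicates. δ is computed by exhaustive search over
  replicate bipartitions, which is exact and affordable at desk scale.
  Consequences checked in tests: TBE ≥ classical branch-wise, and
  TBE = classical on cherries (p = 2, δ ∈ {0,1}).

Newick output uses 6-decimal branch lengths and `classical/tbe`
internal-node labels (two decimals each).

## Classifier

Clade scores are weighted sums over four channels; weights are package
choices (the published practice is tree inspection) and all are exposed:

| channel      | vote                                        | weight |
|--------------|---------------------------------------------|--------|
| placement    | exp(−mean Poisson distance to clade's refs) | 0.5    |
| diagnostics  | matched weight / scored sites               | 0.3    |
| length       | 1 if inside clade length range else 0       | 0.1    |
| fingerprint  | 1 full / 0.5 partial                        | 0.1    |

Placement dominates by design — evolutionary placement first, residues
and architecture as corroboration. The `exp(−d)` map keeps the vote in
(0,1], equals 1 only at distance zero, and makes confidence decay
smoothly with divergence; since it is monotone it never changes the
argmax relative to raw mean distances. Confidence is the winning score
divided by the total active weight. Calls with a top-two gap below
`margin` (default 0.15) are `ambiguous`; the margin was set so that
self-classification of panel references clears it roughly twofold while
an even I/II chimera falls inside it. Length ranges are point values
±≈10% (460–560, 410–490, 380–460, 480–560 for clades I–IV) so length is
soft evidence, never decisive alone. Sequences vetted as BVMO are
reported `family=BVMO, clade=outgroup`; `conflict`/`none` carry no
clade. Taxonomy is never an input: clade membership does not follow the
species tree.

## Synthetic fixtures

The generator provides known truth, not biology:

* A 560-residue uniform-random scaffold carries two Rossmann motifs
  (positions 9–14, 240–245) and the FMO fingerprint instance
  `FAGSTVHLMNYK` at 246–257, directly after the second Rossmann motif
  as in the real inter-domain linker.
* Each clade consensus diverges from the scaffold at rate 0.30 (0.45
  for the outgroups) at unprotected sites before receiving its
  diagnostic residues and clade-typical length (500/450/420/520 for
  I–IV; 560 BVMO, 450 NMO). The between-clade divergence step is
  essential: with literally identical scaffolds the clades would differ
  at only ~8 sites and distance-based placement could not separate
  them, whereas the real clades are deeply divergent lineages.
* References are drawn at 5% within-clade divergence; queries at any
  requested rate, with diagnostic sites and the fingerprint span
  protected. BVMO consensuses swap in `GGAWLLLLFPGSTAD`; NMO
  consensuses carry no family fingerprint. Every draw is
  rejection-sampled until fingerprint vetting returns the intended
  verdict, because a ~500-residue random sequence occasionally contains
  a near-fingerprint window by chance.
* `evolve_alignment` uses the simplest uniform-replacement Poisson
  process (per-branch substitution probability 1 − exp(−length×rate)),
  no indels, no rate heterogeneity.

All generators are pure functions of their seeds; reruns are
byte-identical.

**What passing tests show — and don't.** Recovery results (≥95% clade
recovery at 10% mutation; 6-leaf topology recovery from 2,000 columns)
demonstrate internal consistency: the pipeline recovers truth generated
under its own assumptions. Real sequences bring indels, domain
rearrangements, compositional bias and rate heterogeneity that the
generator deliberately omits, so fixture accuracy is an upper bound, not
a field estimate. The characteristic failure mode visible even on
fixtures is honest: ~1% of 10%-mutated queries acquire a chance partial
BVMO fingerprint and are reported `conflict` rather than silently
forced into a clade.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by choice: 1,000 sequences
for the scanner oracle, 200 short pairs for the exhaustive alignment
oracle, 100 random trees for NJ/midpoint properties, 400 queries for
clade recovery, 100 seeds × 2,000 columns for topology recovery. These
sizes give binomial standard errors comfortably inside the asserted
thresholds while keeping the whole suite in minutes on one core. Every
stochastic step takes an explicit seed; the pipeline stamps seed and
package version into `report.json`, and TSV/Newick artifacts are
byte-stable across reruns.

## Known limitations

* No profile-HMM/PSSM scoring; fingerprints are hard patterns.
* No progressive multiple alignment: the pipeline's internal MSA is a
  reference-anchored projection (query residues at anchor columns,
  insertions relative to the anchor dropped), adequate for distances at
  fixture divergence but not a substitute for a real aligner on deeply
  gapped families. Externally built alignments are accepted as input.
* NJ + Poisson distance is not ML; on real data, supply an external
  tree for the support/rooting/classification stages when accuracy of
  the topology matters.
* NMO identity cannot be asserted from sequence alone (no fingerprint
  is defined); it is reported only as an externally hinted caveat.
* Anchor numbering assumes the crystal-structure numbering matches the
  deposited anchor sequence; users building a panel from real
  accessions should verify there is no tag/offset shift.
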