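# Methods

## The identification model

`taxoprint` implements character-based barcode identification. Given a
taxon-labelled multiple sequence alignment of a marker (e.g. *trnH-psbA*,
*ycf1b*, *rbcL*, *ITS*), the unit of evidence is a *diagnostic
character*: a column state or a coded indel that is fixed in the target
taxon and absent from the comparison taxa, quantified by a support pair
(k target records carrying the state out of n countable) and an explicit
per-taxon exception list. A query is assigned to a taxon when every
character of that taxon's fingerprint is observed at the query's mapped
loci, and to no other taxon's fingerprint completely. This is the
same philosophy as the CAOS family of character-based barcoding methods:
identification rests on discrete, auditable motives rather than on an
aggregate similarity score, which matters when the margin between
intra-taxon variation and inter-taxon divergence is small, as it
routinely is in plants.

### Coordinates

All loci are 1-based alignment columns of the reference alignment,
inclusive spans for indels. All-gap columns are retained so printed
positions remain comparable to the deposited file. Because a fingerprint
is meaningless outside its alignment, the fingerprint JSON carries the
alignment width and SHA-256; the classifier refuses mismatched widths.

## Diagnostic discovery

For a target taxon, a column base state qualifies when at least
`min_target_fraction` (default 1.0 — strictly fixed) of the target's
countable records carry it and at most `max_other_exceptions` (default 0)
non-target records carry it. Characters with a non-zero but small
exception count ("near-diagnostics", the 75-of-76 pattern) are retained
and reported with per-taxon counts, never silently dropped or silently
promoted: by default only zero-exception characters may alone complete a
fingerprint (`allow_near` overrides, and any assignment resting on
near-diagnostics carries an explicit caveat).

Ambiguity codes (R, Y, N, …) carry no state by default: an R neither
supports an A diagnosis nor counts as an exception to it, and ambiguous
records are removed from the target denominator. This permissive default
avoids false negatives from ordinary Sanger ambiguity; a strict mode
counts compatible ambiguous non-target records as exceptions instead. A
column where any target record has a gap is left to the indel characters.

### Indel coding

Gaps are coded by the simple-indel-coding convention: each distinct
maximal internal gap run (start, end) observed in at least one record is
one presence/absence character; a record whose own gap run overlaps the
span without matching it exactly scores *missing*, as do records whose
terminal (leading/trailing) gap runs cover the span. Terminal runs are
never characters themselves — Sanger amplicons have ragged ends, and
treating them as deletions would fabricate diagnostics at the alignment
edges.

### Combination fingerprints

When no single character excludes every non-target taxon, a greedy set
cover assembles a minimal conjunction: iteratively add the candidate
excluding the most not-yet-excluded taxa, with deterministic tie-breaking
(zero-exception before near-diagnostic, then lower column, then SNP
before indel). Greedy is transparent and reproducible, and real
fingerprints are tiny (one or two characters); an exact minimum-cover
search is available for candidate sets of at most 20. A taxon counts as
excluded by a character when none of its records carry the state; with
`allow_near`, taxa whose carriers are declared exceptions also count,
with the caveat propagated to every report.

## Query mapping

Queries arrive unaligned. Re-running a multiple aligner on references
plus query would renumber every column, so instead the reference
alignment is frozen into a per-column {A, C, G, T, gap} frequency profile
(ambiguity codes split uniformly over their constituent bases) and the
degapped query is aligned to it by semi-global affine-gap dynamic
programming (Gotoh three-state recurrence):

- match score of base *b* at column *c*:
  `match_reward · f(b,c) − mismatch_penalty · (1 − f(b,c) − f(gap,c))`;
- defaults: match 2, mismatch 2, gap open 5, gap extend 1;
- deletion penalties (query skipping a column) are scaled by the
  column's non-gap frequency, so columns that are mostly gap in the
  references are nearly free to skip — a query identical to a gapped
  reference row then reproduces that row's gap structure exactly;
- end gaps are free on both sides (partial amplicons), the path starting
  and ending on a matrix edge;
- traceback ties prefer diagonal, then vertical, then horizontal, making
  the mapping deterministic.

An indel character is matched only when the query's gap run has exactly
the diagnostic breakpoints; partial overlap is a mismatch with an
explanatory note. A consequence worth knowing: a polymorphic column
immediately flanking an indel can make a breakpoint-shifted placement
score marginally better than the exact one, in which case an indel
character is (conservatively) not matched. In curated reference sets
breakpoint flanks are conserved and this does not arise.

Mapped queries get a quality flag: *ok* requires aligned fraction ≥ 0.8
and best per-site identity against any reference row ≥ 0.7 (both
configurable); values below 0.5 *fail*, anything between *warns*. A
failed query is never classified — the marker simply did not work for
that sample, which is itself a finding (the wrong-marker failure mode).

Classification is deliberately threshold-free beyond this: a query
matching only part of a fingerprint is reported unassigned with the full
per-character evidence, not scored. Multiple markers are treated as
independent lines of evidence — one classification per marker, no
cross-marker aggregation.

## Phylogenetic corroboration

Trees are a cross-check on fingerprint calls, not the decision. Distances
default to the p-distance with pairwise deletion of gaps and ambiguous
sites (the most transparent choice for a corroborating display); the
Kimura two-parameter correction
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` is selectable and raises an error
at saturation. Trees come from the canonical Neighbour-Joining iteration
(Studier–Keppler O(n³) form of the Saitou–Nei criterion), with
deterministic tie-breaking (first minimal pair in input order) and
negative branch lengths clamped to zero with the raw value logged.
Output is an unrooted tree (trifurcating root) serialized as Newick with
6-decimal branch lengths; outgroup rooting is a display option. On
additive matrices the implementation reproduces the generating tree's
patristic distances to numerical precision, and it is cross-checked
against scikit-bio's NJ in the test suite.

## Synthetic data

The generator emulates the statistical structure of a curated barcoding
reference set: K taxa (default 3) of n_k sequences (default 5) copied
from a random consensus (default 120 columns), each taxon fixed for
`planted_snps_per_taxon` taxon-specific SNPs (default 1, state differing
from consensus) and optionally for taxon-specific deletions with shared
breakpoints; i.i.d. per-site substitution noise at rate θ (default 0)
and IUPAC ambiguity calls always compatible with the true base
(Sanger-style soft calls) at a configurable rate. A taxon's own planted
loci are exempt from noise (fixed by construction, as in a
well-delimited taxon); every other site, including other taxa's planted
loci, mutates freely — which is exactly how noise erodes strict
diagnostics. Per-record random substreams draw their uniform fields
identically for every θ, so mutated site sets are nested as θ grows and
recovery recall is monotone non-increasing under a shared seed, a
property the tests assert exactly rather than statistically.

What the generator does *not* emulate: phylogenetic correlation within
and between taxa, alignment error, PCR chimeras, heterozygous ITS
copies. Inter-taxon divergence is represented by the planted characters
alone. Passing recovery tests therefore demonstrates that the counting,
coding and classification logic is correct under the stated noise model
— not that any particular real marker will yield complete fingerprints.

The three bundled case-study sets (`synthetic_cases`) are synthetic
stand-ins whose taxon compositions and character coordinates reproduce
the published Camellia (A at 82 in 7/7, G in 22/22 and 75/76, 7-nt gap
at 232 absent in 60/76), Nerium (C at 545 and T at 587, 5 vs 11) and
Prunus (10-bp deletion at 114, absent in all 57 congeners)
configurations, with species-private background substitutions placed
away from the diagnostic loci and indel breakpoints.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: discovery is
checked against a brute-force enumeration oracle on 1000 random
alignments up to 10 × 50; recovery benchmarks use 50 replicates (3 taxa
× 5 sequences × 120 columns) with leave-one-out classification over the
first 5 records per replicate; NJ is checked on hundreds of random
additive matrices of up to 8 leaves (the acceptance script uses 200).
Profile-column frequencies sum to 1 within 1e-9; NJ patristic recovery
on additive inputs is asserted at 1e-9; Newick round-trips at 1e-6 per
branch. Degenerate inputs (empty queries, all-gap records, ragged
alignments, saturated K2P pairs, sub-3-leaf matrices) raise informative
errors rather than guessing.

## Known limitations

- Fingerprint completeness is relative to the taxa present in the
  reference alignment; an unsampled sister species can share the
  fingerprint states.
- Exact-breakpoint indel matching is conservative near polymorphic
  flanks (see above).
- Profile alignment assumes the query belongs to the marker; distant
  off-target amplicons are caught by the quality flag, near-target
  chimeras are not.
- The greedy cover can exceed the minimum conjunction size in
  adversarial candidate sets (the exact search covers the realistic
  range).
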