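# Methods

This note records the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Read cleaning and tag accounting

Reads are cleaned in four steps: 3′-adapter removal, quality filtering,
length filtering, and poly-A removal, then collapsed into unique tags.

*Adapter trimming* is a best-overlap semi-global search: the suffix of
the read is aligned against every prefix of the 3′ adapter (overlap ≥ 6
nt, mismatches ≤ 10% of the overlap), and the highest-scoring occurrence
(matches − 2·mismatches, ties toward the longest adapter block) is cut.
Reads without a 3′ adapter occurrence are discarded: their insert may
run past the read end, so the insert length is unknowable.  A 5′-adapter
remnant at the read start is removed by the symmetric rule when a 5′
adapter is configured.

*Quality filtering* keeps reads with mean Phred ≥ 20 and no ambiguous
bases by default (thresholds configurable); FASTA input is filtered on N
content only.  *Length filtering* defaults to 18–30 nt, the informatic
regime; gel purification of small-RNA libraries spans 15–30 nt, and both
bounds are configurable.  *Poly-A removal* drops tags with ≥ 80% A
content or a terminal run of ≥ 8 A's — poly-A artifacts have no
principled published cutoff, so both knobs are explicit.

Collapsing preserves total read number exactly; tags are ordered by
descending count, then sequence, so every downstream table is
deterministic.

## Genome mapping and category partition

Mapping records every exact, ungapped, full-length occurrence of a tag
on either strand (1-based inclusive coordinates throughout).  Mismatch-
tolerant or spliced placement is deliberately out of scope.

Each mapped tag receives exactly one category by precedence:
miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > siRNA > exon > intron >
unann.  Structural-RNA contamination must not be absorbed by gene-model
categories, and the miRNA category is sequence-based (tags matched to
the known mature set), not track-based.  Multi-locus tags are classified
once by the highest-precedence category over all loci, and their
redundant count attributed once, so the unique/redundant columns always
sum to the library totals.

The siRNA category has no recoverable published definition; the stand-in
used here is a 21–24 nt tag whose locus is overlapped, on the opposite
strand, by another mapped tag — the double-stranded signature of siRNA
production.  It can be switched off.

## Conserved matching and divergence

A tag is conserved when an ungapped containment alignment against a
known mature exists with ≤ 3 substitutions in the overlap and total
terminal overhang ≤ 3 nt.  Terminal shifts are tracked separately from
substitutions because ortholog comparisons show terminal divergence, not
internal mismatch, dominating between closely related species.  The best
assignment minimizes substitutions, then total overhang, then known id
(lexicographic) — fully deterministic.  Family labels are parsed from
the id stem ("miR" + number; member letters and species prefixes
ignored).

`terminal_divergence` considers all ungapped relative offsets of two
matures and keeps the alignment with the most matching core bases (ties:
fewest substitutions, then smallest 5′ overhang); d5/d3 are the summed
unmatched terminal lengths at each end.  Values are reported as
computed, never clamped to a narrative range.

## Variant calling

Within each conserved miRNA's tag group the wild type is the tag equal
to the known mature (regardless of abundance), else the most abundant
tag.  A non-wild-type tag is a **miR-SNP** when it has the same length
and Hamming distance exactly 1, a **miR-LD** when an ungapped alignment
exists with a substitution-free overlap and nonzero terminal shifts
(|Δ5|+|Δ3| ≤ 4; beyond that a tag is treated as a distinct sequence).  A
tag with both a shift and a substitution is neither — it is reported in
an `other_variant` bucket so the two statistics stay clean.  Minimum
read support defaults to 1 (all sequenced variants count) and is
configurable to suppress noise.

SNP sites are classified against a miRNA:target duplex by comparing the
wild-type pairing state with the alt base's pairing: `creates_new_mismatch`
(paired position, alt no longer pairs), `at_existing_mismatch` (position
already mismatched; flagged `pairing_gained` when the alt restores
pairing), `pairing_retained` (paired and still pairs — e.g. a G→U
change opposite C), or `outside_duplex`.  The spec'd three-way return
could not express the pairing-restored case its own examples require, so
the fourth label was added.

## Hairpin discovery

Windows around a mapped mature extend its 5′ and 3′ sides independently
in `step` increments up to `max_flank` per side (defaults 20/280,
covering the longest published precursor of 311 nt), strand-aware and
clipped at chromosome ends.

### Built-in folding engine

An exact dynamic program over nested structures (no pseudoknots,
minimum hairpin loop 3 nt) under a deliberately simple energy model: a
pair stacked directly on another pair contributes −3 (G:C), −2 (A:U) or
−1 (G:U) kcal/mol and each hairpin loop costs +4; isolated pairs
contribute nothing.  The DP (numba-compiled, O(n³)) is proven optimal
against full structure enumeration for sequences up to 20 nt in the test
suite.  The empty structure is returned when no structure is negative,
so mfe = 0 iff there are no pairs.

This engine makes no claim of thermodynamic realism or ViennaRNA
compatibility.  Its known limitation: because energies scale with
pairing count, long random windows reach "stable" energies easily, so
the absolute MFE threshold discriminates poorly on its scale.
Properties that depend on energetic realism (decoy rejection, published
MFE values) are therefore checked through the external-engine plug-in —
any executable consuming FASTA on stdin and emitting
`sequence` / `dot-bracket (mfe)` lines, e.g. `RNAfold --noPS`.

### Acceptance criteria

A candidate is accepted when all of the following hold; the thresholds
are configurable and the defaults are:

| criterion | default | rationale |
|---|---|---|
| fold energy | ≤ −18 kcal/mol | published candidates were retained at −19.7, so a strict −20 gate would contradict the catalog |
| single stem-loop | — | mature bases outside any terminal loop, all pairing in one direction, and the region between mature and partner arm self-contained (no pair exits it; otherwise the mature sits in a multiloop) |
| mature pairing | ≤ 4 unpaired mature bases | the standard plant-annotation tolerance |
| compact duplex | partner span ≤ mature span + 4 | the miRNA:miRNA* duplex allows only small asymmetric bulges |
| precursor length | 60–320 nt | brackets the published 65–311 nt range |

The miRNA\* (duplex partner with canonical 2-nt 3′ overhangs, derived
from the pair table so bulges are followed) is searched in the tag
library by exact sequence; finding it is recorded as supporting
evidence, never required — published candidates include many without a
sequenced star.  Among accepted windows the lowest-energy one wins
(ties: shortest precursor, then smallest start).

## Target scanning

An exhaustive scan replaces BLAST seeding: every transcript window of
width |miRNA| (± 1 for a single bulge) is scored by the Allen penalty
scheme — mismatch 1.0, G:U 0.5, bulged position 1.0, doubled at miRNA
positions 2–13 (a convention imported from the target-prediction
literature, since the 5′-proximal region governs cleavage).  Windows at
or under the cutoff (default 4.0) are kept; overlap clusters reduce to
the best-scoring, 5′-most site.  An optional raw-mismatch filter (< 4
mismatches) mirrors the BLAST-era rule literally; weighted score and raw
count can disagree, so both are exposed.  The predicted cleavage
position is the transcript base pairing miRNA nucleotide 10 (or 9),
walked through the state vector so bulges shift it correctly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Genome** (60 kb default): non-overlapping rRNA/tRNA/snRNA/snoRNA/
  repeat/exon/intron features, 24 hairpin precursors (random arm of
  40–55 nt + 10–15 nt loop + reverse-complement arm with ≤ 2 defects
  planted away from the mature/star duplex), 20 decoy windows
  (first-order-Markov resampled precursor neighbourhoods: dinucleotide
  statistics preserved in expectation, long-range pairing destroyed),
  plus dedicated siRNA and unannotated zones.
* **Expression**: log-normal read counts (meanlog 4.0, sdlog 1.6) — a
  desk-scale rendering of the heavy-tailed copy-number spread observed
  in real libraries (copies from single digits to hundreds of
  thousands); a full 19-million-read library is out of desk scope, and
  the recovery metrics are rates, not absolute counts.
* **Variants**: 56/126 of miRNAs carry a planted miR-SNP (uniform
  internal position, random alt base) and 43/126 a miR-LD (±1–2 nt
  templated terminal shift) — the fractions of variant-bearing conserved
  miRNAs in the published library — at 3% of wild-type reads (minimum
  1), echoing the strong wild-type dominance reported.
* **Stars** at 10% of mature reads, the published rule of thumb.
* **Categories**: redundant-read fractions set to the published category
  table; read lengths drawn from a 24-nt-dominant profile (36.94% at 24
  nt, 20–24 nt ≈ 85%).
* Every read is wrapped with the 3′ adapter, given synthetic qualities
  (a configurable fraction planted low-quality), and recorded in a truth
  table; a fixed seed yields byte-identical output files.

What the generator does **not** emulate: sequencing error profiles
(homopolymer decay, miscalls), genuine miRNA family sequence similarity
(members are independent random sequences), isomiR biology beyond the
planted SNP/LD classes, and real-genome repeat structure.  Closed-loop
results therefore demonstrate correctness of the pipeline's logic on
data satisfying its assumptions, not performance on real libraries.

Truth labels for miRNA\* reads are kept in a separate `star` class and
excluded from the category-accuracy metric: the pipeline's miRNA
category is defined by known-mature matching, and a star is
legitimately ambiguous between the miRNA and siRNA-signature classes.
Decoys are evaluated as the planted windows they are (one fold per
decoy); mature discovery, in contrast, enumerates windows around the
tag, which is why its search is the recall path.

## Pipeline composition

Stage order: clean → map → conserved → categorize → variants → novel →
targets.  Conserved matching precedes novel discovery so conserved tags
never enter hairpin-candidate input, and only unannotated tags (category
`unann`, read count ≥ 5 by default) are folded.  Closed-loop validation
at desk scale uses windows of `max_flank` 120 / `step` 40, which cover
the generator's ~100–130 nt precursors; the production defaults
(280/20) remain available for real-genome work.  Every run writes its
resolved configuration and a manifest with seed, version and a
parameter hash; identical configs produce byte-identical tables.

## Numerical conventions

Percentages are rounded half-up at 2 decimals (never banker's rounding)
to reproduce printed tables deterministically.  All RNA input is
normalized U→T at load time.  Ties anywhere (tag ordering, assignment
choice, window choice, site overlap) break by explicit deterministic
rules stated at each operation.
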