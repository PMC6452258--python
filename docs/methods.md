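# Methods

## Overview

`spacerscope` analyses CRISPR spacer repertoires sampled by
repeat-anchored amplicon sequencing. The pipeline assumes that every
CRISPR type of interest is described by a degenerate repeat consensus,
that amplicons span one to a few repeat–spacer units, and that sequencing
error is substitution-dominated. Under those assumptions each stage is a
deterministic function of its inputs and parameters; this note records
the models, the parameters that matter, and the choices made where the
design was genuinely open.

## Repeat matching

A repeat consensus is an IUPAC-degenerate string; a subject base matches
a pattern symbol when it belongs to the symbol's base class. Matching is
evaluated at every offset on both strands (a minus-strand match means the
reverse complement of the subject carries the consensus; coordinates stay
on the forward strand, 0-based half-open). Subject `N`s match every
symbol but are tallied separately, and a window with more than 2 `N`s is
flagged as unreliable. Overlapping matches of the same type are resolved
greedily — fewest mismatches, then leftmost, then plus strand — because
a repeat locus can legitimately match at shifted offsets (several of the
consensi are internally repetitive or partially self-complementary) and
only one call per locus is meaningful.

The default mismatch budget for read scanning is 3. The tolerance used
by the original extraction tooling for this assay is not published, so
the budget is an explicit parameter, recorded in output metadata, rather
than a claim. The packaged consensus table carries six *Thermus*
types/subtypes with expected spacer lengths 41 (IIIAB), 32 (I-E), 38
(I-C), 36 (I-B, I-U, I-A) nt; subtypes III-A and III-B share a repeat
(and crRNAs) and are treated as one type, IIIAB.

## Spacer extraction

A spacer is the gap between two adjacent same-type, same-strand,
full-length repeat matches whose length lies in the type's expected band
(expected ± 10 nt by default; the assay itself only constrains spacers
to "an expected length", so the half-width is configurable per type).
Reads are 3'-quality-trimmed at Phred 20 before scanning; spacers
containing ambiguous bases are dropped. Gaps bounded by repeats of
*different* types yield nothing and flag the read as a chimera
candidate — amplification across two arrays is indistinguishable from a
genuine mixed junction at read level, so these junctions are dropped,
not salvaged. A spacer that itself contains an 8-nt terminal fragment of
either observed flanking repeat (within 1 mismatch) is discarded as
likely repeat contamination. All spacers are reported in the consensus
(+) frame and indexed in array order within their read, so forward and
reverse reads of one array are indistinguishable downstream.

Genome mining chains ≥ 2 same-type, same-strand matches with in-band
gaps into arrays. Array spacers are stored in the consensus frame in
array order, which makes the mined content invariant to
reverse-complementing the contig (only the orientation flag flips).
Paired-end mates are treated as independent reads; each spacer
observation keeps its read id so per-read or per-pair tallies can both
be recomputed.

## Clustering

Within each sample and type, unique sequences are clustered greedily in
decreasing read-count order (ties broken lexicographically — an explicit
determinism choice, since the original tool's input order is
unknowable): a sequence joins the first cluster whose centre it matches
at ≥ 85% identity, else founds a new cluster. Identity is the best
ungapped overlap alignment (internal gaps disallowed, terminal overhangs
free) divided by the *shorter* sequence length; the denominator
convention is ambiguous in the UCLUST description, so the choice is
recorded in output metadata. Centres are finalised as the most abundant
member (ties: lexicographically smallest). Clusters with more than 10
reads are retained for repertoire comparisons; the filter threshold is
the `min_size` parameter (default 11, i.e. strictly more than 10).

Across samples, sites or genomes, two same-type centres count as the
same spacer when they differ by fewer than two mismatches: Hamming ≤ 1
at equal lengths, or, at unequal lengths, a best end-gap-free overlap
with ≤ 1 mismatch and at most 2 nt of total overhang (the unequal-length
extension is ours and is flagged distinctly). The number of unique
spacers in a pooled collection is the number of connected components of
this match graph; both the per-site union and the global component count
are reported because they answer subtly different questions. Pairs of
*different* types that align over ≥ 20 nt with ≤ 1 mismatch are listed
separately as independent-acquisition candidates and never merge
components.

## Diversity statistics

Per-sample cluster abundances feed Shannon entropy (natural log, on read
counts; a unique-sequence tally is also emitted since assays differ in
which they report), the bias-corrected Chao1 estimator
`S_obs + f1(f1−1)/(2(f2+1))` (defined even when doubletons are absent;
the variant name is recorded in output), and Good's coverage `1 − n1/N`.
β-diversity defaults to Bray–Curtis on counts with Jaccard on
presence/absence as companion — the upstream description names no
metric, and these are the common defaults — summarised by UPGMA
(average-linkage) dendrograms in Newick. Abundance correlations of
shared clusters are Pearson coefficients on log10 counts, because
cluster sizes span orders of magnitude; the linear-scale coefficient is
emitted alongside. Fisher's exact test is two-sided by the
probability-mass rule (`scipy.stats.fisher_exact`); the test suite
cross-checks it against full hypergeometric enumeration.

## Array assembly

Consecutive spacer pairs (and triplets) within single reads accumulate
into a directed adjacency graph with read-support counts. Edges with
support below 2 are pruned — single-read adjacencies are
indistinguishable from PCR/sequencing chimeras, and the upstream
description is silent on chimera handling, so conservatism wins.
Fragments are maximal chains of edges that are the unique successor of
their source and unique predecessor of their target; branching nodes
(spacers shared between arrays) terminate chains, and a triplet (A, X, C)
whose flanking pairs are unique among the recorded triplets phases two
chains through the branch. There is no probabilistic phasing: a reported
order is always directly witnessed by reads. Cycles (possible when a
spacer genuinely repeats) are broken at their lowest-support edge and
flagged.

Fragment comparison finds the longest common contiguous spacer block
(trying both orientations) and classifies pairs as identical,
end-trimmed (one fragment is an end-anchored sub-run of the other),
partially renewed, or unrelated. When both fragments carry private
spacers beyond the shared block at the same end, that end is labelled
the putative leader-proximal end — leader-end inference is purely
comparative (new spacers appear at the leader), never from sequence
context, because amplicons carry no leader sequence.

## Protospacer search and PAM inference

The hit definition — identity strictly greater than 0.85 over the entire
spacer length, no indels — is implemented directly as an ungapped
seed-and-extend search (exact 8-mer seeds on both strands, full-length
extension) rather than by wrapping an external aligner; this removes a
binary dependency while keeping the seed length (word size 8) of
short-sequence BLASTn searches. For a 32-mer the threshold admits ≥ 28
matching positions (28/32 = 0.875) and rejects 27. Subject `N`s count as
mismatches. The test suite proves the search equivalent to an exhaustive
every-offset scan.

Eight nucleotides upstream and downstream of each hit are extracted in
protospacer orientation (minus-strand hits take reverse-complemented
flanks from the opposite sides); flanks truncated by a contig edge are
excluded from PAM counting. PAM models are per-position count matrices
over the 8+8 flank positions with information content
`2 + Σ p·log2 p` bits; the consensus symbol is the base at ≥ 0.75
frequency, a two-fold IUPAC code when the top two bases jointly reach
0.9, else `N`. At least 5 intact flank pairs are required for a call.

Locality is tested per target with a 2×2 table (spacer local/foreign to
the target's isolation site × hit/no-hit) and Fisher's exact test.
Strand bias assigns hits to genes overlapping ≥ 50% of the hit length
and reports the fraction of hits lying on the transcribed (template)
strand — defined as the protospacer strand being *opposite* the gene's
coding strand, i.e. the configuration in which the crRNA can base-pair
with the transcript and transcription-coupled (type III) interference is
active — with a two-sided exact binomial test against 0.5. The
convention is stated here and in report headers because published figure
legends alone cannot disambiguate it.

## Synthetic communities

The generator emulates the structure the analysis assumes, with all
randomness from one integer seed:

- **Sites and samples** — default two sites, two samples per site,
  ~220 spacers per site.
- **Arrays** — 10–35 spacers (the fragment-length range observed in
  environmental array reconstructions), spacer lengths drawn from the
  per-type bands of the repeat table. Spacers that contain repeat-like
  terminal 8-mers are rejected at generation time: such sequences are
  inherently unextractable (they are indistinguishable from repeat
  contamination) and would contaminate ground truth.
- **Sharing** — a configurable fraction of each site's spacers belongs
  to arrays present at every site; shared arrays receive site-specific
  leader-proximal additions (0–2 by default) and leader-distal deletions
  (0–1), matching the acquisition/loss narrative of longitudinal
  observations; private arrays top repertoires up so the realised shared
  fraction matches the setting.
- **Abundances** — one strain per array with log-normal(0, 1.5)
  abundance, producing the heavy singleton tail that Good's coverage and
  the >10-read filter act on; per-sample log-normal(0, 0.2) noise on top.
- **Phages** — random genomes with community spacers planted as
  protospacers (a locality fraction, default 0.9, from the phage's home
  site), the type's PAM written at the 5' flank (AAG for I-E, GGTN for
  I-B, TTC for I-C/I-U), and toy alternating-strand gene blocks for
  strand-bias analyses; type III protospacers are placed in the
  transcription-coupled configuration by default.
- **Reads** — alternating repeat/spacer runs of 1–4 units (one concrete
  repeat instantiation per array), random orientation, uniform per-base
  substitution errors (default 0.5%), flat Phred qualities. Indel errors
  are deliberately absent: the error model is Illumina-substitution-
  dominated and the clustering stage absorbs substitutions; an indel
  error model is out of scope.

What the generator does **not** emulate: PCR amplification bias,
instrument-specific quality profiles, indels, phage evolution, or real
repeat-sequence divergence within an array beyond the degenerate
consensus. Tests passing on synthetic data therefore demonstrate
correctness of the algorithms under the stated error model, not
robustness to every artefact of real libraries.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
communities of 120–300 spacers per site, 250–2 500 reads per sample,
phage genomes of 20–60 kb, 20-seed replications for assembly and PAM
recovery. These sizes were chosen so every property that matters —
perfect extraction on clean reads, ≥ 95% recall at 0.5% error,
planted-centre recovery at 50× depth, ≥ 90% junction recovery at 10×
junction coverage, 100% PAM-motif recovery — is measurable with tight
statistics in minutes on one CPU. Degenerate inputs (empty sequences,
zero-margin tables, all-singleton samples, fewer than three shared
clusters, truncated flanks) return defined values or explicit warnings
rather than raising mid-pipeline; every tie-break in the codebase is
lexicographic so that permuting input order never changes a result.

## Known limitations

- Repeat types must be supplied; there is no de novo repeat discovery.
- Chimera-candidate junctions are dropped, never rescued, slightly
  under-counting spacers at genuine array boundaries shared by two types.
- Leader-end labels are comparative hypotheses, not sequence-based calls.
- The unequal-length spacer match rule (overhang ≤ 2) is an extension of
  the fewer-than-two-mismatches rule; matches produced only by it are
  flagged.
- `run_all` drives the simulated workflow end to end; externally supplied
  reads are analysed through the individual stage commands.
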