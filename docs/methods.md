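# Methods

This note documents the models, parameter choices and numerical conventions
behind `natphase`, and what the synthetic test data do and do not show.

## Scope and data model

The workflow runs genome-free: NATs are inferred purely from
transcript-level complementarity, which means cis- and trans-NATs cannot be
distinguished by locus. The proxy used instead is annealing quality — a
pair whose single validated region anneals perfectly (one maximal segment,
no bubbles) is flagged a *cis-NAT candidate*, because perfect annealing is
what overlapping opposite-strand transcription produces, while trans pairs
typically anneal with mismatches.

All sequences are folded to DNA (U→T, upper case) on input so one alphabet
serves alignment and mapping; `N` is legal in transcripts but never pairs
and never matches. Coordinates are 1-based inclusive on each transcript's
forward strand, everywhere. Collapsed sRNA/degradome libraries use the
community `>{id}_x{count}` header dialect; sRNA reads outside 15–35 nt are
dropped at parse time and excluded from the library total, so RPM values
over the retained reads sum to one million per library.

## Antisense alignment stage

Pairs are gated by an exact shared k-mer (default `seed_len` 12) between A
and revcomp(B); gated pairs get an optimal local alignment (biotite's
C implementation) with +1/−2 substitution scores and affine gaps costing
`gap_open + (L−1)·gap_extend` = −5, −2. These defaults approximate blastn
behaviour; all are configurable. `min_score` 60 doubles as a minimum
alignment length (score s needs ≥ s matched columns), which keeps random
200-nt decoys safely unalignable. Because the extension step is an optimal
DP rather than an X-drop heuristic, the reported score provably equals the
full Smith–Waterman/Gotoh score whenever a seed exists inside the optimal
alignment — the property the oracle tests assert.

Additional regions for the same pair are found by recursively realigning
the A-flanks left and right of each accepted region, which guarantees
non-overlap on A (B-side reuse is permitted; a region is an A-anchored
entity here).

Classification: *HC* when the region spans more than `hc_fraction` (0.5)
of at least one transcript — the at-least-one reading is the default
(`hc_mode`) with a both-transcripts mode available, since the prose
definition ("either transcript") admits both. *100-nt* when the longest
gap-free aligned block reaches 100 nt, mismatches allowed inside the block:
trans-NAT annealed regions usually contain mismatches, so demanding
perfection would empty the class; a mismatch-free variant is available
(`nt100_perfect`).

## Duplex validation stage

Structure-level validation replaces thermodynamics with a combinatorial
objective: over all monotone, non-crossing inter-molecular pairings of the
two windows (the matched intervals padded by 10 nt), maximize
`pairs − λ·bubble_columns` with λ = 1. A mismatch cannot occupy a column —
it necessarily becomes a 1+1 bubble (size 1). G·U wobble counts as a pair
by default (RNA duplex), switchable. This keeps the stage exactly testable:
the DP is checked against exhaustive alignment enumeration on tiny toys and
against an independent longest-path-on-DAG solver up to 40 nt. The
stage answers the only questions downstream code asks — does the region
anneal, where are the bubbles, where are the perfect segments — for which
pair counting is sufficient statistics; it does not rank duplexes by free
energy.

Tie-breaks are deterministic: the best-scoring cell is the first
encountered in row-major order (strict `>` update), so the *shortest*
optimal alignment wins and net-zero extensions (a pair bought at an equal
bubble cost) are excluded; traceback prefers pair > gap-in-B > gap-in-A.

Retention criterion 1 divides the overlap by the structure-predicted
region length (the fraction of the structure region covered by the
alignment region), checked on both transcripts at ≥ 0.8. Criterion 2
bounds every bubble size (max of the two strand gap lengths) by 10% of the
annealed-region length measured on strand A; the two strands differ only by
bubble asymmetry, and a per-bubble max-gap-strand denominator is available.
Both "≥ 80%" and "no larger than 10%" are inclusive boundaries, and the
tests sweep them (retain at bubble 10, drop at 11; retain at coverage 80%,
drop at 79%).

## Phased-siRNA detection

Mapping is exact and strand-specific: a read is evidence only for the
transcript it matches as a literal substring (sense). Antisense
relationships are represented by the same read matching the *partner*
transcript — no reverse-complement mapping step exists, which is what makes
strand bookkeeping trivial. The mapper is a k-mer prefix index (k = 12)
with full verification; multi-mapped reads count at every locus with no
fractional weighting, matching the retain-all-perfect-alignments
convention.

Detection is per perfect segment, per sRNA length *n* ∈ {21, 24} by
default, lengths searched independently (a phase grid is only meaningful at
one length; mixed-length clusters are not merged). The segment must be
strictly longer than 80 bp (81 is the shortest searched; the boundary is
tested from both sides). For each register r ∈ [0, n) the slot grid starts
at `segment_start + r`; slot `[i, i+n−1]`'s antisense partner occupies
sense coordinates `[i−2, i+n−3]` — both offsets forced by the 2-nt 3′
overhang. A slot is evidenced by a sense 5′ end exactly at `i` or an
antisense 5′ end exactly at the partner position; *either strand* suffices
(libraries routinely miss the weakly expressed strand), with a stricter
both-strands mode as a flag. Maximal runs of ≥ 4 consecutive evidenced
slots become clusters; maximality and the run threshold are verified
against a brute-force (register × run) enumeration.

Edge rule: a sense footprint must lie fully inside the perfect segment; an
antisense partner whose 2-nt overhang would exit the segment does not
count (its slot can still be evidenced on the sense strand). The
permissive variant (`allow_edge_overhang`) admits partners extending up to
2 nt past the segment edge; strict containment is the default because
phasing is anchored to the perfectly annealed region and positions beyond
it have no guaranteed pairing partner.

Evidence is pooled across selected libraries (combinatory use); each
cluster records per-library presence and per-sRNA RPM for reporting, so a
single-library view is a selection, not a re-run.

## Degradome evidence

Tags map under the same exact sense-only contract, restricted to
transcripts carrying clusters. A tag supports slot k when its 5′ end equals
the siRNA 5′ end on that strand (sense slots on transcript A; antisense
positions located on B through the antiparallel coordinate map
`m(x) = b_start + (a_end − x)`, an involution). Terminus evidence requires
the 5′ end exactly one nucleotide past the last phased siRNA's 3′ end,
searched on both strands — on the antisense strand the "last" siRNA in that
transcript's 5′→3′ sense is the partner of the *first* slot. The position
test is exact by default; a ±1-nt window exists as a flag but defaults off.
Reports carry the standard caveat that poly(A)-selected degradome
libraries cannot show processing of non-Pol II transcripts.

Counting is cluster-assigned on distinct sRNA sequences, so supported
siRNAs ⊆ phased siRNAs and supported clusters ⊆ clusters hold structurally;
the suite asserts this nesting on every run.

## Synthetic data: what it emulates and what it does not

The fixture generator plants one NAT pair (transcript A holding a random
core; B holding its reverse complement, optionally damaged), decoy
transcripts, phased reads cut from both strands with exact duplex geometry,
and degradome tags at siRNA 5′ ends and at terminus+1 — with a machine-
readable truth record for every expected output. Everything derives from
one integer seed; identical seeds give byte-identical files.

The construction guarantees its own ground truth rather than approximating
it:

* decoys are rejection-sampled to share no 12-mer with any other transcript
  in either orientation, so decoy hits of any kind are impossible, not just
  unlikely — the zero-false-positive assertion is exact;
* flanks are A/C-only on both transcripts: no A/C base pairs another A/C
  base under Watson-Crick or G·U rules, so both alignment stages provably
  stop at the planted core;
* defect neighbourhoods are pairing-inert — deletion blocks are all-C with
  C-free windows, foreign (mismatch/insertion) bases all-A with T-free
  windows, junction bases resampled until no equal-score swap-pairing
  exists — making the optimal duplex decomposition unique;
* every planted read and tag sequence is verified to occur exactly once
  across the transcript set (the build retries under a fresh deterministic
  substream on collision);
* bubbles are pure deletions or pure insertions: a mixed-gap bubble lets
  the affine aligner trade gap columns for substitution columns at equal
  score, leaving block-length truth genuinely ambiguous, so mixed bubbles
  are rejected by the fixture validator (they are exercised at the
  duplex-DP level by the oracle tests instead).

Consequently, passing the closure test means the pipeline inverts the
generative model exactly on clean data. It does **not** demonstrate
robustness to sequencing error, expression noise, assembly artifacts
(chimeras, redundant isoforms), repeat-induced multi-mapping ambiguity, or
borderline duplexes whose optimal structure is honestly degenerate — real
transcriptomes contain all of these. Scale is also synthetic: test runs use
a handful of transcripts of a few hundred nt with regions of 100–300 bp,
chosen so the whole suite and the acceptance script run in seconds; the
all-pairs seed gate plus optimal DP is adequate at this scale and for
moderate transcript sets, but a transcriptome-scale run (hundreds of
thousands of transcripts) would want the optional external BLAST tabular
import path instead of the internal all-pairs alignment.

## Known limitations

* No E-value statistics; `min_score` is a raw-score threshold.
* No thermodynamic duplex scoring or intramolecular structure; a
  combinatorial bubble penalty stands in for both.
* No miRNA annotation/exclusion and no phasing P-value statistic: cluster
  membership is the combinatorial criterion (≥ 4 consecutive evidenced
  slots), not a significance score.
* Genome-based cis/trans classification is out of scope by design; the
  cis flag is a structural candidate label only.
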