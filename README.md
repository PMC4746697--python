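# natphase

Discovery of **natural antisense transcript (NAT) pairs** and
**phase-distributed nat-siRNAs** from *de novo* assembled transcriptomes —
built for organisms without a usable reference genome, where NATs cannot be
read off genome annotation and must be inferred from transcript
complementarity alone.

## The problem

NATs are pairs of endogenous transcripts with long complementary regions
that anneal *in vivo*. Their double-stranded regions are processed by
Dicer-like (DCL) proteins into **nat-siRNAs**, and processive DCL cleavage
leaves a distinctive signature: sRNA duplexes of one fixed length *n*
released head-to-tail, each with **2-nt 3′ overhangs**, so that sRNA 5′ ends
fall at regular *n*-nt intervals (a fixed phase *register*) along the
precursor. `natphase` finds candidate NAT pairs in an assembled
transcriptome, validates that they can anneal, then scans the perfectly
annealed regions for these phased clusters and attaches degradome (PARE)
5′-end evidence of processing.

## The method

1. **Antisense alignment** — every transcript pair sharing an exact k-mer
   seed (default 12) between A and revcomp(B) is aligned with an optimal
   gapped local alignment (+1 match, −2 mismatch, affine gaps −5/−2).
   Regions scoring ≥ 60 are classified **HC** (complementary region longer
   than 50% of either transcript) and/or **100-nt** (longest contiguous
   complementary block ≥ 100 nt).
2. **Duplex validation** — each candidate region is re-examined at the
   structure level with a base-pair-maximizing duplex alignment
   (objective: pairs − λ·bubble columns, λ = 1; G·U wobble allowed).
   Candidates are retained when (1) the structure-predicted annealed region
   overlaps the alignment-predicted region at ≥ 80% on both transcripts and
   (2) no interior bubble exceeds 10% of the region length. A pair whose
   single retained region is one bubble-free perfect segment is flagged a
   **cis-NAT candidate**.
3. **Phased-siRNA search** — collapsed sRNA reads are mapped exactly and
   strand-specifically onto retained NATs. In every perfectly annealed
   segment > 80 bp, for every sRNA length (default 21 and 24 nt) and every
   register, a phase grid is laid out; a slot `[i, i+n−1]` is *evidenced*
   when a read 5′ end sits exactly at `i` on the sense strand or at the
   antisense partner position (sense coordinate `i+n−3`, forced by the 2-nt
   3′-overhang geometry) — evidence on **either strand** of a duplex
   suffices. Maximal runs of ≥ 4 consecutive evidenced slots are reported
   as **phased clusters**.
4. **Degradome evidence** — degradome tags mapped perfectly to cluster
   transcripts support a phased siRNA when their 5′ end coincides with its
   5′ end, or the cluster terminus when it falls one nucleotide past the
   last phased siRNA's 3′ end.

## Worked example

The package ships a deterministic synthetic-data generator (the same one
the tests use), so a complete run needs no downloads:

```bash
natphase make-fixtures -o demo --seed 7
natphase all -t demo/transcripts.fa -o demo_out \
    -s lib1=demo/srna_lib1.fa -d deg1=demo/degradome_deg1.fa
```

which prints

```
1 phased clusters (8 nat-siRNAs, 1 degradome-supported); reports in demo_out
```

and writes TSV tables plus a plain-text report, `demo_out/report.txt`:

```
## Pair 1: nat_a / nat_b
  (1) annealed region: nat_a from 61th to 180th nucleotide; nat_b from 41th
      to 160th nucleotide  [cis-NAT candidate]
  (2) cluster nat_a|nat_b|61-180|n21|r3|p64: 8 nat-siRNAs assigned to 4
      consecutive phases (21-nt register 3); libraries: lib1
  (3) degradome tag deg1_t0 (deg1, 508196.72 RPM) supports slot 0 [sense]
      at position 64 of nat_a
  (3) degradome tag deg1_t1 (deg1, 491803.28 RPM) supports terminus [sense]
      at position 148 of nat_a
```

Reading this: the two planted transcripts anneal over a single perfect
120-bp region (hence the cis-NAT candidate flag); inside it the eight
21-nt reads form four consecutive phased duplexes starting at position 64
(register 3); one degradome tag confirms the 5′ end of the first siRNA and
another the expected cleavage point just past the last one. RPM is reads
per million, normalized per library.

The block numbering — (1) pair and annealed region, (2) clusters with
per-library breakdown, (3) degradome detail — mirrors the summary counts in
`demo_out/summary.tsv`: pairs per class, retained regions, cis candidates,
regions searched, clusters, phased siRNAs, degradome-supported siRNAs.

Real data drop in the same way: transcripts as FASTA, each sRNA or
degradome library as collapsed FASTA with `>{id}_x{count}` headers.
`predict-nats` runs the first half alone when no sRNA data exist.

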