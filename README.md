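# editscan

Offline design engine for CRISPR/Cas9 sgRNA and TALEN genome editing:
given a locally supplied genome (FASTA) and optional gene models
(refFlat/BED12), it finds candidate target sites, enumerates their genomic
off-targets exactly under several mismatch models, ranks them, and emits
genotyping aids — specificity-ranked PCR primer pairs and restriction-site
maps — as TSV and annotated GenBank files. Everything runs locally; no
downloads, no external aligner binaries.

## Who it is for

Anyone making targeted mutants (zebrafish, *Drosophila*, cell lines, ...)
who needs to pick a guide or TALEN pair that cuts where intended and
nowhere else, and then genotype the result. The package is primarily a
Python library (see `examples/`), with a thin `editscan` command for
shell use.

## The rules it implements

**Cas9 sites.** A candidate is a 23 bp window: a 20 bp protospacer
followed by the -NGG protospacer-adjacent motif (PAM), scanned on both
strands. Optional 5′ constraints (GG- for T7, GN-/NG- for U6 synthesis)
restrict the protospacer start. Off-targets are genomic windows whose PAM
matches -NGG exactly, under one of three mismatch models:

* `all_upstream` (default) — up to `max_mm` (default 2) mismatches
  anywhere in the protospacer, never in the PAM;
* `seed_exact` — the 11 PAM-proximal bases (protospacer positions 10–20)
  must match exactly, mismatches allowed only in positions 1–9;
* `perfect_only` — exact matches only.

The search is seed-and-extend over an exact k-mer index with a pigeonhole
guarantee (k ≤ ⌊L/(max_mm+1)⌋, so no admissible hit can escape every
seed); an exhaustive window-scan oracle verifies equivalence in the tests.

**Ranking.** Strict lexicographic order: ascending counts of off-targets
with 0, then 1, then 2 mismatches (a perfect off-target is worse than a
mismatched one); then GC content inside the effective 45–80 % window;
then a guanine at protospacer position 20 (PAM-adjacent); then distance
from the transcript 5′ end (early sites favor null alleles).

**TALEN pairs.** Two half-sites on opposite strands, each beginning with
the invariant 5′ T, flanking a 14–20 bp spacer where FokI dimerizes.
RVD strings use NI=A, HD=C, NG=T and NN or NH for G (the 5′ T is read by
the TALE N-terminus, not a repeat). Off-target search allows 0–2
mismatches per half-site (default 2); loci where two hits face each other
across an in-range gap are *paired* off-targets — the ones that can
actually cut — and dominate the ranking. Near-identical pairs (e.g.
differing only in spacer width) are clustered and represented by their
best member.

**Genotyping.** Primer pairs spanning the cut site are enumerated
exhaustively under classic constraints (length 18–25 bp, optimum 22;
product 150–290 bp; Tm 57–63 °C, optimum 60, SantaLucia nearest-neighbor),
then ranked by genome-wide specificity: exact hits of each primer are
mapped and convergent off-site amplicons counted. Restriction sites
(IUPAC-aware, built-in table of ~40 common enzymes or a user TSV) are
mapped and flagged unique/non-unique in the region; TALEN mode also lists
sites inside the spacer.

## Worked example

`examples/01_design_sgrnas.py` plants a known guide plus a perfect
duplicate and a single-mismatch copy in a 20 kb synthetic genome, then
scans a 400 bp window and ranks all 57 candidates:

```
57 candidate sites in chr1:5001-5400
rank  site(23bp)               strand  GC%   G20  mm0 mm1 mm2
   1  GAGAGATGCTCGTGTACGGGCGG      -   60.0  1    0   0   0
   2  TCAGGTCAACGTAACCCAGGAGG      -   55.0  1    0   0   0
   3  GTTGACCTGAGTCAAGCATGGGG      +   50.0  1    0   0   0
...
planted guide ranks 57/57 with tallies mm0=1 mm1=1 mm2=0
```

`mm0/mm1/mm2` count other genomic loci matching each guide with 0/1/2
mismatches. The deliberately duplicated guide drops to the bottom: a
perfect off-target (mm0=1) loses to every clean guide regardless of GC or
position, which is exactly the intended severity order. The other
examples walk through TALEN design (`02`), primer/restriction genotyping
(`03`) and a full report-writing run (`04`).

CLI equivalent:

```bash
editscan --query gene1 --genome genome.fa --gene-table genes.txt \
         --mode crispr --out out/
# out/results.tsv, out/offtargets/rankNNNN.tsv, out/primers.tsv,
# out/region.gb, out/region_nointrons.gb
```

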