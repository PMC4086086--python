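# Methods

## Scope and model

editscan treats nuclease target design as exact combinatorial search over
a finite genome, not as probabilistic prediction. A Cas9 candidate is any
23 bp window (20 bp protospacer + -NGG PAM) on either strand; a TALEN
candidate is a pair of half-sites on opposite strands, each starting with
the invariant 5′ thymine read by the TALE N-terminal domain, flanking a
spacer where FokI must dimerize to cut. Off-target risk is quantified by
exhaustively enumerating every genomic window that the design could still
engage under a fixed mismatch budget, rather than by a learned activity
score. This reflects the assumption — appropriate at design time — that
any sufficiently similar locus is a liability, and it keeps every number
in the output independently checkable.

## Coordinates and alphabets

Internal coordinates are 0-based half-open; user-facing strings (query
grammar `chrom:start-end`, TSV `start_1based`, GenBank locations) are
1-based inclusive. Sequences are uppercase A/C/G/T/N. Degenerate IUPAC
letters in a genome are collapsed to N on load (they cannot be targeted or
synthesized); N never matches anything during search, and no candidate
site may contain N. Degenerate letters are honored only in restriction
enzyme recognition sequences, where they are expanded to character
classes.

## Off-target search

Three Cas9 mismatch models coexist because the literature disagrees about
where mismatches abolish cleavage:

* `all_upstream` (default): ≤ `max_mm` mismatches anywhere in the 20-mer,
  PAM always -NGG exact (N free). Default `max_mm` = 2 — the reported
  tally cascade is 0/1/2 mismatches, so 2 is the deepest level the table
  displays.
* `seed_exact`: the 11 PAM-proximal protospacer positions (10–20 in our
  1-based, 5′-anchored numbering) must be exact; mismatches only in
  positions 1–9. This encodes the finding that single mismatches within
  11 bp of the PAM abolish cleavage.
* `perfect_only`: exact protospacer matches, a fast screen.

NAG PAMs are not counted (a configuration flag exists but defaults off).
TALEN half-sites are searched with ≤ 2 mismatches across the whole site;
the 5′ T is enforced at the hit locus too, since binding requires it —
the source rule set is silent on this point and we chose the stricter
reading. Paired TALEN off-targets combine any plus-strand hit with any
minus-strand hit (from either half-site — FokI does not care which array
binds which side) whose gap lies in the configured spacer range.

The engine is seed-and-extend over an exact k-mer postings index of the
plus strand (minus-strand queries look up reverse complements). For a
query of length L at mismatch budget m, the query is split into m+1
disjoint k-length chunks; by pigeonhole any admissible hit matches at
least one chunk exactly, so candidate loci recovered through the index
and verified base-by-base are provably complete. This requires
k ≤ ⌊L/(m+1)⌋ — k = 6 for 20-mers at m = 2, k = 5 for 15 bp half-sites —
hence the index accepts 4 ≤ k ≤ 16. Verification of a candidate locus is
a direct window comparison, shared with the brute-force oracle; the
oracle (an exhaustive both-strand window scan with no seeding, in a plain
and a vectorized form) is what the tests compare the indexed search
against, on random 50–100 kb genomes across all three modes.

Each candidate's own locus is returned flagged `is_self` and excluded
from tallies. Mismatch positions are reported 1-based from the query 5′
end.

## Ranking

A strict lexicographic key, never a weighted score — the criteria have a
stated priority order but no stated weights, and a lexicographic cascade
is the unique order consistent with that priority:

* Cas9: (n0, n1, n2 ascending; GC-in-window flag; G20 flag; transcript
  offset ascending), ties broken by plus-strand coordinate then strand.
  GC is a binary in-window test with inclusive bounds 45 % and 80 %
  (a range is stated, not a response curve). G20 is guanine at
  protospacer position 20, i.e. PAM-adjacent — the numbering is anchored
  at the 5′ end so that this matches the PAM-proximal-G activity
  observation.
* TALEN: (paired off-target count; summed half-site n0, n1, n2;
  transcript offset), paired events first because only a dimer cuts.

Transcript offset is measured from the transcript 5′ end using gene
strand when a model is available, else from region start. Rank quartiles
map to green/yellow/orange/red display bins.

TALEN pairs whose combined footprints reciprocally overlap ≥ 80 % are
clustered (the threshold is our choice; the source rule set says
"equivalent" without quantifying) and the best-ranked member represents
the cluster; members remain accessible for detailed inspection.

## Gene models and sub-regions

refFlat (UCSC 11-column) and BED12 are parsed directly; rows with
malformed or overlapping exon lists are skipped with a warning. When a
gene name matches several transcripts the longest by exonic length is
used (logged; the choice was genuinely open). Sub-region filters: UTRs
and CDS by intersecting exons with the CDS interval; `splice_sites` as
±20 bp windows (configurable half-width; no width is stated anywhere)
around internal exon boundaries; exon subsets are 1-based in transcript
orientation, so exon 1 of a minus-strand gene is its last genomic exon.

## Primer design and specificity

Candidates are enumerated exhaustively — every start × length in the
feasible flanks — because at amplicon scale (≤ ~300 bp each side) this is
cheap and guarantees no feasible pair is silently pruned. Defaults:
length 18–25 bp (optimum 22), product 150–290 bp, Tm 57–63 °C (optimum
60), and ≥ 50 bp between each primer and the cut site (our default; the
option is exposed without a stated value). Pair penalty is
|Tm−60| + 0.2·|len−22| summed over both primers; the emitted list is
penalty-sorted and capped (default 25) before specificity ranking so
genome mapping stays proportionate — every emitted pair still satisfies
every constraint.

Tm is the nearest-neighbor duplex model with the SantaLucia (1998)
unified parameters, 50 mM monovalent cation, 50 nM total oligo entering
as CT/4, SantaLucia (1998) entropic salt correction — computed via
Biopython's `MeltingTemp.Tm_NN`; the test suite carries an independent
hand-written nearest-neighbor summation and requires agreement within
0.5 °C.

Specificity: each primer is mapped exactly (both strands, enumeration
capped at 10 hits); `off_products` counts loci other than the target
where a plus-strand hit of one primer and a minus-strand hit of the other
converge within 1.5× the maximum product size — our operationalization of
"off-targets producing amplicons of similar length", which names no
threshold. Order: off_products, then total hit count, then penalty.
Hairpin/dimer thermodynamics are out of scope.

## Restriction mapping

Recognition sequences are IUPAC-expanded to regexes and scanned on both
strands with overlapping matches; palindromic sites are reported once, on
the plus strand. A site is `unique_in_region` iff its enzyme cuts exactly
once in the displayed region. TALEN spacer sites must be fully contained
in the spacer. A built-in table of ~40 common enzymes with supplier tags
ships for convenience; supplier filtering is a tag match.

## Synthetic fixtures

The generator writes chosen payloads (Cas9 sites, mismatch decoys, TALEN
pairs/monomers, arbitrary sequences) into a seeded uniform-composition
background, then rejection-scrubs the background: any window within 2
mismatches of a planted protospacer (with NGG context) or half-site (with
5′ T) that is not itself a planted locus has a background base
re-randomized, iterating to convergence. Truth tables are therefore
exact — planted loci are the only admissible hits — and the tests verify
this independently by brute force. Gene models are non-overlapping
multi-exon coding transcripts on both strands. The generator reproduces
the combinatorics of real search spaces but not real genome composition:
no repeats, GC isochores or biased k-mer spectra, so passing tests
demonstrate algorithmic correctness, not robustness to repetitive
genomes (where hit lists simply grow longer).

Problem sizes used in the verification suite — 50–100 kb genomes, 200
candidates for oracle equivalence, a 50-locus primer battery — were
chosen as the smallest scales at which every code path (multi-seed
recovery, strand mirroring, cap semantics) is exercised with comfortable
margins.

## Determinism and numerical notes

There is no unseeded randomness anywhere: fixture generation takes
explicit seeds, search and ranking are pure, ties break on coordinates,
and the GenBank record date is pinned, so identical configuration and
inputs yield byte-identical outputs. Tm values are rounded to 0.01 °C and
penalties to 1e-4 only at the reporting boundary. Degenerate inputs
(regions shorter than a site, cut sites too close to an edge, non-coding
models asked for UTRs) produce empty results with logged diagnostics
rather than errors; genuinely contradictory requests (inverted spacer
bounds, out-of-range indices) raise typed errors that the CLI maps to
exit codes 2 and 1.

## Known limitations

No gapped/bulged off-target alignment; no learned on-target efficiency
scores; no NAG-PAM accounting by default; no primer secondary-structure
screening; single-genome (no alt contigs/patches semantics); TALEN
clustering threshold and splice-window width are reasonable defaults, not
fitted quantities.
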