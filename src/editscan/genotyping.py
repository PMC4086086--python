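"""Genotyping aids: specificity-ranked PCR primer pairs and restriction maps.

After a nuclease run, the edited locus is typically amplified for a T7E1
assay, restriction digest or sequencing.  Primer pairs are enumerated
exhaustively around the predicted cut site under classic PCR constraints
(length 18-25 bp, optimum 22; product 150-290 bp; Tm 57-63 C, optimum 60),
then ranked by genome-wide specificity: a pair whose primers form a second
convergent amplicon elsewhere risks genotyping the wrong locus.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from ._dna import is_palindromic, iupac_pattern, revcomp
from .discover import TalenPair
from .enzymes import EnzymeDef
from .errors import FormatError, UsageError
from .genome import Genome, TargetRegion
from .offtargets import SeedIndex

log = logging.getLogger(__name__)


@dataclass
class PrimerOptions:
    """Primer design constraints (classic PCR genotyping defaults)."""

    min_len: int = 18
    max_len: int = 25
    opt_len: int = 22
    min_product: int = 150
    max_product: int = 290
    min_tm: float = 57.0
    max_tm: float = 63.0
    opt_tm: float = 60.0
    min_dist_from_cut: int = 50
    max_pairs: int | None = 25  # None = emit every feasible pair
    map_cap: int = 10  # stop counting genomic hits per primer at this many

    def validate(self) -> None:
        if not (0 < self.min_len <= self.opt_len <= self.max_len):
            raise UsageError("primer length bounds must satisfy min <= opt <= max")
        if not (0 < self.min_product <= self.max_product):
            raise UsageError("product size bounds inverted")
        if self.min_tm > self.max_tm:
            raise UsageError("Tm bounds inverted")


@dataclass
class PrimerPair:
    """A left (plus-strand) / right (minus-strand) primer pair spanning the cut."""

    left_seq: str
    right_seq: str  # 5'->3' on the minus strand
    left_start: int  # 0-based plus-strand start of left footprint
    right_start: int  # 0-based plus-strand start of right footprint
    tm_left: float
    tm_right: float
    product_size: int
    penalty: float
    chrom: str = ""
    left_hits: int = 0
    right_hits: int = 0
    hits_capped: bool = False
    off_products: int = 0
    specificity_rank: int = 0

    @property
    def left_end(self) -> int:
        return self.left_start + len(self.left_seq)

    @property
    def right_end(self) -> int:
        return self.right_start + len(self.right_seq)


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    start: int  # 0-based plus-strand
    strand: Literal["+", "-"]
    length: int
    unique_in_region: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PrimerHits:
    """Exact genomic occurrences of one primer, possibly truncated at a cap."""

    hits: tuple[tuple[str, int, str], ...]  # (chrom, plus-strand start, strand)
    capped: bool


def melting_temperature(seq: str, na_mM: float = 50.0, oligo_nM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Uses the SantaLucia (1998) unified parameter set with the SantaLucia
    (1998) salt correction, at 50 mM monovalent cation and 50 nM total
    oligo by default.  The total strand concentration enters the
    two-state model as CT/4 for non-self-complementary duplexes.
    """
    if not 10 <= len(seq) <= 40:
        raise UsageError(f"Tm defined for 10..40-mers, got {len(seq)} bp")
    if any(b not in "ACGT" for b in seq):
        raise FormatError(f"non-ACGT base in primer {seq!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,  # SantaLucia 1998 unified
            Na=na_mM,
            dnac1=oligo_nM / 2.0,  # Tm_NN uses dnac1 - dnac2/2 = CT/4
            dnac2=oligo_nM / 2.0,
            saltcorr=5,  # SantaLucia 1998 entropy correction
        )
    )


def _enumerate_side(
    region: TargetRegion,
    lo: int,
    hi: int,
    opts: PrimerOptions,
    side: Literal["left", "right"],
) -> list[tuple[int, str, float, float]]:
    """(start, seq 5'->3', tm, penalty) for every in-bounds, in-Tm window
    whose footprint lies within [lo, hi) on the plus strand."""
    out = []
    seq = region.sequence
    off = region.start
    for length in range(opts.min_len, opts.max_len + 1):
        for start in range(max(lo, off), min(hi, region.end) - length + 1):
            window = seq[start - off : start - off + length]
            if len(window) < length or "N" in window:
                continue
            primer = window if side == "left" else revcomp(window)
            tm = melting_temperature(primer)
            if not opts.min_tm <= tm <= opts.max_tm:
                continue
            penalty = abs(tm - opts.opt_tm) + 0.2 * abs(length - opts.opt_len)
            out.append((start, primer, tm, penalty))
    return out


def design_primer_pairs(
    region_context: TargetRegion,
    cut_site: int,
    opts: PrimerOptions | None = None,
) -> list[PrimerPair]:
    """Enumerate every feasible primer pair spanning *cut_site*, best first.

    Candidate windows are enumerated exhaustively (every start x length in
    the feasible flanks — cheap at amplicon scale), filtered by all
    constraints, and paired under the product-size bounds.  Pairs are
    sorted by ascending penalty ``|Tm-opt| + 0.2*|len-opt|`` summed over
    both primers; specificity ranking happens separately against the
    genome.  Returns an empty list (with a logged diagnostic) when the
    geometry is infeasible, e.g. a cut site too close to the region edge.
    """
    opts = opts or PrimerOptions()
    opts.validate()
    region = region_context
    if not region.start <= cut_site < region.end:
        raise UsageError(
            f"cut site {cut_site} outside context {region.to_query_string()}"
        )
    left_room = cut_site - region.start
    right_room = region.end - cut_site
    need = opts.min_dist_from_cut + opts.min_len
    if left_room < need or right_room < need:
        log.warning(
            "primer design infeasible: cut site %d has %d/%d bp of context but "
            "needs >= %d bp (min distance %d + primer %d) on each side",
            cut_site, left_room, right_room, need,
            opts.min_dist_from_cut, opts.min_len,
        )
        return []
    if left_room < opts.max_product or right_room < opts.max_product:
        log.warning(
            "context around cut site %d is narrower than the maximum product "
            "size (%d bp); search clipped at the region edges",
            cut_site, opts.max_product,
        )
    # left footprints end at most min_dist before the cut, start within reach
    lefts = _enumerate_side(
        region,
        max(region.start, cut_site - opts.max_product + opts.min_len),
        cut_site - opts.min_dist_from_cut,
        opts,
        "left",
    )
    rights = _enumerate_side(
        region,
        cut_site + opts.min_dist_from_cut,
        min(region.end, cut_site + opts.max_product),
        opts,
        "right",
    )
    if not lefts or not rights:
        log.warning("no primer candidates satisfy the Tm/length constraints")
        return []
    lefts.sort(key=lambda t: t[0])
    left_starts = [t[0] for t in lefts]
    raw: list[tuple[float, tuple, tuple, int]] = []
    for r in rights:
        r_end = r[0] + len(r[1])
        lo_i = bisect_left(left_starts, r_end - opts.max_product)
        hi_i = bisect_right(left_starts, r_end - opts.min_product)
        for l in lefts[lo_i:hi_i]:
            product = r_end - l[0]
            if not opts.min_product <= product <= opts.max_product:
                continue
            raw.append((l[3] + r[3], l, r, product))
    raw.sort(key=lambda t: (t[0], t[1][0], t[2][0]))
    if opts.max_pairs is not None:
        raw = raw[: opts.max_pairs]
    pairs = [
        PrimerPair(
            left_seq=l[1], right_seq=r[1],
            left_start=l[0], right_start=r[0],
            tm_left=round(l[2], 2), tm_right=round(r[2], 2),
            product_size=product, penalty=round(pen, 4),
            chrom=region.chrom,
        )
        for pen, l, r, product in raw
    ]
    if not pairs:
        log.warning(
            "no primer pair satisfies the product size bounds %d..%d",
            opts.min_product, opts.max_product,
        )
    return pairs


def map_primer(
    primer: str, genome: Genome, index: SeedIndex, cap: int = 10
) -> PrimerHits:
    """Exact-match genomic occurrences of *primer* on both strands.

    Seeded on the primer's first k bases (exact matching needs a single
    seed) and verified in full; enumeration stops once *cap* hits are
    found, setting ``capped``.
    """
    if any(b not in "ACGT" for b in primer):
        raise FormatError(f"non-ACGT base in primer {primer!r}")
    k = index.k
    if len(primer) < k:
        raise UsageError(f"primer shorter than index k={k}")
    hits: list[tuple[str, int, str]] = []
    capped = False
    L = len(primer)
    # plus strand: primer occurs verbatim
    for chrom, pos in index.lookup(primer[:k]):
        if genome.sequences[chrom][pos : pos + L] == primer:
            hits.append((chrom, pos, "+"))
    # minus strand: revcomp occurs on the plus strand; primer's first k
    # bases map to the last k of the revcomp
    rc = revcomp(primer)
    for chrom, pos in index.lookup(rc[-k:]):
        start = pos + k - L
        if start >= 0 and genome.sequences[chrom][start : start + L] == rc:
            hits.append((chrom, start, "-"))
    hits.sort()
    if len(hits) > cap:
        hits = hits[:cap]
        capped = True
    return PrimerHits(tuple(hits), capped)


def rank_primer_pairs(
    pairs: Sequence[PrimerPair],
    genome: Genome,
    index: SeedIndex,
    opts: PrimerOptions | None = None,
) -> list[PrimerPair]:
    """Order pairs by genome-wide specificity.

    ``off_products`` counts loci other than the target where any
    plus-strand hit of one primer and minus-strand hit of the other lie
    convergently within 1.5x the maximum product size — the unintended
    amplicons that could confound genotyping.  Sort key: off_products,
    then total primer hit count, then design penalty (all ascending).
    """
    opts = opts or PrimerOptions()
    limit = int(1.5 * opts.max_product)
    hit_cache: dict[str, PrimerHits] = {}

    def mapped(primer: str) -> PrimerHits:
        if primer not in hit_cache:
            hit_cache[primer] = map_primer(primer, genome, index, cap=opts.map_cap)
        return hit_cache[primer]

    ranked = []
    for p in pairs:
        lh, rh = mapped(p.left_seq), mapped(p.right_seq)
        p.left_hits = len(lh.hits)
        p.right_hits = len(rh.hits)
        p.hits_capped = lh.capped or rh.capped
        n_off = 0
        # forward primer hits (+) against reverse primer hits (-) and vice versa
        for fw, rv, rv_len in ((lh, rh, len(p.right_seq)), (rh, lh, len(p.left_seq))):
            for chrom_f, pos_f, strand_f in fw.hits:
                if strand_f != "+":
                    continue
                for chrom_r, pos_r, strand_r in rv.hits:
                    if strand_r != "-" or chrom_r != chrom_f:
                        continue
                    amp_start, amp_end = pos_f, pos_r + rv_len
                    if amp_end <= amp_start or amp_end - amp_start > limit:
                        continue
                    if chrom_f == p.chrom and (
                        amp_start, amp_end) == (p.left_start, p.right_end):
                        continue  # the intended amplicon
                    n_off += 1
        p.off_products = n_off
        ranked.append(p)
    ranked.sort(key=lambda p: (p.off_products, p.left_hits + p.right_hits, p.penalty,
                               p.left_start, p.right_start))
    for i, p in enumerate(ranked, start=1):
        p.specificity_rank = i
    return ranked


def scan_restriction_sites(
    region: TargetRegion,
    enzymes: Sequence[EnzymeDef],
    min_site_len: int = 1,
) -> list[RestrictionSite]:
    """All recognition-site matches (IUPAC-expanded) on both strands.

    Enzymes with sites shorter than *min_site_len* are dropped entirely.
    Palindromic recognition sequences match both strands at every locus,
    so they are reported once, on the plus strand.
    """
    out: list[RestrictionSite] = []
    seq = region.sequence
    for enz in enzymes:
        if enz.site_length < min_site_len:
            continue
        rec = enz.recognition.upper()
        patterns = [(iupac_pattern(rec), "+")]
        if not is_palindromic(rec):
            patterns.append((iupac_pattern(revcomp(rec)), "-"))
        for pattern, strand in patterns:
            pos = 0
            while True:
                m = pattern.search(seq, pos)
                if m is None:
                    break
                out.append(
                    RestrictionSite(enz.name, region.start + m.start(), strand,  # type: ignore[arg-type]
                                    enz.site_length)
                )
                pos = m.start() + 1  # overlapping matches
    out.sort(key=lambda s: (s.start, s.enzyme, s.strand))
    return out


def classify_uniqueness(
    sites: Sequence[RestrictionSite], region: TargetRegion
) -> list[RestrictionSite]:
    """Mark each site unique iff its enzyme cuts exactly once in the region."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.enzyme] = counts.get(s.enzyme, 0) + 1
    return [
        RestrictionSite(s.enzyme, s.start, s.strand, s.length,
                        unique_in_region=counts[s.enzyme] == 1)
        for s in sites
    ]


def spacer_restriction_sites(
    pair: TalenPair, enzymes: Sequence[EnzymeDef], min_site_len: int = 1
) -> list[RestrictionSite]:
    """Restriction sites fully contained in a TALEN pair's spacer.

    A site in the spacer lets a digest distinguish edited from wild-type
    alleles after NHEJ disrupts it.
    """
    if not pair.spacer_seq:
        return []
    spacer_region = TargetRegion(
        pair.left.chrom, pair.spacer_start, pair.spacer_end, pair.spacer_seq,
        source="coordinates",
    )
    return scan_restriction_sites(spacer_region, enzymes, min_site_len)
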