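"""Candidate discovery: Cas9 target sites, TALEN monomers and pairs, RVDs.

A Cas9 site is 23 bp: a 20 bp protospacer followed by the -NGG protospacer
adjacent motif (PAM).  Protospacer positions are numbered 1..20 from the
5' end, so position 20 is PAM-adjacent.  A TALEN half-site must begin with
T (recognized by the TALE N-terminus); two half-sites on opposite strands
flank a spacer where FokI dimerizes and cuts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from ._dna import gc_fraction, revcomp
from .errors import FormatError, UsageError
from .genome import TargetRegion

log = logging.getLogger(__name__)

CRISPR_SITE_LEN = 23
PROTOSPACER_LEN = 20

#: TALE repeat variable di-residue per base; guanine is NN or NH by kit
RVD_FOR_BASE = {"A": "NI", "C": "HD", "T": "NG"}

FivePrimeConstraint = Literal["none", "GG", "GN_or_NG"]


@dataclass
class CrisprCandidate:
    """One 23 bp Cas9 target site (protospacer + NGG PAM)."""

    chrom: str
    start: int  # 0-based plus-strand genomic start of the 23 bp site
    strand: Literal["+", "-"]
    protospacer: str  # 20-mer, 5'->3' in site orientation
    pam: str  # 3-mer NGG

    @property
    def site(self) -> str:
        return self.protospacer + self.pam

    @property
    def gc_percent(self) -> float:
        return 100.0 * gc_fraction(self.protospacer)

    @property
    def g20(self) -> bool:
        """Guanine at protospacer position 20 (1-based, PAM-adjacent)."""
        return self.protospacer[19] == "G"

    @property
    def end(self) -> int:
        return self.start + CRISPR_SITE_LEN

    @property
    def cut_site(self) -> int:
        """Approximate blunt cut 3 bp 5' of the PAM, as a plus-strand coordinate."""
        return self.start + 17 if self.strand == "+" else self.start + 6


@dataclass
class TalenMonomer:
    """One TALEN half-site; ``sequence`` is 5'->3' on its own strand."""

    chrom: str
    start: int  # 0-based plus-strand start of the footprint
    strand: Literal["+", "-"]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class TalenPair:
    """Left (+) and right (-) half-sites flanking the FokI spacer."""

    left: TalenMonomer
    right: TalenMonomer
    spacer_start: int
    spacer_end: int
    spacer_seq: str

    @property
    def spacer_len(self) -> int:
        return self.spacer_end - self.spacer_start

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.left.start, self.right.end)

    @property
    def cut_site(self) -> int:
        """Middle of the spacer, where the FokI dimer cuts."""
        return (self.spacer_start + self.spacer_end) // 2


def _pam_ok(site: str) -> bool:
    # NGG: position 21 free, 22 and 23 must be G
    return site[21] == "G" and site[22] == "G"


def _five_prime_ok(protospacer: str, constraint: FivePrimeConstraint) -> bool:
    if constraint == "none":
        return True
    if constraint == "GG":
        return protospacer.startswith("GG")
    if constraint == "GN_or_NG":
        return protospacer[0] == "G" or protospacer[1] == "G"
    raise UsageError(f"unknown 5' constraint {constraint!r}")


def scan_crispr(
    region: TargetRegion, five_prime_constraint: FivePrimeConstraint = "none"
) -> list[CrisprCandidate]:
    """Every 23 bp window on either strand ending in -NGG.

    Sites containing N are rejected (N cannot be targeted or synthesized).
    The optional 5' constraint restricts the protospacer start to GG- (T7
    polymerase) or GN-/NG- (U6) for in vitro synthesis.  Overlapping sites
    are all reported.  Candidates carry the plus-strand genomic start of
    the 23 bp window regardless of strand.
    """
    seq = region.sequence
    if len(seq) < CRISPR_SITE_LEN:
        log.warning("region %s shorter than %d bp: no Cas9 sites",
                    region.to_query_string(), CRISPR_SITE_LEN)
        return []
    out: list[CrisprCandidate] = []
    for i in range(len(seq) - CRISPR_SITE_LEN + 1):
        window = seq[i : i + CRISPR_SITE_LEN]
        if "N" in window:
            continue
        for strand, site in (("+", window), ("-", revcomp(window))):
            if not _pam_ok(site):
                continue
            proto = site[:PROTOSPACER_LEN]
            if not _five_prime_ok(proto, five_prime_constraint):
                continue
            out.append(
                CrisprCandidate(
                    chrom=region.chrom,
                    start=region.start + i,
                    strand=strand,  # type: ignore[arg-type]
                    protospacer=proto,
                    pam=site[PROTOSPACER_LEN:],
                )
            )
    return out


def scan_talen_monomers(region: TargetRegion, length: int = 15) -> list[TalenMonomer]:
    """Every N-free window of *length* bp beginning with T on either strand."""
    if not 10 <= length <= 30:
        raise UsageError(f"TALEN half-site length {length} outside 10..30")
    seq = region.sequence
    out: list[TalenMonomer] = []
    for i in range(len(seq) - length + 1):
        window = seq[i : i + length]
        if "N" in window:
            continue
        if window[0] == "T":
            out.append(TalenMonomer(region.chrom, region.start + i, "+", window))
        rc = revcomp(window)
        if rc[0] == "T":
            out.append(TalenMonomer(region.chrom, region.start + i, "-", rc))
    return out


def pair_talens(
    monomers: Sequence[TalenMonomer],
    spacer_min: int = 14,
    spacer_max: int = 20,
    region: TargetRegion | None = None,
) -> list[TalenPair]:
    """All (+ left, - right) half-site combinations with an in-range spacer.

    The spacer is the plus-strand gap strictly between the two footprints;
    the default 14-20 bp range is where FokI dimerizes efficiently.  When
    *region* is given, each pair's plus-strand spacer sequence is sliced
    from it; otherwise ``spacer_seq`` is left empty.
    """
    if spacer_min > spacer_max:
        raise UsageError(f"spacer_min {spacer_min} > spacer_max {spacer_max}")
    plus = sorted((m for m in monomers if m.strand == "+"), key=lambda m: m.start)
    minus = sorted((m for m in monomers if m.strand == "-"), key=lambda m: m.start)
    pairs: list[TalenPair] = []
    for left in plus:
        for right in minus:
            gap = right.start - left.end
            if not spacer_min <= gap <= spacer_max:
                continue
            spacer_seq = ""
            if region is not None:
                spacer_seq = region.sequence[left.end - region.start : right.start - region.start]
            pairs.append(TalenPair(left, right, left.end, right.start, spacer_seq))
    pairs.sort(key=lambda p: (p.left.start, p.right.start))
    return pairs


def cluster_talen_pairs(
    ranked_pairs: Sequence[TalenPair], min_reciprocal_overlap: float = 0.8
) -> list[list[TalenPair]]:
    """Group near-equivalent pairs (e.g. differing only in spacer size).

    Input must already be in rank order (best first).  Two pairs cluster
    when their combined footprints reciprocally overlap by at least
    *min_reciprocal_overlap*; each cluster's first (highest-ranked) member
    is its representative, but every member is retained for detailed
    inspection.
    """
    clusters: list[list[TalenPair]] = []
    for pair in ranked_pairs:
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            if _reciprocal_overlap(pair.footprint, rep.footprint) >= min_reciprocal_overlap:
                cluster.append(pair)
                placed = True
                break
        if not placed:
            clusters.append([pair])
    return clusters


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ovl = min(a[1], b[1]) - max(a[0], b[0])
    if ovl <= 0:
        return 0.0
    return min(ovl / (a[1] - a[0]), ovl / (b[1] - b[0]))


def rvd_string(monomer: TalenMonomer, g_code: Literal["NN", "NH"] = "NN") -> list[str]:
    """RVD codes for a half-site, one per base after the invariant 5' T.

    The leading thymine is read by the TALE N-terminal domain rather than a
    repeat, so it is not RVD-encoded; the array covers positions 2..L.
    NH binds guanine more specifically than NN; the choice follows the
    assembly kit in use.
    """
    seq = monomer.sequence
    if not seq.startswith("T"):
        raise FormatError(f"TALEN half-site must start with T: {seq!r}")
    if g_code not in ("NN", "NH"):
        raise UsageError(f"guanine RVD must be NN or NH, got {g_code!r}")
    code = dict(RVD_FOR_BASE, G=g_code)
    try:
        return [code[b] for b in seq[1:]]
    except KeyError as exc:
        raise FormatError(f"non-ACGT base {exc.args[0]!r} in half-site {seq!r}") from None
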