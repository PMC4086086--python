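"""Rank Cas9 candidates and TALEN pairs by specificity and sequence features.

Both modes order first by off-target severity: a perfect-match off-target
is worse than a mismatched one, so counts cascade n0 -> n1 -> n2
(ascending).  Cas9 candidates are then preferred when their GC content
falls in the empirically effective 45-80% window and when the protospacer
carries a guanine at position 20 (PAM-adjacent), and finally by proximity
to the transcript 5' end — mutations early in the coding sequence are more
likely to produce a null allele.  TALEN pairs order by paired (cleavable)
off-targets before individual half-site occurrences, because FokI cuts
only as a dimer.

The criteria form a strict lexicographic key rather than a weighted score;
ties after every criterion break deterministically by genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .discover import CrisprCandidate, TalenPair
from .errors import UsageError
from .genome import GeneModel, TargetRegion
from .offtargets import OffTargetHit, PairedOffTarget

GC_WINDOW_LOW = 45.0
GC_WINDOW_HIGH = 80.0


@dataclass(frozen=True)
class OffTargetTally:
    """Non-self off-target counts at 0, 1 and 2 mismatches."""

    n0: int = 0
    n1: int = 0
    n2: int = 0

    @classmethod
    def from_hits(cls, hits: Iterable[OffTargetHit]) -> "OffTargetTally":
        counts = [0, 0, 0]
        for h in hits:
            if h.is_self:
                continue
            if h.mismatch_count <= 2:
                counts[h.mismatch_count] += 1
        return cls(*counts)

    def __add__(self, other: "OffTargetTally") -> "OffTargetTally":
        return OffTargetTally(self.n0 + other.n0, self.n1 + other.n1, self.n2 + other.n2)


@dataclass
class RankedTarget:
    """A candidate with its tally, features and final 1-based rank."""

    candidate: CrisprCandidate | TalenPair
    tally: OffTargetTally
    paired_offtargets: int = 0  # TALEN mode only
    transcript_offset: int = 0
    rank: int = 0

    @property
    def gc_percent(self) -> float:
        if isinstance(self.candidate, CrisprCandidate):
            return self.candidate.gc_percent
        raise UsageError("gc_percent applies to Cas9 candidates")

    @property
    def g20(self) -> bool:
        if isinstance(self.candidate, CrisprCandidate):
            return self.candidate.g20
        raise UsageError("g20 applies to Cas9 candidates")


def gc_percent(protospacer: str) -> float:
    """GC content of a 20-mer protospacer, in percent."""
    if len(protospacer) != 20 or any(b not in "ACGT" for b in protospacer):
        raise UsageError("gc_percent expects a 20 bp A/C/G/T protospacer")
    return 100.0 * (protospacer.count("G") + protospacer.count("C")) / 20.0


def gc_in_window(
    gc: float, low: float = GC_WINDOW_LOW, high: float = GC_WINDOW_HIGH
) -> bool:
    """True iff *gc* lies in the effective window, bounds inclusive."""
    if not 0.0 <= gc <= 100.0:
        raise UsageError(f"GC percent {gc} outside 0..100")
    return low <= gc <= high


def transcript_offset(
    position: int, region: TargetRegion, model: GeneModel | None = None
) -> int:
    """Distance (bp) of a plus-strand coordinate from the transcript 5' end.

    With a gene model the offset respects gene strand (a minus-strand
    gene's 5' end is its genomically-right edge); without one, distance
    from the region start.
    """
    if model is not None:
        if model.strand == "+":
            return position - model.tx_start
        return model.tx_end - position
    return position - region.start


def crispr_rank_key(
    tally: OffTargetTally, gc: float, g20: bool, offset: int
) -> tuple:
    """Lexicographic comparison key; smaller sorts better."""
    return (tally.n0, tally.n1, tally.n2, not gc_in_window(gc), not g20, offset)


def talen_rank_key(paired: int, tally: OffTargetTally, offset: int) -> tuple:
    return (paired, tally.n0, tally.n1, tally.n2, offset)


def rank_crispr(
    entries: Sequence[tuple[CrisprCandidate, OffTargetTally]],
    region: TargetRegion,
    model: GeneModel | None = None,
) -> list[RankedTarget]:
    """Total order over Cas9 candidates with computed tallies.

    Key: n0, n1, n2 ascending; GC-in-window then G20 preferred; transcript
    offset ascending; remaining ties by plus-strand coordinate then strand
    (+ before -).
    """
    if model is None and region.model is not None:
        model = region.model
    records = []
    for cand, tally in entries:
        off = transcript_offset(cand.start, region, model)
        records.append(RankedTarget(cand, tally, transcript_offset=off))
    records.sort(
        key=lambda r: crispr_rank_key(
            r.tally, r.candidate.gc_percent, r.candidate.g20, r.transcript_offset  # type: ignore[union-attr]
        )
        + (r.candidate.start, r.candidate.strand)  # type: ignore[union-attr]
    )
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records


def rank_talen(
    entries: Sequence[tuple[TalenPair, OffTargetTally, int]],
    region: TargetRegion,
    model: GeneModel | None = None,
) -> list[RankedTarget]:
    """Total order over TALEN pairs: paired off-targets dominate, then the
    summed half-site tally cascade, then transcript offset, then coordinate."""
    if model is None and region.model is not None:
        model = region.model
    records = []
    for pair, tally, paired_count in entries:
        off = transcript_offset(pair.cut_site, region, model)
        records.append(
            RankedTarget(pair, tally, paired_offtargets=paired_count,
                         transcript_offset=off)
        )
    records.sort(
        key=lambda r: talen_rank_key(r.paired_offtargets, r.tally, r.transcript_offset)
        + (r.candidate.left.start, r.candidate.right.start)  # type: ignore[union-attr]
    )
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records


def quartile_color(rank: int, total: int) -> str:
    """Display bin for a rank: green/yellow/orange/red by quartile."""
    if total <= 0 or rank < 1:
        raise UsageError("rank/total must be positive")
    q = (rank - 1) * 4 // total
    return ("green", "yellow", "orange", "red")[min(q, 3)]
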