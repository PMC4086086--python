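"""Mismatch-tolerant off-target search over a local genome.

The search is seed-and-extend over an exact k-mer index.  Completeness is
guaranteed by the pigeonhole principle: a query of length L matched with at
most m mismatches is split into m+1 disjoint chunks of the index's k-mer
length (requiring (m+1)*k <= L), so at least one chunk must occur exactly
in any admissible hit.  Every candidate locus recovered through a chunk is
then verified base-by-base under the requested mismatch model.

Three Cas9 mismatch models are supported, reflecting published (and
conflicting) findings on sgRNA mismatch tolerance:

``all_upstream``
    mismatches tolerated anywhere in the 20 bp protospacer but never in
    the PAM (the default),
``seed_exact``
    the 11 PAM-proximal protospacer bases (positions 10-20) must match
    exactly — a single mismatch there abolishes cleavage — while up to
    ``max_mm`` mismatches are allowed in positions 1-9,
``perfect_only``
    a fast mode reporting perfect matches only.

In every mode the hit's PAM must itself match -NGG (N free).  TALEN
half-sites are searched with 0-2 mismatches across the whole site, with
the invariant 5' T enforced at the hit locus; opposite-strand hits whose
gap falls in the spacer range form paired off-targets — the loci actually
at risk of cleavage, since FokI cuts only as a dimer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from ._dna import revcomp
from .discover import CRISPR_SITE_LEN, PROTOSPACER_LEN, CrisprCandidate, TalenPair
from .errors import DataError, UsageError
from .genome import Genome

log = logging.getLogger(__name__)

OfftargetMode = Literal["all_upstream", "seed_exact", "perfect_only"]

#: number of PAM-proximal protospacer positions where any mismatch kills cleavage
SEED_REGION_LEN = 11
#: 0-based protospacer index where the seed region begins (positions 10..20)
SEED_REGION_START = PROTOSPACER_LEN - SEED_REGION_LEN


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic occurrence of a query under a mismatch model.

    ``start`` is the 0-based plus-strand coordinate of the full matched
    window (23 bp for Cas9 sites, the half-site length for TALENs);
    mismatch positions are 1-based from the query's 5' end.
    """

    chrom: str
    start: int
    strand: Literal["+", "-"]
    length: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    is_self: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PairedOffTarget:
    """Two opposite-strand TALEN hits within cutting distance of each other."""

    left_hit: OffTargetHit  # plus strand
    right_hit: OffTargetHit  # minus strand
    gap_len: int


@dataclass
class SeedIndex:
    """Exact k-mer postings over the plus strand of a genome.

    Minus-strand queries are served by looking up reverse complements, so
    both strands are searchable from one postings table.
    """

    k: int
    postings: dict[str, list[tuple[str, int]]]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])


def build_index(genome: Genome, k: int) -> SeedIndex:
    """Index every N-free k-mer of the genome's plus strand.

    k between 4 and 16; mismatch search over a query of length L with m
    mismatches requires (m+1)*k <= L, so e.g. k=6 serves 20-mer
    protospacers at 2 mismatches and k=5 serves 15 bp TALEN half-sites.
    """
    if not 4 <= k <= 16:
        raise UsageError(f"index k-mer length {k} outside 4..16")
    if not genome.sequences:
        raise DataError("cannot index an empty genome")
    postings: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            postings.setdefault(kmer, []).append((chrom, i))
    return SeedIndex(k=k, postings=postings)


def index_k_for(query_len: int, max_mm: int) -> int:
    """Largest admissible seed length for pigeonhole-complete search."""
    k = min(16, query_len // (max_mm + 1))
    if k < 4:
        raise UsageError(
            f"query length {query_len} cannot support {max_mm} mismatches "
            "with k-mer seeds >= 4"
        )
    return k


# ---------------------------------------------------------------------------
# window predicates (shared by indexed search and the simple oracle)

def _crispr_window_check(
    window: str, protospacer: str, mode: OfftargetMode, max_mm: int
) -> tuple[int, ...] | None:
    """Mismatch positions if *window* (23 bp, site orientation) is a hit, else None."""
    if len(window) != CRISPR_SITE_LEN or "N" in window:
        return None
    if not (window[21] == "G" and window[22] == "G"):
        return None
    mm = tuple(
        i + 1 for i in range(PROTOSPACER_LEN) if window[i] != protospacer[i]
    )
    if mode == "perfect_only":
        return mm if not mm else None
    if len(mm) > max_mm:
        return None
    if mode == "seed_exact":
        # positions 10..20 (1-based) must be exact
        if any(p > SEED_REGION_START for p in mm):
            return None
        return mm
    if mode == "all_upstream":
        return mm
    raise UsageError(f"unknown off-target mode {mode!r}")


def _talen_window_check(
    window: str, monomer_seq: str, max_mm: int
) -> tuple[int, ...] | None:
    if len(window) != len(monomer_seq) or "N" in window:
        return None
    if window[0] != "T":  # binding requires the 5' thymine at the hit, too
        return None
    mm = tuple(i + 1 for i in range(len(monomer_seq)) if window[i] != monomer_seq[i])
    return mm if len(mm) <= max_mm else None


# ---------------------------------------------------------------------------
# seed-and-extend

def _candidate_starts(
    query: str,
    index: SeedIndex,
    genome: Genome,
    n_chunks: int,
    window_len: int,
) -> set[tuple[str, int, str]]:
    """All (chrom, plus-strand window start, strand) loci sharing at least
    one exact chunk with *query* (site orientation)."""
    k = index.k
    if n_chunks * k > len(query):
        raise UsageError(
            f"index k={k} too long for {n_chunks} disjoint seeds in a "
            f"{len(query)}-mer; rebuild with k <= {len(query) // n_chunks}"
        )
    lengths = genome.lengths
    out: set[tuple[str, int, str]] = set()
    for i in range(n_chunks):
        a = i * k
        chunk = query[a : a + k]
        # plus strand: chunk appears verbatim at (window_start + a)
        for chrom, pos in index.lookup(chunk):
            start = pos - a
            if 0 <= start <= lengths[chrom] - window_len:
                out.add((chrom, start, "+"))
        # minus strand: the chunk's reverse complement appears on the plus
        # strand; in site orientation the chunk sits a bases into the window,
        # which maps to (window_end - a - k) on the plus strand
        for chrom, pos in index.lookup(revcomp(chunk)):
            start = pos + a + k - window_len
            if 0 <= start <= lengths[chrom] - window_len:
                out.add((chrom, start, "-"))
    return out


def _window_in_orientation(genome: Genome, chrom: str, start: int, length: int,
                           strand: str) -> str:
    w = genome.sequences[chrom][start : start + length]
    return w if strand == "+" else revcomp(w)


def find_crispr_offtargets(
    candidate: CrisprCandidate,
    genome: Genome,
    index: SeedIndex,
    mode: OfftargetMode = "all_upstream",
    max_mm: int = 2,
) -> list[OffTargetHit]:
    """All genomic loci matching *candidate* under the requested model.

    The candidate's own locus is returned flagged ``is_self`` so callers
    can display it but exclude it from off-target tallies.
    """
    if mode not in ("all_upstream", "seed_exact", "perfect_only"):
        raise UsageError(f"unknown off-target mode {mode!r}")
    if not 0 <= max_mm <= 3:
        raise UsageError(f"max_mm {max_mm} outside 0..3")
    mm_eff = 0 if mode == "perfect_only" else max_mm
    loci = _candidate_starts(
        candidate.protospacer, index, genome, mm_eff + 1, CRISPR_SITE_LEN
    )
    hits = []
    for chrom, start, strand in loci:
        window = _window_in_orientation(genome, chrom, start, CRISPR_SITE_LEN, strand)
        mm = _crispr_window_check(window, candidate.protospacer, mode, max_mm)
        if mm is None:
            continue
        is_self = (
            chrom == candidate.chrom
            and start == candidate.start
            and strand == candidate.strand
        )
        hits.append(
            OffTargetHit(chrom, start, strand, CRISPR_SITE_LEN,  # type: ignore[arg-type]
                         len(mm), mm, is_self)
        )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def find_talen_monomer_hits(
    monomer_seq: str,
    genome: Genome,
    index: SeedIndex,
    max_mm: int = 2,
    self_locus: tuple[str, int, str] | None = None,
) -> list[OffTargetHit]:
    """All genomic half-site occurrences with <= max_mm mismatches and a 5' T."""
    if not 0 <= max_mm <= 2:
        raise UsageError(f"TALEN max_mm {max_mm} outside 0..2")
    L = len(monomer_seq)
    loci = _candidate_starts(monomer_seq, index, genome, max_mm + 1, L)
    hits = []
    for chrom, start, strand in loci:
        window = _window_in_orientation(genome, chrom, start, L, strand)
        mm = _talen_window_check(window, monomer_seq, max_mm)
        if mm is None:
            continue
        is_self = self_locus == (chrom, start, strand)
        hits.append(
            OffTargetHit(chrom, start, strand, L, len(mm), mm, is_self)  # type: ignore[arg-type]
        )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def find_talen_offtargets(
    pair: TalenPair,
    genome: Genome,
    index: SeedIndex,
    max_mm: int = 2,
    spacer_min: int = 14,
    spacer_max: int = 20,
) -> tuple[list[OffTargetHit], list[PairedOffTarget]]:
    """Monomer hits for both half-sites plus paired (cleavable) off-targets.

    A paired off-target is any plus-strand hit and minus-strand hit (from
    either half-site's hit list) on the same chromosome whose gap falls in
    the spacer range — FokI does not care which array binds which side.
    The on-target pair itself is excluded.
    """
    left_hits = find_talen_monomer_hits(
        pair.left.sequence, genome, index, max_mm,
        (pair.left.chrom, pair.left.start, "+"),
    )
    right_hits = find_talen_monomer_hits(
        pair.right.sequence, genome, index, max_mm,
        (pair.right.chrom, pair.right.start, "-"),
    )
    all_hits = _dedupe_hits(left_hits + right_hits)
    plus = [h for h in all_hits if h.strand == "+"]
    minus = [h for h in all_hits if h.strand == "-"]
    paired: list[PairedOffTarget] = []
    for h1 in plus:
        for h2 in minus:
            if h1.chrom != h2.chrom:
                continue
            gap = h2.start - h1.end
            if not spacer_min <= gap <= spacer_max:
                continue
            if h1.is_self and h2.is_self:
                continue  # the on-target pair
            paired.append(PairedOffTarget(h1, h2, gap))
    paired.sort(key=lambda p: (p.left_hit.chrom, p.left_hit.start, p.right_hit.start))
    return all_hits, paired


def _dedupe_hits(hits: Iterable[OffTargetHit]) -> list[OffTargetHit]:
    seen: dict[tuple[str, int, str], OffTargetHit] = {}
    for h in hits:
        key = (h.chrom, h.start, h.strand)
        prev = seen.get(key)
        # keep the better (fewer-mismatch, or self-flagged) record
        if prev is None or h.mismatch_count < prev.mismatch_count or (
            h.mismatch_count == prev.mismatch_count and h.is_self and not prev.is_self
        ):
            seen[key] = h
    return sorted(seen.values(), key=lambda h: (h.chrom, h.start, h.strand))


# ---------------------------------------------------------------------------
# brute-force oracles (exhaustive window scans; no seeding)

WindowPredicate = Callable[[str], "tuple[int, ...] | None"]


def brute_force_offtargets(
    query: str,
    genome: Genome,
    predicate: WindowPredicate,
    self_locus: tuple[str, int, str] | None = None,
) -> list[OffTargetHit]:
    """Exhaustive both-strand window scan; the reference the index must match.

    *predicate* receives each window in site orientation and returns the
    1-based mismatch positions for a hit, or None.  Quadratic and meant for
    verification at small scale (queries <= 40 bp, genomes ~100 kb).
    """
    if len(query) > 40:
        raise UsageError("oracle scan limited to queries <= 40 bp")
    L = len(query)
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.sequences.items():
        for start in range(len(seq) - L + 1):
            w = seq[start : start + L]
            for strand, oriented in (("+", w), ("-", revcomp(w))):
                mm = predicate(oriented)
                if mm is None:
                    continue
                hits.append(
                    OffTargetHit(
                        chrom, start, strand, L, len(mm), tuple(mm),  # type: ignore[arg-type]
                        self_locus == (chrom, start, strand),
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def crispr_window_predicate(
    protospacer: str, mode: OfftargetMode, max_mm: int
) -> WindowPredicate:
    """Window predicate matching :func:`find_crispr_offtargets` semantics."""
    return lambda w: _crispr_window_check(w, protospacer, mode, max_mm)


def talen_window_predicate(monomer_seq: str, max_mm: int) -> WindowPredicate:
    return lambda w: _talen_window_check(w, monomer_seq, max_mm)


def brute_force_crispr_offtargets(
    candidate: CrisprCandidate,
    genome: Genome,
    mode: OfftargetMode,
    max_mm: int = 2,
) -> list[OffTargetHit]:
    """Vectorized exhaustive scan for Cas9 queries (no seeding involved).

    Mismatch counts for every window start are accumulated position by
    position over the whole genome, so completeness does not depend on the
    k-mer index; used to cross-check the indexed search at scale.
    """
    proto = candidate.protospacer
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        if n < CRISPR_SITE_LEN:
            continue
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            g = np.frombuffer(s.encode(), dtype=np.uint8)
            nw = n - CRISPR_SITE_LEN + 1
            mm_all = np.zeros(nw, dtype=np.int16)
            mm_seed = np.zeros(nw, dtype=np.int16)
            for j, base in enumerate(proto.encode()):
                neq = g[j : j + nw] != base
                mm_all += neq
                if j >= SEED_REGION_START:
                    mm_seed += neq
            pam_ok = (g[21 : 21 + nw] == ord("G")) & (g[22 : 22 + nw] == ord("G"))
            has_n = np.zeros(nw, dtype=bool)
            is_n = g == ord("N")
            if is_n.any():
                cn = np.concatenate([[0], np.cumsum(is_n)])
                has_n = (cn[CRISPR_SITE_LEN:] - cn[:nw]) > 0
            if mode == "perfect_only":
                sel = mm_all == 0
            elif mode == "seed_exact":
                sel = (mm_seed == 0) & (mm_all <= max_mm)
            else:
                sel = mm_all <= max_mm
            sel &= pam_ok & ~has_n
            for p in np.flatnonzero(sel):
                p = int(p)
                window = s[p : p + CRISPR_SITE_LEN]
                mm = tuple(i + 1 for i in range(PROTOSPACER_LEN) if window[i] != proto[i])
                start = p if strand == "+" else n - p - CRISPR_SITE_LEN
                is_self = (
                    chrom == candidate.chrom
                    and start == candidate.start
                    and strand == candidate.strand
                )
                hits.append(
                    OffTargetHit(chrom, start, strand, CRISPR_SITE_LEN,  # type: ignore[arg-type]
                                 len(mm), mm, is_self)
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits
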