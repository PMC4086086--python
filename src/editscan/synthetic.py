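"""Synthetic genomes with planted target structures and exact truth tables.

Every other module is exercised against genomes built here: a seeded
random background into which known Cas9 sites, mismatch decoys, TALEN
pairs, primer amplicons and enzyme sites are written at chosen positions.
The background is then rejection-scrubbed so that no *accidental*
near-match of any planted query survives — any window within two
mismatches of a planted protospacer (with an NGG context) or TALEN
half-site (with a 5' T) that is not itself a planted locus gets a
background base re-randomized until the genome is clean.  Truth tables
are therefore exact: the planted loci are the only admissible hits, which
the tests verify independently by brute force.

This emulates the combinatorics of a real search space (both strands,
overlapping windows, decoys at controlled mismatch distances) but not
real genome composition — no repeats, isochores or biased k-mer spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._dna import revcomp
from .discover import CRISPR_SITE_LEN, PROTOSPACER_LEN
from .errors import DataError, UsageError
from .genome import GeneModel, Genome

PlantKind = Literal[
    "crispr_site", "crispr_decoy", "talen_monomer", "talen_pair", "talen_decoy",
    "primer_site", "enzyme_site", "other"
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Plant:
    """One concrete plus-strand sequence written at a fixed position.

    ``geometry`` is (left_len, spacer_len, right_len) for TALEN plants.
    ``mismatch_positions`` are 1-based positions (in the source query's
    orientation) where a decoy differs from the plant it derives from.
    """

    kind: PlantKind
    position: int
    payload: str
    strand: Literal["+", "-"] = "+"
    label: str = ""
    mismatch_positions: tuple[int, ...] = ()
    source: str = ""
    geometry: tuple[int, int, int] = ()

    @property
    def end(self) -> int:
        return self.position + len(self.payload)

    def site_sequence(self) -> str:
        """Payload in site orientation (reverse-complemented for '-')."""
        return self.payload if self.strand == "+" else revcomp(self.payload)


@dataclass
class PlantSpec:
    genome_length: int
    seed: int
    plants: list[Plant] = field(default_factory=list)
    chrom: str = "chr1"
    gc_fraction: float = 0.5

    def add(self, plant: Plant) -> "PlantSpec":
        self.plants.append(plant)
        return self


@dataclass
class TruthTable:
    """Per-plant expected outcomes, exact by construction."""

    entries: list[Plant]
    chrom: str

    def of_kind(self, *kinds: PlantKind) -> list[Plant]:
        return [p for p in self.entries if p.kind in kinds]

    def labelled(self, label: str) -> Plant:
        for p in self.entries:
            if p.label == label:
                return p
        raise KeyError(label)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["kind\tlabel\tchrom\tstart_1based\tstrand\tpayload\tmismatches\tsource"]
        for p in self.entries:
            mm = ",".join(map(str, p.mismatch_positions))
            lines.append(
                f"{p.kind}\t{p.label}\t{self.chrom}\t{p.position + 1}\t{p.strand}"
                f"\t{p.payload}\t{mm}\t{p.source}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# -- plant constructors ------------------------------------------------------

def crispr_site_plant(
    position: int, protospacer: str, pam: str = "TGG", label: str = "site"
) -> Plant:
    """An on-target Cas9 site written on the plus strand."""
    if len(protospacer) != PROTOSPACER_LEN:
        raise UsageError("protospacer must be 20 bp")
    if not (len(pam) == 3 and pam[1:] == "GG"):
        raise UsageError("PAM must be NGG")
    return Plant("crispr_site", position, protospacer + pam, "+", label)


def crispr_decoy_plant(
    site: Plant,
    position: int,
    edits: Sequence[tuple[int, str]],
    label: str = "",
    strand: Literal["+", "-"] = "+",
) -> Plant:
    """A copy of a planted site with mismatches at the given protospacer
    positions (1-based from the 5' end); the PAM stays intact."""
    site_seq = site.site_sequence()
    proto = list(site_seq[:PROTOSPACER_LEN])
    for pos1, base in edits:
        if not 1 <= pos1 <= PROTOSPACER_LEN:
            raise UsageError(f"protospacer position {pos1} outside 1..20")
        if proto[pos1 - 1] == base:
            raise UsageError(f"edit at position {pos1} does not change the base")
        proto[pos1 - 1] = base
    edited = "".join(proto) + site_seq[PROTOSPACER_LEN:]
    payload = edited if strand == "+" else revcomp(edited)
    return Plant(
        "crispr_decoy", position, payload, strand,
        label or f"{site.label}_decoy",
        tuple(sorted(p for p, _ in edits)), source=site.label,
    )


def talen_pair_plant(
    position: int,
    left_seq: str,
    spacer_seq: str,
    right_seq: str,
    label: str = "talen",
    kind: PlantKind = "talen_pair",
    source: str = "",
    mismatch_positions: tuple[int, ...] = (),
) -> Plant:
    """A full TALEN target: left half-site + spacer + right half-site.

    Half-sites are given 5'->3' on their own strands (the right one binds
    the minus strand); the payload is the plus-strand concatenation.
    Decoys (``kind="talen_decoy"``) are built the same way with edited
    half-sites.
    """
    if not left_seq.startswith("T") or not right_seq.startswith("T"):
        raise UsageError("TALEN half-sites must start with T")
    payload = left_seq + spacer_seq + revcomp(right_seq)
    return Plant(
        kind, position, payload, "+", label, mismatch_positions, source,
        geometry=(len(left_seq), len(spacer_seq), len(right_seq)),
    )


def talen_monomer_plant(
    position: int, sequence: str, strand: Literal["+", "-"] = "+", label: str = ""
) -> Plant:
    """A lone half-site (e.g. a single re-planted monomer off-target)."""
    if not sequence.startswith("T"):
        raise UsageError("TALEN half-site must start with T")
    payload = sequence if strand == "+" else revcomp(sequence)
    return Plant("talen_monomer", position, payload, strand, label,
                 geometry=(len(sequence), 0, 0))


def sequence_plant(position: int, payload: str, label: str = "",
                   kind: PlantKind = "other") -> Plant:
    """An arbitrary verbatim plus-strand sequence (primer site, enzyme site...)."""
    return Plant(kind, position, payload, "+", label)


def talen_half_sites(plant: Plant) -> list[tuple[str, int, str]]:
    """(sequence 5'->3' on its strand, plus-strand start, strand) for each
    half-site of a TALEN plant."""
    if plant.kind == "talen_monomer":
        return [(plant.site_sequence(), plant.position, plant.strand)]
    if plant.kind not in ("talen_pair", "talen_decoy"):
        return []
    ll, sl, rl = plant.geometry
    left = plant.payload[:ll]
    right = revcomp(plant.payload[ll + sl :])
    return [(left, plant.position, "+"), (right, plant.position + ll + sl, "-")]


# -- genome synthesis --------------------------------------------------------

def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mismatch_counts(g: np.ndarray, query: bytes) -> np.ndarray:
    """Mismatch count of *query* against every window start of byte array *g*."""
    L = len(query)
    n = len(g) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for j, b in enumerate(query):
        mm += g[j : j + n] != b
    return mm


def _both_strand_views(g: np.ndarray) -> list[tuple[str, np.ndarray]]:
    rc = np.frombuffer(revcomp(g.tobytes().decode()).encode(), dtype=np.uint8)
    return [("+", g), ("-", rc)]


def _accidental(
    g: np.ndarray,
    query: str,
    window_len: int,
    allowed: set[tuple[int, str]],
    require_pam: bool,
    require_t: bool,
    max_mm: int = 2,
) -> list[tuple[int, int]]:
    """(plus-strand window start, window length) of unintended near-matches."""
    out = []
    n = len(g)
    q = query.encode()
    for strand, s in _both_strand_views(g):
        mm = _mismatch_counts(s, q)
        lim = min(len(mm), n - window_len + 1)
        for p in np.flatnonzero(mm[:lim] <= max_mm):
            p = int(p)
            if require_pam and not (
                s[p + 21] == ord("G") and s[p + 22] == ord("G")
            ):
                continue
            if require_t and s[p] != ord("T"):
                continue
            start = p if strand == "+" else n - p - window_len
            if (start, strand) not in allowed:
                out.append((start, window_len))
    return out


def synth_genome(spec: PlantSpec) -> tuple[Genome, TruthTable]:
    """Build the genome described by *spec*; deterministic in the seed.

    Raises on overlapping plants.  After plants are written, the
    background is scrubbed until no accidental near-match (see module
    docstring) survives outside the planted loci.
    """
    rng = np.random.default_rng(spec.seed)
    plants = sorted(spec.plants, key=lambda p: p.position)
    for a, b in zip(plants, plants[1:]):
        if b.position < a.end:
            raise DataError(
                f"overlapping plants {a.label or a.kind}@{a.position} and "
                f"{b.label or b.kind}@{b.position}"
            )
    if plants and plants[-1].end > spec.genome_length:
        raise DataError("plant extends past genome end")
    if plants and plants[0].position < 0:
        raise DataError("plant at negative position")
    g = _random_background(rng, spec.genome_length, spec.gc_fraction)
    occupied = np.zeros(spec.genome_length, dtype=bool)
    for p in plants:
        g[p.position : p.end] = np.frombuffer(p.payload.encode(), dtype=np.uint8)
        occupied[p.position : p.end] = True

    # Any planted Cas9 locus (site or decoy, either strand) is exempt from
    # scrubbing for every planted protospacer; mismatch accounting per decoy
    # is asserted downstream, not here.
    crispr_loci: set[tuple[int, str]] = set()
    crispr_queries: set[str] = set()
    for p in plants:
        if p.kind in ("crispr_site", "crispr_decoy"):
            crispr_loci.add((p.position, p.strand))
        if p.kind == "crispr_site":
            crispr_queries.add(p.site_sequence()[:PROTOSPACER_LEN])
    talen_loci: set[tuple[int, str]] = set()
    talen_queries: set[str] = set()
    for p in plants:
        for seq, start, strand in talen_half_sites(p):
            talen_loci.add((start, strand))
            if p.kind in ("talen_pair", "talen_monomer"):
                talen_queries.add(seq)

    for _round in range(500):
        offenders: list[tuple[int, int]] = []
        for proto in crispr_queries:
            offenders += _accidental(
                g, proto, CRISPR_SITE_LEN, crispr_loci,
                require_pam=True, require_t=False,
            )
        for monomer in talen_queries:
            offenders += _accidental(
                g, monomer, len(monomer), talen_loci,
                require_pam=False, require_t=True,
            )
        if not offenders:
            break
        start, wlen = offenders[0]
        free = [i for i in range(max(0, start), min(start + wlen, spec.genome_length))
                if not occupied[i]]
        if not free:
            raise DataError(
                "accidental near-match lies entirely within planted sequence; "
                "adjust the plant layout"
            )
        i = free[int(rng.integers(len(free)))]
        old = g[i]
        choices = _BASES[_BASES != old]
        g[i] = choices[int(rng.integers(len(choices)))]
    else:
        raise DataError("background scrubbing did not converge")

    genome = Genome({spec.chrom: g.tobytes().decode()})
    return genome, TruthTable(entries=list(plants), chrom=spec.chrom)


def synth_gene_table(genome: Genome, n_genes: int, seed: int) -> list[GeneModel]:
    """Non-overlapping multi-exon coding gene models on both strands."""
    if n_genes < 0:
        raise UsageError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    chrom, seq = next(iter(genome.sequences.items()))
    slot = len(seq) // n_genes
    if slot < 600:
        raise DataError(
            f"genome too small for {n_genes} genes (needs >= {600 * n_genes} bp)"
        )
    models = []
    for i in range(n_genes):
        lo = i * slot + 50
        hi = (i + 1) * slot - 50
        n_exons = int(rng.integers(2, 5))
        exons = []
        pos = lo
        for _ in range(n_exons):
            ex_len = int(rng.integers(100, 250))
            if pos + ex_len > hi:
                break
            exons.append((pos, pos + ex_len))
            pos += ex_len + int(rng.integers(80, 300))
        if len(exons) < 2:
            exons = [(lo, lo + 150), (lo + 250, lo + 400)]
        strand = "+" if rng.integers(2) == 0 else "-"
        cds_start = exons[0][0] + int(rng.integers(10, 50))
        cds_end = exons[-1][1] - int(rng.integers(10, 50))
        models.append(
            GeneModel(f"gene{i + 1}", f"tx{i + 1}", chrom, strand,  # type: ignore[arg-type]
                      exons, cds_start, cds_end)
        )
    return models


# -- plain-text writers (fixtures are generated at run time, never stored) ---

def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_table(models: Sequence[GeneModel], path: str | Path) -> None:
    """refFlat (UCSC 11-column) dump of gene models."""
    lines = []
    for m in models:
        starts = ",".join(str(s) for s, _ in m.exons) + ","
        ends = ",".join(str(e) for _, e in m.exons) + ","
        cs = m.cds_start if m.cds_start is not None else m.tx_end
        ce = m.cds_end if m.cds_end is not None else m.tx_end
        lines.append(
            f"{m.gene_name}\t{m.transcript_id}\t{m.chrom}\t{m.strand}\t"
            f"{m.tx_start}\t{m.tx_end}\t{cs}\t{ce}\t{len(m.exons)}\t{starts}\t{ends}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
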