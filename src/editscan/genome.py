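"""Genome and gene-model input, query resolution, gene sub-regions.

Internal coordinates are 0-based half-open throughout the package; the
user-facing query grammar ``chrom:start-end`` is 1-based inclusive, the way
genome-browser users write coordinates.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from ._dna import is_dna
from .errors import FormatError, QueryError, RangeError

log = logging.getLogger(__name__)

_COORD_RE = re.compile(r"^([\w.\-]+):([\d,]+)-([\d,]+)$")

# IUPAC degenerate letters other than N are not usable as targets; they are
# collapsed to N on load (with a warning) so downstream scanning only ever
# sees A/C/G/T/N.
_NON_ACGTN = re.compile(r"[RYSWKMBDHV]")


@dataclass
class Genome:
    """Named DNA sequences; the search universe for every downstream step."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Extract ``[start, end)`` from *chrom* (0-based half-open)."""
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise QueryError(f"unknown sequence {chrom!r}") from None
        if start < 0 or end > len(seq) or end <= start:
            raise RangeError(
                f"{chrom}:{start}-{end} outside sequence bounds (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneModel:
    """One transcript: strand, exon structure and optional CDS."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = exons

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return (
            self.cds_start is not None
            and self.cds_end is not None
            and self.cds_end > self.cds_start
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' on the transcript (reversed for minus strand)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class TargetRegion:
    """A resolved stretch of DNA to scan for target sites.

    ``intervals`` carries the genomic sub-intervals selected by a
    sub-region filter (exons, UTRs, ...); candidates are later restricted
    to lie inside them.  ``None`` means the whole region.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    source: Literal["gene", "coordinates", "raw"]
    intervals: list[tuple[int, int]] | None = None
    model: GeneModel | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RangeError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start:
            raise FormatError("sequence length does not match region bounds")

    def to_query_string(self) -> str:
        """1-based inclusive ``chrom:start-end`` form of this region."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class SubRegion:
    """Gene sub-region filter: UTRs, CDS, exons, splice-site windows, or a
    1-based exon subset in transcript orientation."""

    kind: Literal[
        "five_prime_utr", "three_prime_utr", "splice_sites", "exons", "exon_subset", "cds"
    ]
    exon_indices: tuple[int, ...] = ()
    splice_half_width: int = 20

    @classmethod
    def parse(cls, text: str) -> "SubRegion":
        """Parse CLI spellings like ``exons``, ``5utr``, ``exon:1,3``."""
        text = text.strip().lower()
        aliases = {
            "5utr": "five_prime_utr",
            "3utr": "three_prime_utr",
            "utr5": "five_prime_utr",
            "utr3": "three_prime_utr",
            "splice": "splice_sites",
        }
        text_key = aliases.get(text, text)
        if text_key in ("five_prime_utr", "three_prime_utr", "splice_sites", "exons", "cds"):
            return cls(kind=text_key)  # type: ignore[arg-type]
        m = re.match(r"^exons?:([\d,]+)$", text)
        if m:
            idx = tuple(int(x) for x in m.group(1).split(",") if x)
            return cls(kind="exon_subset", exon_indices=idx)
        raise QueryError(f"unrecognized sub-region filter {text!r}")


def load_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    Sequences are uppercased; degenerate IUPAC letters other than N are
    mapped to N with a warning.  Duplicate record names and empty files are
    format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    sequences: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises ValueError subclasses
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    for rec in records:
        name = rec.id
        if name in sequences:
            raise FormatError(f"duplicate sequence name {name!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {name!r}")
        if _NON_ACGTN.search(seq):
            log.warning(
                "record %s contains degenerate IUPAC bases; mapping them to N", name
            )
            seq = _NON_ACGTN.sub("N", seq)
        if not is_dna(seq):
            raise FormatError(f"record {name!r} contains non-DNA characters")
        sequences[name] = seq
    return Genome(sequences)


def _parse_refflat_row(fields: Sequence[str]) -> GeneModel:
    # geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds
    gene, tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    cds_start, cds_end = int(fields[6]), int(fields[7])
    starts = [int(x) for x in fields[9].rstrip(",").split(",")]
    ends = [int(x) for x in fields[10].rstrip(",").split(",")]
    exons = list(zip(starts, ends))
    cds = (cds_start, cds_end) if cds_end > cds_start else (None, None)
    return GeneModel(gene, tx, chrom, strand, exons, cds[0], cds[1])  # type: ignore[arg-type]


def _parse_bed12_row(fields: Sequence[str]) -> GeneModel:
    chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")][:n_blocks]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")][:n_blocks]
    exons = [(start + off, start + off + size) for off, size in zip(offsets, sizes)]
    cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
    return GeneModel(name, name, chrom, strand, exons, cds[0], cds[1])  # type: ignore[arg-type]


def load_gene_table(
    path: str | Path, format: Literal["refFlat", "bed12"] = "refFlat"
) -> list[GeneModel]:
    """Parse a refFlat (UCSC 11-column) or BED12 gene table.

    Rows that fail to parse (e.g. overlapping exons) are skipped with a
    warning rather than aborting the whole table.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene table not found: {path}")
    parser = {"refFlat": _parse_refflat_row, "bed12": _parse_bed12_row}.get(format)
    if parser is None:
        raise FormatError(f"unknown gene table format {format!r}")
    n_cols = {"refFlat": 11, "bed12": 12}[format]
    models: list[GeneModel] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < n_cols:
            log.warning("%s line %d: expected %d columns, got %d; skipped",
                        path.name, i, n_cols, len(fields))
            continue
        try:
            models.append(parser(fields))
        except (ValueError, FormatError) as exc:
            log.warning("%s line %d: %s; row skipped", path.name, i, exc)
    return models


def _select_transcript(models: Iterable[GeneModel], name: str) -> GeneModel:
    """Longest transcript by exonic length among those matching *name*."""
    hits = [m for m in models if m.gene_name == name or m.transcript_id == name]
    if not hits:
        universe = {m.gene_name for m in models} | {m.transcript_id for m in models}
        near = difflib.get_close_matches(name, sorted(universe), n=5)
        hint = f"; close matches: {', '.join(near)}" if near else ""
        raise QueryError(f"unknown gene {name!r}{hint}")
    chosen = max(hits, key=lambda m: (m.exonic_length, m.transcript_id))
    if len(hits) > 1:
        log.info(
            "gene %s has %d transcripts; using longest by exonic length (%s)",
            name, len(hits), chosen.transcript_id,
        )
    return chosen


def extract_subregion(model: GeneModel, filter: SubRegion) -> list[tuple[int, int]]:
    """Genomic intervals (0-based half-open, sorted) selected by *filter*.

    Exon-subset indices are 1-based in transcript orientation: exon 1 is the
    5'-most exon of the transcript, i.e. the last genomic exon for a
    minus-strand gene.  UTR/CDS filters on non-coding models return an
    empty list with a warning.
    """
    kind = filter.kind
    if kind == "exons":
        return list(model.exons)
    if kind == "exon_subset":
        tx_exons = model.exons_transcript_order()
        out = []
        for idx in filter.exon_indices:
            if not 1 <= idx <= len(tx_exons):
                raise RangeError(
                    f"exon index {idx} out of range for {model.transcript_id} "
                    f"({len(tx_exons)} exons)"
                )
            out.append(tx_exons[idx - 1])
        return sorted(out)
    if kind == "splice_sites":
        w = filter.splice_half_width
        boundaries: list[int] = []
        for s, e in model.exons:
            if s != model.tx_start:
                boundaries.append(s)
            if e != model.tx_end:
                boundaries.append(e)
        return [(max(0, b - w), b + w) for b in sorted(set(boundaries))]
    if kind in ("five_prime_utr", "three_prime_utr", "cds"):
        if not model.is_coding:
            log.warning("%s filter on non-coding model %s: empty result",
                        kind, model.transcript_id)
            return []
        cs, ce = model.cds_start, model.cds_end
        assert cs is not None and ce is not None
        if kind == "cds":
            lo, hi = cs, ce
        elif (kind == "five_prime_utr") == (model.strand == "+"):
            lo, hi = model.tx_start, cs  # genomically-left UTR
        else:
            lo, hi = ce, model.tx_end  # genomically-right UTR
        out = []
        for s, e in model.exons:
            s2, e2 = max(s, lo), min(e, hi)
            if e2 > s2:
                out.append((s2, e2))
        return out
    raise QueryError(f"unknown sub-region filter kind {kind!r}")


MIN_RAW_QUERY_LEN = 23  # shortest sequence that can hold one full Cas9 site


def resolve_query(
    query: str,
    genome: Genome,
    models: Sequence[GeneModel] = (),
    sub_region: SubRegion | None = None,
) -> TargetRegion:
    """Resolve a gene name, ``chrom:start-end`` string or raw DNA to a region.

    Coordinate queries are 1-based inclusive (as users write them) and are
    converted to 0-based half-open.  Raw sequence yields a region with
    ``chrom="query"`` starting at 0.  Gene queries use the longest
    transcript and may be narrowed by *sub_region*.
    """
    query = query.strip()
    m = _COORD_RE.match(query)
    if m and m.group(1) in genome:
        chrom = m.group(1)
        start = int(m.group(2).replace(",", "")) - 1
        end = int(m.group(3).replace(",", ""))
        seq = genome.slice(chrom, start, end)
        return TargetRegion(chrom, start, end, seq, source="coordinates")

    upper = query.upper()
    if is_dna(upper) and not (models and any(
            m_.gene_name == query or m_.transcript_id == query for m_ in models)):
        if len(upper) < MIN_RAW_QUERY_LEN:
            raise RangeError(
                f"raw sequence of length {len(upper)} is shorter than the minimum "
                f"target site ({MIN_RAW_QUERY_LEN} bp)"
            )
        return TargetRegion("query", 0, len(upper), upper, source="raw")

    if re.match(r"^[A-Za-z*]+$", query) and not models and query not in genome:
        # looks like a sequence attempt with bad characters, no gene table to consult
        if not is_dna(upper):
            raise FormatError(f"query contains non-DNA characters: {query!r}")

    model = _select_transcript(models, query)
    if model.chrom not in genome:
        raise QueryError(
            f"gene {query!r} is on {model.chrom}, absent from the genome"
        )
    intervals: list[tuple[int, int]] | None = None
    start, end = model.tx_start, model.tx_end
    if sub_region is not None:
        intervals = extract_subregion(model, sub_region)
        if not intervals:
            raise QueryError(
                f"sub-region filter {sub_region.kind} selects nothing in {query!r}"
            )
        start, end = intervals[0][0], intervals[-1][1]
    seq = genome.slice(model.chrom, start, end)
    return TargetRegion(
        model.chrom, start, end, seq, source="gene", intervals=intervals, model=model
    )
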