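"""Writers for results tables, off-target details and annotated GenBank files.

All user-facing coordinates are 1-based inclusive; GenBank features use
``complement()`` for minus-strand locations.  Output is deterministic:
identical inputs produce byte-identical files (the GenBank record date is
pinned).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .discover import CrisprCandidate, TalenPair, rvd_string
from .errors import RangeError
from .genome import TargetRegion
from .genotyping import PrimerPair, RestrictionSite, spacer_restriction_sites
from .offtargets import OffTargetHit
from .ranking import RankedTarget

log = logging.getLogger(__name__)

_GENBANK_DATE = "01-JAN-1980"  # pinned so reruns are byte-identical

CRISPR_COLUMNS = [
    "rank", "target_seq", "chrom", "start_1based", "strand", "exon",
    "gc_percent", "g20", "mm0", "mm1", "mm2",
]
TALEN_COLUMNS = [
    "rank", "left_seq", "right_seq", "chrom", "start_1based", "spacer_len",
    "rvds_left", "rvds_right", "spacer_enzymes", "paired_offtargets",
    "mm0", "mm1", "mm2",
]


def _exon_number(position: int, region: TargetRegion) -> str:
    """1-based transcript-order exon index containing *position*, or ''."""
    model = region.model
    if model is None:
        return ""
    for i, (s, e) in enumerate(model.exons_transcript_order(), start=1):
        if s <= position < e:
            return str(i)
    return ""


def crispr_results_frame(ranked: Sequence[RankedTarget],
                         region: TargetRegion) -> pd.DataFrame:
    rows = []
    for r in ranked:
        c = r.candidate
        assert isinstance(c, CrisprCandidate)
        rows.append({
            "rank": r.rank,
            "target_seq": c.site,
            "chrom": c.chrom,
            "start_1based": c.start + 1,
            "strand": c.strand,
            "exon": _exon_number(c.start, region),
            "gc_percent": round(c.gc_percent, 1),
            "g20": int(c.g20),
            "mm0": r.tally.n0,
            "mm1": r.tally.n1,
            "mm2": r.tally.n2,
        })
    return pd.DataFrame(rows, columns=CRISPR_COLUMNS)


def talen_results_frame(
    ranked: Sequence[RankedTarget],
    region: TargetRegion,
    g_code: str = "NN",
    enzymes: Sequence = (),
) -> pd.DataFrame:
    rows = []
    for r in ranked:
        p = r.candidate
        assert isinstance(p, TalenPair)
        spacer_enz = sorted(
            {s.enzyme for s in spacer_restriction_sites(p, enzymes)}
        ) if enzymes else []
        rows.append({
            "rank": r.rank,
            "left_seq": p.left.sequence,
            "right_seq": p.right.sequence,
            "chrom": p.left.chrom,
            "start_1based": p.left.start + 1,
            "spacer_len": p.spacer_len,
            "rvds_left": "-".join(rvd_string(p.left, g_code)),  # type: ignore[arg-type]
            "rvds_right": "-".join(rvd_string(p.right, g_code)),  # type: ignore[arg-type]
            "spacer_enzymes": ",".join(spacer_enz),
            "paired_offtargets": r.paired_offtargets,
            "mm0": r.tally.n0,
            "mm1": r.tally.n1,
            "mm2": r.tally.n2,
        })
    return pd.DataFrame(rows, columns=TALEN_COLUMNS)


def write_results_table(frame: pd.DataFrame, path: str | Path) -> None:
    """TSV dump of a results frame (header always present)."""
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_offtarget_table(hits: Sequence[OffTargetHit], path: str | Path) -> None:
    """Detailed per-candidate off-target list."""
    rows = [{
        "chrom": h.chrom,
        "start_1based": h.start + 1,
        "strand": h.strand,
        "mismatches": h.mismatch_count,
        "positions": ",".join(map(str, h.mismatch_positions)),
        "is_self": int(h.is_self),
    } for h in hits]
    pd.DataFrame(
        rows, columns=["chrom", "start_1based", "strand", "mismatches",
                       "positions", "is_self"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_primer_table(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    rows = [{
        "rank": p.specificity_rank,
        "left_seq": p.left_seq,
        "right_seq": p.right_seq,
        "tm_left": p.tm_left,
        "tm_right": p.tm_right,
        "product_size": p.product_size,
        "off_products": p.off_products,
        "left_hits": p.left_hits,
        "right_hits": p.right_hits,
    } for p in pairs]
    pd.DataFrame(
        rows, columns=["rank", "left_seq", "right_seq", "tm_left", "tm_right",
                       "product_size", "off_products", "left_hits", "right_hits"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _feature(start: int, end: int, strand: int | None, ftype: str,
             qualifiers: dict) -> SeqFeature:
    return SeqFeature(
        SimpleLocation(start, end, strand), type=ftype,
        qualifiers={k: [v] for k, v in qualifiers.items()},
    )


def _region_features(
    region: TargetRegion,
    targets: Sequence[RankedTarget] = (),
    primers: Sequence[PrimerPair] = (),
    sites: Sequence[RestrictionSite] = (),
) -> list[SeqFeature]:
    off = region.start
    feats: list[SeqFeature] = []
    for r in targets:
        c = r.candidate
        if isinstance(c, CrisprCandidate):
            lo, hi, strand = c.start, c.end, 1 if c.strand == "+" else -1
            label = f"sgRNA_rank_{r.rank}"
        else:
            lo, hi, strand = c.footprint[0], c.footprint[1], 1
            label = f"TALEN_rank_{r.rank}"
        _check_bounds(lo, hi, region)
        feats.append(_feature(lo - off, hi - off, strand, "misc_feature",
                              {"label": label}))
    for p in primers:
        _check_bounds(p.left_start, p.right_end, region)
        feats.append(_feature(p.left_start - off, p.left_end - off, 1,
                              "primer_bind", {"label": f"primer_F{p.specificity_rank}"}))
        feats.append(_feature(p.right_start - off, p.right_end - off, -1,
                              "primer_bind", {"label": f"primer_R{p.specificity_rank}"}))
    for s in sites:
        _check_bounds(s.start, s.end, region)
        feats.append(_feature(
            s.start - off, s.end - off, 1 if s.strand == "+" else -1,
            "misc_feature",
            {"label": s.enzyme,
             "note": "unique in region" if s.unique_in_region else "multiple in region"},
        ))
    return feats


def _check_bounds(lo: int, hi: int, region: TargetRegion) -> None:
    if lo < region.start or hi > region.end:
        raise RangeError(
            f"feature {lo}-{hi} outside region {region.to_query_string()}"
        )


def write_genbank(
    region: TargetRegion,
    path: str | Path,
    targets: Sequence[RankedTarget] = (),
    primers: Sequence[PrimerPair] = (),
    sites: Sequence[RestrictionSite] = (),
    include_introns: bool = True,
) -> None:
    """GenBank flat file of the region annotated with designs.

    With ``include_introns=False`` (requires a gene model) the exons are
    spliced together and feature coordinates remapped; features that cross
    an exon boundary are dropped with a warning.
    """
    feats = _region_features(region, targets, primers, sites)
    name = region.chrom[:16] or "region"
    if include_introns or region.model is None:
        seq, out_feats = region.sequence, feats
    else:
        exons = [(max(s, region.start), min(e, region.end))
                 for s, e in region.model.exons
                 if min(e, region.end) > max(s, region.start)]
        seq = "".join(
            region.sequence[s - region.start : e - region.start] for s, e in exons
        )
        # map genomic -> spliced coordinates
        offsets = []
        acc = 0
        for s, e in exons:
            offsets.append((s, e, acc))
            acc += e - s
        out_feats = []
        for f in feats:
            lo, hi = int(f.location.start) + region.start, int(f.location.end) + region.start
            for s, e, base in offsets:
                if s <= lo and hi <= e:
                    out_feats.append(SeqFeature(
                        SimpleLocation(base + lo - s, base + hi - s, f.location.strand),
                        type=f.type, qualifiers=f.qualifiers,
                    ))
                    break
            else:
                log.debug("feature %s spans an exon boundary; dropped from "
                          "intron-less GenBank", f.qualifiers.get("label"))
        name = f"{name}_spliced"[:16]
    record = SeqRecord(
        Seq(seq), id=region.chrom, name=name,
        description=f"designed targets in {region.to_query_string()}",
        features=out_feats,
        annotations={"molecule_type": "DNA", "date": _GENBANK_DATE,
                     "topology": "linear"},
    )
    SeqIO.write(record, str(path), "genbank")
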