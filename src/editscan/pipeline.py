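"""End-to-end design runs: configuration plus the orchestration the CLI wraps.

A run resolves the query, discovers candidates, searches off-targets,
ranks, designs genotyping aids for the best candidates and writes the
report files.  Everything is deterministic for a fixed config and inputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Literal, Sequence

from . import discover, genotyping, offtargets, ranking, report
from .enzymes import EnzymeDef, builtin_enzymes, load_enzyme_table
from .errors import UsageError
from .genome import (Genome, GeneModel, SubRegion, TargetRegion, load_fasta,
                     load_gene_table, resolve_query)
from .genotyping import PrimerOptions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a design run; serializable to a key=value config file."""

    query: str = ""
    genome_path: str = ""
    gene_table_path: str = ""
    gene_table_format: Literal["refFlat", "bed12"] = "refFlat"
    mode: Literal["crispr", "talen"] = "crispr"
    offtarget_mode: offtargets.OfftargetMode = "all_upstream"
    max_mm: int = 2
    five_prime_constraint: discover.FivePrimeConstraint = "none"
    spacer_min: int = 14
    spacer_max: int = 20
    monomer_length: int = 15
    g_code: Literal["NN", "NH"] = "NN"
    sub_region: str = ""
    primer: PrimerOptions = field(default_factory=PrimerOptions)
    enzyme_table_path: str = ""
    enzyme_supplier: str = ""
    min_site_len: int = 4
    primer_targets: int = 1  # design primers for this many top-ranked targets
    out_dir: str = "editscan_out"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("crispr", "talen"):
            raise UsageError(f"unknown mode {self.mode!r}")
        if self.offtarget_mode not in ("all_upstream", "seed_exact", "perfect_only"):
            raise UsageError(f"unknown off-target mode {self.offtarget_mode!r}")
        if not 0 <= self.max_mm <= 3:
            raise UsageError("max_mm outside 0..3")
        if self.mode == "talen" and self.max_mm > 2:
            raise UsageError("TALEN off-target search supports at most 2 mismatches")
        if self.spacer_min > self.spacer_max:
            raise UsageError(
                f"spacer_min {self.spacer_min} > spacer_max {self.spacer_max}"
            )
        if not 10 <= self.monomer_length <= 30:
            raise UsageError("monomer_length outside 10..30")
        self.primer.validate()

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "primer":
                for pf in fields(PrimerOptions):
                    lines.append(f"primer.{pf.name}={getattr(v, pf.name)}")
            else:
                lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        popts = cfg.primer
        casts = {f.name: f for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key.startswith("primer."):
                pname = key[len("primer."):]
                cur = getattr(popts, pname)
                setattr(popts, pname, _cast_like(cur, val))
            elif key in casts:
                cur = getattr(cfg, key)
                setattr(cfg, key, _cast_like(cur, val))
        return cfg


def _cast_like(current, val: str):
    if isinstance(current, bool):
        return val.lower() in ("1", "true", "yes")
    if current is None or val == "None":
        return None if val == "None" else int(val)
    if isinstance(current, int):
        return int(val)
    if isinstance(current, float):
        return float(val)
    return val


@dataclass
class RunResult:
    region: TargetRegion
    ranked: list[ranking.RankedTarget]
    offtarget_hits: dict[int, list[offtargets.OffTargetHit]]  # keyed by rank
    primer_pairs: list[genotyping.PrimerPair]
    restriction_sites: list[genotyping.RestrictionSite]
    out_dir: Path | None = None


def _load_enzymes(config: RunConfig) -> list[EnzymeDef]:
    if config.enzyme_table_path:
        enzymes = load_enzyme_table(config.enzyme_table_path)
        if config.enzyme_supplier:
            enzymes = [e for e in enzymes
                       if config.enzyme_supplier in e.supplier_tags]
        return enzymes
    return builtin_enzymes(config.enzyme_supplier or None)


def _within_intervals(lo: int, hi: int, region: TargetRegion) -> bool:
    if region.intervals is None:
        return True
    return any(s <= lo and hi <= e for s, e in region.intervals)


def run(
    config: RunConfig,
    genome: Genome | None = None,
    models: Sequence[GeneModel] | None = None,
    write_files: bool = True,
) -> RunResult:
    """Execute a full design run; optionally write the report files.

    *genome* and *models* may be passed directly (e.g. synthetic fixtures)
    instead of being loaded from the configured paths.
    """
    config.validate()
    if genome is None:
        if not config.genome_path:
            raise UsageError("no genome supplied")
        genome = load_fasta(config.genome_path)
    if models is None:
        models = (load_gene_table(config.gene_table_path, config.gene_table_format)
                  if config.gene_table_path else [])
    sub = SubRegion.parse(config.sub_region) if config.sub_region else None
    region = resolve_query(config.query, genome, models, sub)
    search_genome = genome
    if region.source == "raw":
        # pasted sequence: off-targets are searched within the paste itself
        search_genome = Genome({"query": region.sequence})

    enzymes = _load_enzymes(config)

    if config.mode == "crispr":
        result = _run_crispr(config, region, search_genome)
    else:
        result = _run_talen(config, region, search_genome)

    sites = genotyping.classify_uniqueness(
        genotyping.scan_restriction_sites(region, enzymes, config.min_site_len),
        region,
    )
    result.restriction_sites = sites

    # primers around the cut site of the top-ranked candidates
    primer_index = offtargets.build_index(
        search_genome, min(16, max(4, config.primer.min_len // 2))
    )
    primer_pairs: list[genotyping.PrimerPair] = []
    for r in result.ranked[: config.primer_targets]:
        cut = r.candidate.cut_site
        ctx_lo = max(0, cut - config.primer.max_product)
        ctx_hi = min(len(search_genome.sequences[region.chrom])
                     if region.chrom in search_genome else region.end,
                     cut + config.primer.max_product)
        chrom = region.chrom if region.chrom in search_genome else "query"
        ctx = TargetRegion(
            chrom, ctx_lo, ctx_hi,
            search_genome.slice(chrom, ctx_lo, ctx_hi), source="coordinates",
        )
        pairs = genotyping.design_primer_pairs(ctx, cut, config.primer)
        pairs = genotyping.rank_primer_pairs(pairs, search_genome, primer_index,
                                             config.primer)
        primer_pairs.extend(pairs)
        break  # report primers for the best target; others via API
    result.primer_pairs = primer_pairs

    if write_files:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.mode == "crispr":
            frame = report.crispr_results_frame(result.ranked, region)
        else:
            frame = report.talen_results_frame(result.ranked, region,
                                               config.g_code, enzymes)
        report.write_results_table(frame, out / "results.tsv")
        detail_dir = out / "offtargets"
        detail_dir.mkdir(exist_ok=True)
        for r in result.ranked:
            hits = result.offtarget_hits.get(r.rank, [])
            report.write_offtarget_table(hits, detail_dir / f"rank{r.rank:04d}.tsv")
        report.write_primer_table(primer_pairs, out / "primers.tsv")
        # primer context can extend past the displayed region; annotate only
        # the pairs that fit inside it
        gb_primers = [p for p in primer_pairs
                      if p.left_start >= region.start and p.right_end <= region.end]
        report.write_genbank(region, out / "region.gb", targets=result.ranked,
                             primers=gb_primers, sites=sites)
        if region.model is not None:
            report.write_genbank(region, out / "region_nointrons.gb",
                                 targets=result.ranked, primers=gb_primers,
                                 sites=sites, include_introns=False)
        config.to_file(out / "run_config.txt")
        result.out_dir = out
    return result


def _run_crispr(config: RunConfig, region: TargetRegion,
                genome: Genome) -> RunResult:
    candidates = discover.scan_crispr(region, config.five_prime_constraint)
    candidates = [c for c in candidates
                  if _within_intervals(c.start, c.end, region)]
    mm_eff = 0 if config.offtarget_mode == "perfect_only" else config.max_mm
    index = offtargets.build_index(
        genome, offtargets.index_k_for(discover.PROTOSPACER_LEN, mm_eff)
    )
    entries = []
    hits_by_cand = []
    for c in candidates:
        hits = offtargets.find_crispr_offtargets(
            c, genome, index, config.offtarget_mode, config.max_mm
        )
        entries.append((c, ranking.OffTargetTally.from_hits(hits)))
        hits_by_cand.append(hits)
    ranked = ranking.rank_crispr(entries, region)
    hit_map = {}
    by_id = {id(c): h for (c, _), h in zip(entries, hits_by_cand)}
    for r in ranked:
        hit_map[r.rank] = by_id[id(r.candidate)]
    return RunResult(region, ranked, hit_map, [], [])


def _run_talen(config: RunConfig, region: TargetRegion,
               genome: Genome) -> RunResult:
    monomers = discover.scan_talen_monomers(region, config.monomer_length)
    pairs = discover.pair_talens(monomers, config.spacer_min, config.spacer_max,
                                 region)
    pairs = [p for p in pairs
             if _within_intervals(p.footprint[0], p.footprint[1], region)]
    index = offtargets.build_index(
        genome, offtargets.index_k_for(config.monomer_length, config.max_mm)
    )
    entries = []
    hits_by_pair = []
    for p in pairs:
        hits, paired = offtargets.find_talen_offtargets(
            p, genome, index, config.max_mm, config.spacer_min, config.spacer_max
        )
        entries.append((p, ranking.OffTargetTally.from_hits(hits), len(paired)))
        hits_by_pair.append(hits)
    ranked = ranking.rank_talen(entries, region)
    # cluster near-equivalent pairs; representatives (cluster heads) keep
    # their rank order, members remain available for the detailed view
    ordered_pairs = [r.candidate for r in ranked]
    clusters = discover.cluster_talen_pairs(ordered_pairs)  # type: ignore[arg-type]
    reps = {id(c[0]) for c in clusters}
    by_id = {id(p): h for (p, _, _), h in zip(entries, hits_by_pair)}
    represented = [r for r in ranked if id(r.candidate) in reps]
    for i, r in enumerate(represented, start=1):
        r.rank = i
    hit_map = {r.rank: by_id[id(r.candidate)] for r in represented}
    return RunResult(region, represented, hit_map, [], [])
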