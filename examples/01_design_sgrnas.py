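"""Design and rank Cas9 sgRNA target sites in a small synthetic locus.

Builds a 20 kb genome with one planted target site and two decoys (a
perfect duplicate and a single-mismatch copy), scans a 400 bp window for
all 23 bp protospacer+NGG sites, enumerates each candidate's genomic
off-targets, and prints the top of the ranked table.
"""

from editscan import (OffTargetTally, build_index, find_crispr_offtargets,
                      index_k_for, rank_crispr, scan_crispr)
from editscan.genome import TargetRegion
from editscan.synthetic import (PlantSpec, crispr_decoy_plant,
                                crispr_site_plant, synth_genome)

spec = PlantSpec(genome_length=20_000, seed=42)
site = crispr_site_plant(5_100, "ACGTTGACCTGAGTCAAGCA", "TGG", "ontarget")
spec.add(site)
spec.add(crispr_decoy_plant(site, 12_000, [], "perfect_copy"))
spec.add(crispr_decoy_plant(site, 15_000, [(5, "C")], "one_mismatch"))
genome, truth = synth_genome(spec)

region = TargetRegion("chr1", 5_000, 5_400,
                      genome.slice("chr1", 5_000, 5_400), source="coordinates")
candidates = scan_crispr(region)
print(f"{len(candidates)} candidate sites in {region.to_query_string()}")

index = build_index(genome, index_k_for(20, max_mm=2))
entries = []
for cand in candidates:
    hits = find_crispr_offtargets(cand, genome, index, "all_upstream", max_mm=2)
    entries.append((cand, OffTargetTally.from_hits(hits)))

ranked = rank_crispr(entries, region)
print("rank  site(23bp)               strand  GC%   G20  mm0 mm1 mm2")
for r in ranked[:5]:
    c = r.candidate
    print(f"{r.rank:>4}  {c.site}  {c.strand:>5}  {c.gc_percent:5.1f}  "
          f"{int(c.g20)}    {r.tally.n0}   {r.tally.n1}   {r.tally.n2}")

# mm0/mm1/mm2 count *other* genomic loci matching a guide with 0/1/2
# mismatches; guides with no off-targets, in-window GC and a PAM-adjacent
# G rank first.  The planted guide carries its duplicate and mismatch copy
# as off-targets, pushing it down the table:
planted = next(r for r in ranked
               if r.candidate.start == 5_100 and r.candidate.strand == "+")
print(f"planted guide ranks {planted.rank}/{len(ranked)} with tallies "
      f"mm0={planted.tally.n0} mm1={planted.tally.n1} mm2={planted.tally.n2}")
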