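"""Design a TALEN pair, assemble its RVD string, and check paired off-targets.

TALENs cut as a FokI dimer: two half-sites on opposite strands flanking a
14-20 bp spacer.  A lone half-site elsewhere in the genome is only a
binding event; the dangerous off-targets are loci where two half-site
hits again face each other across an in-range gap.
"""

from editscan import (build_index, find_talen_offtargets, index_k_for,
                      pair_talens, rvd_string, scan_talen_monomers)
from editscan.genome import TargetRegion
from editscan.synthetic import PlantSpec, synth_genome, talen_pair_plant

LEFT, RIGHT = "TGACCTGAGTCAAGC", "TCAGGATGTGCCAAG"

spec = PlantSpec(genome_length=30_000, seed=11)
spec.add(talen_pair_plant(2_000, LEFT, "GAATTCAGTCAGGTCA", RIGHT, "ontarget"))
# both half-sites re-planted 16 bp apart elsewhere: a cleavable off-target
spec.add(talen_pair_plant(9_000, LEFT, "ACGGTTACGGTTACGG", RIGHT, "offtarget"))
genome, truth = synth_genome(spec)

region = TargetRegion("chr1", 1_990, 2_060,
                      genome.slice("chr1", 1_990, 2_060), source="coordinates")
monomers = scan_talen_monomers(region, length=15)
pairs = pair_talens(monomers, spacer_min=14, spacer_max=20, region=region)
pair = next(p for p in pairs if p.left.start == 2_000)
print(f"left  {pair.left.sequence}  (+) at {pair.left.start}")
print(f"right {pair.right.sequence} (-) at {pair.right.start}")
print(f"spacer {pair.spacer_len} bp: {pair.spacer_seq}")
print("RVDs(left, NN for G):", "-".join(rvd_string(pair.left, "NN")))

index = build_index(genome, index_k_for(15, max_mm=2))
hits, paired = find_talen_offtargets(pair, genome, index, max_mm=2,
                                     spacer_min=14, spacer_max=20)
print(f"{sum(not h.is_self for h in hits)} non-self half-site hits, "
      f"{len(paired)} paired off-target(s)")
for p in paired:
    print(f"  cleavable off-target at {p.left_hit.start}/{p.right_hit.start}, "
          f"gap {p.gap_len} bp")
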