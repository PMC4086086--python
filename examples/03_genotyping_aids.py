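"""Primer pairs and restriction sites around a predicted cut site.

After editing, the locus is amplified and assayed (sequencing, T7E1 or a
restriction digest).  Primers are enumerated exhaustively under classic
constraints, then ranked by genome-wide specificity: pairs whose primers
could form a second amplicon elsewhere are demoted.
"""

import numpy as np

from editscan import (PrimerOptions, build_index, builtin_enzymes,
                      classify_uniqueness, design_primer_pairs,
                      rank_primer_pairs, scan_restriction_sites)
from editscan.genome import Genome, TargetRegion

rng = np.random.default_rng(7)
seq = "".join(rng.choice(list("ACGT"), size=20_000))
genome = Genome({"chr1": seq})
cut_site = 10_000  # e.g. 3 bp upstream of a chosen guide's PAM

context = TargetRegion("chr1", cut_site - 400, cut_site + 400,
                       genome.slice("chr1", cut_site - 400, cut_site + 400),
                       source="coordinates")
opts = PrimerOptions()  # 18-25 bp (opt 22), product 150-290, Tm 57-63 (opt 60)
pairs = design_primer_pairs(context, cut_site, opts)
index = build_index(genome, 9)
ranked = rank_primer_pairs(pairs, genome, index, opts)

print("rank  left                       right                      Tm_L  Tm_R  size  off")
for p in ranked[:3]:
    print(f"{p.specificity_rank:>4}  {p.left_seq:<25}  {p.right_seq:<25}  "
          f"{p.tm_left:5.2f} {p.tm_right:5.2f}  {p.product_size:>4}  {p.off_products}")

# restriction map: a unique site near the cut lets a digest distinguish
# edited (site destroyed by NHEJ) from wild-type alleles
window = TargetRegion("chr1", cut_site - 100, cut_site + 100,
                      genome.slice("chr1", cut_site - 100, cut_site + 100),
                      source="coordinates")
sites = classify_uniqueness(
    scan_restriction_sites(window, builtin_enzymes("NEB"), min_site_len=6),
    window)
for s in sites:
    tag = "unique" if s.unique_in_region else "multiple"
    print(f"{s.enzyme:<8} at {s.start + 1} ({s.strand})  [{tag} in region]")
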