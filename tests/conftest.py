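"""Shared fixtures: small planted genomes built at test time."""

from __future__ import annotations

import pytest
from hypothesis import settings

from editscan.genome import Genome, TargetRegion
from editscan.synthetic import (PlantSpec, crispr_decoy_plant,
                                crispr_site_plant, synth_genome)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

# a protospacer with no internal repeats and mixed composition
PROTO = "ACGTTGACCTGAGTCAAGCA"


def region_of(genome: Genome, chrom: str, start: int, end: int) -> TargetRegion:
    return TargetRegion(chrom, start, end, genome.slice(chrom, start, end),
                        source="coordinates")


@pytest.fixture(scope="session")
def planted_crispr():
    """Genome with one on-target site and decoys at 1/2/3 mismatches plus a
    minus-strand single-mismatch copy."""
    site = crispr_site_plant(1000, PROTO, "TGG", "site")
    spec = PlantSpec(20000, seed=7)
    spec.add(site)
    spec.add(crispr_decoy_plant(site, 3000, [(5, "C")], "mm1"))
    spec.add(crispr_decoy_plant(site, 5000, [(4, "A"), (15, "G")], "mm2"))
    spec.add(crispr_decoy_plant(site, 7000, [(2, "G"), (9, "T"), (18, "A")], "mm3"))
    spec.add(crispr_decoy_plant(site, 9000, [(3, "A")], "mm1_minus", strand="-"))
    genome, truth = synth_genome(spec)
    return genome, truth, site
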