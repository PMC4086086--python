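"""A complete run through the pipeline, writing the same reports as the CLI.

Equivalent to:

    editscan --query gene1 --genome genome.fa --gene-table genes.txt \\
             --mode crispr --out demo_out

but driven from Python with in-memory fixtures written to disk first.
"""

import tempfile
from pathlib import Path

from editscan.pipeline import RunConfig, run
from editscan.synthetic import (PlantSpec, crispr_site_plant, synth_gene_table,
                                synth_genome, write_fasta, write_gene_table)

workdir = Path(tempfile.mkdtemp(prefix="editscan_demo_"))
spec = PlantSpec(genome_length=20_000, seed=3)
spec.add(crispr_site_plant(5_100, "ACGTTGACCTGAGTCAAGCA", "TGG", "s1"))
genome, _ = synth_genome(spec)
models = synth_gene_table(genome, n_genes=2, seed=4)
write_fasta(genome, workdir / "genome.fa")
write_gene_table(models, workdir / "genes.txt")

config = RunConfig(
    query="gene1",
    genome_path=str(workdir / "genome.fa"),
    gene_table_path=str(workdir / "genes.txt"),
    mode="crispr",
    out_dir=str(workdir / "out"),
)
result = run(config)
print(f"{len(result.ranked)} ranked guides in {result.region.to_query_string()}")
print(f"{len(result.primer_pairs)} primer pairs for the top guide")
print(f"{len(result.restriction_sites)} restriction sites in the region")
print("reports written to:", result.out_dir)
for f in sorted(result.out_dir.iterdir()):
    print("  ", f.name)
# results.tsv holds the ranked table; offtargets/rankNNNN.tsv the per-guide
# hit lists; region.gb / region_nointrons.gb are annotated GenBank files.
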