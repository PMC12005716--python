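#!/usr/bin/env python
"""Build Oxford-plot source tables: gene occupancy per chromosome x
linkage group, plus long-format dot-plot tables.

Writes results/oxford/occupancy_<genome>.tsv and dotplot_<genome>.tsv.
The duplicated pair in Liolophura shows up as the same two linkage-group
columns loaded on two separate chromosomes.
"""
import os

from karyolg.formats_io import read_gene_table, read_ortholog_table
from karyolg.karyo_ancestry import attach_duplication_evidence
from karyolg.mlg_infer import assignment_vectors, cluster_linkage_groups
from karyolg.orthology import filter_universal_single_copy
from karyolg.rates_occupancy import dotplot_table, occupancy_matrix

HERE = os.path.dirname(__file__)
DATASET = os.path.join(HERE, "..", "results", "dataset")
OUT = os.path.join(HERE, "..", "results", "oxford")
os.makedirs(OUT, exist_ok=True)

genomes = {}
for name in sorted(os.listdir(os.path.join(DATASET, "genomes"))):
    g = read_gene_table(os.path.join(DATASET, "genomes", name), format="bed")
    genomes[g.genome_id] = g
single, dup_evidence = filter_universal_single_copy(
    read_ortholog_table(os.path.join(DATASET, "orthologs.tsv")), genomes
)
vectors = assignment_vectors(single, genomes)
linkage_groups, _noise = cluster_linkage_groups(vectors)
dup_by_mlg = attach_duplication_evidence(dup_evidence, linkage_groups, vectors, genomes)

for gid, genome in genomes.items():
    occ = occupancy_matrix(genome, linkage_groups, single, dup_by_mlg)
    occ.to_csv(os.path.join(OUT, f"occupancy_{gid}.tsv"), sep="\t")
    dotplot_table(genome, linkage_groups, single).to_csv(
        os.path.join(OUT, f"dotplot_{gid}.tsv"), sep="\t", index=False
    )
    doubled = [
        int(m) for m in occ.columns if (occ[m] >= 0.2 * occ[m].sum()).sum() >= 2
    ]
    note = f"; linkage groups on two chromosomes: {doubled}" if doubled else ""
    print(f"  {gid}: {occ.shape[0]} chromosomes x {occ.shape[1]} linkage groups{note}")
print(f"tables written to {os.path.abspath(OUT)}")
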