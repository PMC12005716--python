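#!/usr/bin/env python
"""Estimate pairwise translocation rates (r = c / t per My).

For every genome pair: the fraction of single-copy orthologs violating
linkage-group consensus in either genome, divided by the divergence
time read from the dated tree. Writes results/rates/rates.tsv.
"""
import os

from karyolg.formats_io import read_gene_table, read_ortholog_table, read_tree
from karyolg.mlg_infer import assignment_vectors, cluster_linkage_groups
from karyolg.orthology import filter_universal_single_copy
from karyolg.rates_occupancy import rates_table

HERE = os.path.dirname(__file__)
DATASET = os.path.join(HERE, "..", "results", "dataset")
OUT = os.path.join(HERE, "..", "results", "rates")
os.makedirs(OUT, exist_ok=True)

genomes = {}
for name in sorted(os.listdir(os.path.join(DATASET, "genomes"))):
    g = read_gene_table(os.path.join(DATASET, "genomes", name), format="bed")
    genomes[g.genome_id] = g
tree = read_tree(os.path.join(DATASET, "tree.nwk"))
single, _ = filter_universal_single_copy(
    read_ortholog_table(os.path.join(DATASET, "orthologs.tsv")), genomes
)
vectors = assignment_vectors(single, genomes)
linkage_groups, noise = cluster_linkage_groups(vectors)

rates = rates_table(vectors, linkage_groups, noise, tree)
rates.to_csv(os.path.join(OUT, "rates.tsv"), sep="\t", index=False)

print("translocation rates (non-syntenic fraction / divergence time):")
for _, row in rates.sort_values("rate_per_my", ascending=False).iterrows():
    print(f"  {row['genome_a']} vs {row['genome_b']}: "
          f"c = {row['nonsyntenic_fraction']:.4f} "
          f"({row['n_violating']}/{row['n_total']}), "
          f"t = {row['divergence_time_my']:.0f} My, "
          f"r = {row['rate_per_my']:.2e}/My")
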