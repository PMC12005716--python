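#!/usr/bin/env python
"""Infer ancestral linkage groups from the simulated tips alone.

Reads results/dataset/, filters universal single-copy orthologs,
clusters chromosome-assignment vectors, tests chromosome-pair homology
(hypergeometric + BH), and writes the linkage-group tables under
results/mlg/.
"""
import os

import pandas as pd

from karyolg.formats_io import (
    read_gene_table,
    read_ortholog_table,
    write_mlg_assignments,
)
from karyolg.mlg_infer import (
    assignment_vectors,
    cluster_linkage_groups,
    fused_sets,
    homology_tests_frame,
    test_chromosome_homology,
)
from karyolg.orthology import filter_universal_single_copy

HERE = os.path.dirname(__file__)
DATASET = os.path.join(HERE, "..", "results", "dataset")
OUT = os.path.join(HERE, "..", "results", "mlg")
os.makedirs(OUT, exist_ok=True)

genomes = {}
for name in sorted(os.listdir(os.path.join(DATASET, "genomes"))):
    g = read_gene_table(os.path.join(DATASET, "genomes", name), format="bed")
    genomes[g.genome_id] = g
groups_all = read_ortholog_table(os.path.join(DATASET, "orthologs.tsv"))
single, dup_evidence = filter_universal_single_copy(groups_all, genomes)
print(f"{len(groups_all)} ortholog groups: {len(single)} universal single-copy, "
      f"{len(dup_evidence)} duplication-evidence")

vectors = assignment_vectors(single, genomes)
linkage_groups, noise = cluster_linkage_groups(vectors, min_support=5, epsilon=0.05)
print(f"{len(linkage_groups)} linkage groups inferred "
      f"({len(noise)} orthologs in the translocation-noise set)")

write_mlg_assignments(linkage_groups, os.path.join(OUT, "mlg_assignments.tsv"))
pd.DataFrame({"og_id": noise}).to_csv(
    os.path.join(OUT, "noise_orthologs.tsv"), sep="\t", index=False
)

genome_ids = sorted(genomes)
tests = []
for i, a in enumerate(genome_ids):
    for b in genome_ids[i + 1:]:
        tests.extend(test_chromosome_homology(vectors, a, b, alpha=0.05))
frame = homology_tests_frame(tests)
frame.to_csv(os.path.join(OUT, "homology_tests.tsv"), sep="\t", index=False)
print(f"{len(frame)} chromosome-pair homology tests, "
      f"{int((frame['q_value'] <= 0.05).sum())} significant at FDR 0.05")

rows = []
for gid in genome_ids:
    parts = fused_sets(linkage_groups, gid)
    fused = [p for p in parts if len(p) > 1]
    print(f"  {gid}: {len(parts)} chromosomes, fused sets "
          f"{sorted(sorted(p) for p in fused)}")
    rows += [{"genome_id": gid, "mlgs": ",".join(map(str, sorted(p)))} for p in parts]
pd.DataFrame(rows).to_csv(os.path.join(OUT, "fused_sets.tsv"), sep="\t", index=False)
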