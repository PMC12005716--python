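#!/usr/bin/env python
"""Reconstruct ancestral karyotypes and call rearrangement events.

Builds co-localization characters from each tip's fused linkage-group
sets, runs Fitch parsimony over the dated tree, calls per-branch
fusion/fission/duplication events with synapomorphy flags, and writes
results/ancestry/.
"""
import os

from karyolg.formats_io import read_gene_table, read_ortholog_table, read_tree
from karyolg.karyo_ancestry import (
    annotate_synapomorphies,
    attach_duplication_evidence,
    build_tip_state,
    call_events,
    colocalization_characters,
    reconstruct_states,
    replay_events_on_state,
)
from karyolg.mlg_infer import assignment_vectors, cluster_linkage_groups, fused_sets
from karyolg.orthology import filter_universal_single_copy
from karyolg.pipeline import _events_frame, _states_frame

HERE = os.path.dirname(__file__)
DATASET = os.path.join(HERE, "..", "results", "dataset")
OUT = os.path.join(HERE, "..", "results", "ancestry")
os.makedirs(OUT, exist_ok=True)

genomes = {}
for name in sorted(os.listdir(os.path.join(DATASET, "genomes"))):
    g = read_gene_table(os.path.join(DATASET, "genomes", name), format="bed")
    genomes[g.genome_id] = g
tree = read_tree(os.path.join(DATASET, "tree.nwk"))
single, dup_evidence = filter_universal_single_copy(
    read_ortholog_table(os.path.join(DATASET, "orthologs.tsv")), genomes
)
vectors = assignment_vectors(single, genomes)
linkage_groups, noise = cluster_linkage_groups(vectors)

fused_by_tip = {gid: fused_sets(linkage_groups, gid) for gid in genomes}
characters = colocalization_characters(fused_by_tip, len(linkage_groups))
states = reconstruct_states(characters, tree, mode="fitch")
dup_by_mlg = attach_duplication_evidence(dup_evidence, linkage_groups, vectors, genomes)
for gid, genome in genomes.items():
    states[gid] = build_tip_state(genome, linkage_groups, single, dup_by_mlg)

events = {}
for parent, child, _l in tree.preorder_edges():
    events[child] = call_events(states[parent], states[child], branch=child)
events = annotate_synapomorphies(events, tree, characters)

_states_frame(states).to_csv(
    os.path.join(OUT, "ancestral_karyotypes.tsv"), sep="\t", index=False
)
_events_frame(events).to_csv(os.path.join(OUT, "events.tsv"), sep="\t", index=False)

print("reconstructed haploid numbers along the chiton route:")
for node in ("Mollusca", "Polyplacophora", "Chitonida_sl", "Chitonida_ss", "Acanthochitona"):
    print(f"  {node}: 1n = {states[node].chromosome_count}")
stem = [c for c in events["Polyplacophora"] if c.event_type == "FUSION" and c.synapomorphy]
print(f"chiton stem: {len(stem)} synapomorphic fusion events "
      f"{[sorted(c.mlgs) for c in stem]}")
for tip in ("Acanthochitona_rubrolineata", "Acanthochitona_discrepans"):
    n = replay_events_on_state(states["Acanthochitona"], events[tip])
    print(f"  {tip}: replayed tip 1n = {n}")
lio = events["Liolophura_japonica"]
print("Liolophura events:", [(c.event_type, sorted(c.mlgs)) for c in lio])
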