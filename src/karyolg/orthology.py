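"""Universal single-copy ortholog groups from mutual best hits.

Groups can be consumed directly (OrthoFinder-like long table) or derived
from pairwise similarity scores: a pair (a, b) is a mutual best hit (MBH)
iff b is a's strictly unique top score in the other genome and vice
versa; score ties discard the gene (conservative — no arbitrary
orthology). MBH pairs over all genome pairs are chained into candidate
groups as connected components of the pair graph.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .formats_io import Genome, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "OrthoGroup",
    "mutual_best_hits",
    "chain_to_groups",
    "filter_universal_single_copy",
    "read_similarity_table",
]


@dataclass
class OrthoGroup:
    """A cross-genome ortholog set with per-genome copy counts."""

    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def copy_number(self) -> dict[str, int]:
        return {g: len(genes) for g, genes in self.members.items()}

    def genomes(self) -> set[str]:
        return set(self.members)


def read_similarity_table(path: str) -> pd.DataFrame:
    """Read a pairwise similarity table (query_gene, target_gene, bitscore)."""
    df = pd.read_csv(path, sep="\t", dtype={"query_gene": str, "target_gene": str})
    required = {"query_gene", "target_gene", "bitscore"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: similarity table needs columns {sorted(required)}")
    return df


def _unique_top(df: pd.DataFrame, by: str, other: str) -> dict[str, str]:
    """Map each ``by``-gene to its strictly unique top-score ``other``-gene."""
    top = df.groupby(by)["bitscore"].transform("max")
    best = df[df["bitscore"] == top]
    counts = best.groupby(by)[other].nunique()
    unique = counts[counts == 1].index
    best = best[best[by].isin(unique)].drop_duplicates(by)
    return dict(zip(best[by], best[other]))


def mutual_best_hits(
    scores: pd.DataFrame, genome_a: Genome, genome_b: Genome
) -> set[tuple[str, str]]:
    """MBH gene pairs between two genomes from a similarity table.

    ``scores`` holds rows in either query direction; genes are assigned
    to a side by membership in the two genomes. Unknown genes are an
    error; an empty table yields an empty set with a warning.
    """
    if scores.empty:
        warnings.warn(
            f"empty similarity table for {genome_a.genome_id} vs {genome_b.genome_id}",
            stacklevel=2,
        )
        return set()
    a_genes, b_genes = set(genome_a.genes), set(genome_b.genes)
    known = a_genes | b_genes
    for col in ("query_gene", "target_gene"):
        unknown = set(scores[col]) - known
        if unknown:
            raise ValidationError(
                f"similarity table references unknown genes, e.g. {sorted(unknown)[:3]}"
            )
    # orient every row as (a, b)
    fwd = scores[scores["query_gene"].isin(a_genes) & scores["target_gene"].isin(b_genes)]
    rev = scores[scores["query_gene"].isin(b_genes) & scores["target_gene"].isin(a_genes)]
    oriented = pd.concat(
        [
            fwd.rename(columns={"query_gene": "a", "target_gene": "b"}),
            rev.rename(columns={"query_gene": "b", "target_gene": "a"}),
        ],
        ignore_index=True,
    )[["a", "b", "bitscore"]]
    # collapse duplicate (a, b) rows to their max score
    oriented = oriented.groupby(["a", "b"], as_index=False)["bitscore"].max()
    best_for_a = _unique_top(oriented, "a", "b")
    best_for_b = _unique_top(oriented, "b", "a")
    return {(a, b) for a, b in best_for_a.items() if best_for_b.get(b) == a}


def chain_to_groups(
    pairsets: dict[tuple[str, str], set[tuple[str, str]]],
    genomes: dict[str, Genome],
) -> list[OrthoGroup]:
    """Chain per-pair MBH sets into ortholog groups (graph components).

    ``pairsets`` maps (genome_a_id, genome_b_id) to MBH pairs of gene ids
    oriented (gene-of-a, gene-of-b). Components become candidate groups;
    og_ids are assigned deterministically (``OG`` + zero-padded rank of
    the sorted member gene-id tuple).
    """
    if len(genomes) < 2:
        raise ValidationError("orthology chaining needs at least two genomes")
    gene_home = {
        gene_id: genome_id for genome_id, g in genomes.items() for gene_id in g.genes
    }
    graph = nx.Graph()
    for (ga, gb), pairs in pairsets.items():
        for a, b in pairs:
            if gene_home.get(a) != ga or gene_home.get(b) != gb:
                raise ValidationError(
                    f"MBH pair ({a!r}, {b!r}) inconsistent with genomes ({ga}, {gb})"
                )
            graph.add_edge(a, b)
    components = sorted(
        (tuple(sorted(comp)) for comp in nx.connected_components(graph))
    )
    width = max(4, len(str(len(components))))
    groups = []
    for rank, comp in enumerate(components, start=1):
        members: dict[str, list[str]] = {}
        for gene_id in comp:
            members.setdefault(gene_home[gene_id], []).append(gene_id)
        groups.append(OrthoGroup(og_id=f"OG{rank:0{width}d}", members=members))
    return groups


def filter_universal_single_copy(
    groups: list[OrthoGroup], genomes: dict[str, Genome]
) -> tuple[list[OrthoGroup], list[OrthoGroup]]:
    """Split groups into the universal single-copy set and the duplication-evidence set.

    Returns ``(single_copy, duplication_evidence)`` where the first holds
    groups with exactly one member in every genome and the second holds
    groups with two copies in exactly one genome and one copy everywhere
    else — the evidence later used to tell duplication from fission.
    """
    if not groups:
        raise ValidationError("no ortholog groups to filter")
    wanted = set(genomes)
    single, dup_evidence = [], []
    for og in groups:
        cn = og.copy_number
        if set(cn) != wanted:
            continue
        counts = sorted(cn.values())
        if counts == [1] * len(wanted):
            single.append(og)
        elif counts == [1] * (len(wanted) - 1) + [2]:
            dup_evidence.append(og)
    if not single:
        raise ValidationError(
            "no universal single-copy ortholog groups survive filtering; "
            "inputs may be too divergent or copy-heavy"
        )
    log.info(
        "ortholog filtering: %d universal single-copy, %d duplication-evidence, "
        "%d discarded",
        len(single),
        len(dup_evidence),
        len(groups) - len(single) - len(dup_evidence),
    )
    return single, dup_evidence
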