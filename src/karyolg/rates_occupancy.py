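"""Inter-chromosomal translocation rates and gene-occupancy matrices.

The translocation rate for a genome pair is the non-syntenic rate of
change divided by the divergence time: c / t, where c is the fraction
of single-copy orthologs whose chromosome in either genome violates
their linkage group's consensus there, and t (My) is the time since the
pair's common ancestor read from the input tree. Occupancy matrices
(chromosomes x linkage groups) and long-format dot-plot tables feed
Oxford-plot rendering.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import Genome, Phylogeny, ValidationError
from .mlg_infer import LinkageGroup
from .orthology import OrthoGroup

__all__ = [
    "RateEstimate",
    "nonsyntenic_fraction",
    "translocation_rate",
    "rates_table",
    "occupancy_matrix",
    "dotplot_table",
]


@dataclass(frozen=True)
class RateEstimate:
    """Translocation-rate estimate for one genome pair (r = c / t per My)."""

    genome_a: str
    genome_b: str
    nonsyntenic_fraction: float
    divergence_time: float
    n_violating: int
    n_total: int

    def __post_init__(self):
        if not 0.0 <= self.nonsyntenic_fraction <= 1.0:
            raise ValidationError("non-syntenic fraction outside [0, 1]")
        if self.divergence_time <= 0:
            raise ValidationError("divergence time must be positive")

    @property
    def rate(self) -> float:
        return self.nonsyntenic_fraction / self.divergence_time


def _membership(
    groups: list[LinkageGroup], noise: list[str], vectors: pd.DataFrame
) -> dict[str, int | None]:
    """og_id -> mlg_id; noise orthologs attach to their unique best-matching
    group (most consensus slots agreeing), or None when ambiguous."""
    member: dict[str, int | None] = {}
    for lg in groups:
        for og_id in lg.member_og_ids:
            member[og_id] = lg.mlg_id
    if not noise:
        return member
    genome_ids = list(vectors.columns)
    cons = np.array(
        [[lg.consensus_chrom[g] for g in genome_ids] for lg in groups], dtype=object
    )
    ids = [lg.mlg_id for lg in groups]
    sub = vectors.loc[noise]
    for og_id, row in zip(sub.index, sub.to_numpy(dtype=object)):
        agree = (cons == row).sum(axis=1)
        best = agree.max()
        winners = np.flatnonzero(agree == best)
        member[og_id] = ids[int(winners[0])] if len(winners) == 1 else None
    return member


def nonsyntenic_fraction(
    vectors: pd.DataFrame,
    groups: list[LinkageGroup],
    noise: list[str],
    genome_a: str,
    genome_b: str,
) -> tuple[float, int, int]:
    """Fraction of orthologs violating linkage-group consensus in A or B.

    Every universal single-copy ortholog counts toward the denominator;
    noise-set orthologs are attached to their best-matching group first
    (an ortholog with no unique best match counts as violating). The
    result is symmetric in the two genomes.
    """
    for g in (genome_a, genome_b):
        if g not in vectors.columns:
            raise ValidationError(f"genome {g!r} not in assignment vectors")
    total = len(vectors)
    if total == 0:
        raise ValidationError("no shared orthologs between the pair")
    consensus = {
        lg.mlg_id: lg.consensus_chrom for lg in groups
    }
    member = _membership(groups, noise, vectors)
    violating = 0
    col_a, col_b = vectors[genome_a], vectors[genome_b]
    for og_id in vectors.index:
        mlg = member.get(og_id)
        if mlg is None:
            violating += 1
            continue
        cons = consensus[mlg]
        if col_a[og_id] != cons[genome_a] or col_b[og_id] != cons[genome_b]:
            violating += 1
    return violating / total, violating, total


def translocation_rate(
    c: float, t: float, genome_a: str = "A", genome_b: str = "B",
    n_violating: int = 0, n_total: int = 0,
) -> RateEstimate:
    """Package c and t into a rate estimate (r = c / t per My)."""
    return RateEstimate(
        genome_a=genome_a, genome_b=genome_b,
        nonsyntenic_fraction=c, divergence_time=t,
        n_violating=n_violating, n_total=n_total,
    )


def rates_table(
    vectors: pd.DataFrame,
    groups: list[LinkageGroup],
    noise: list[str],
    tree: Phylogeny,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Translocation-rate estimates for genome pairs (default: all pairs)."""
    genome_ids = sorted(vectors.columns)
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(genome_ids) for b in genome_ids[i + 1 :]
        ]
    rows = []
    for a, b in pairs:
        c, nv, nt = nonsyntenic_fraction(vectors, groups, noise, a, b)
        t = tree.divergence_time(a, b)
        est = translocation_rate(c, t, a, b, nv, nt)
        rows.append(
            {
                "genome_a": a, "genome_b": b,
                "nonsyntenic_fraction": est.nonsyntenic_fraction,
                "n_violating": nv, "n_total": nt,
                "divergence_time_my": est.divergence_time,
                "rate_per_my": est.rate,
            }
        )
    return pd.DataFrame(rows)


def _greedy_order(mat: pd.DataFrame) -> pd.DataFrame:
    """Reorder rows and columns by repeatedly seating the largest cell."""
    rows = list(mat.index)
    cols = list(mat.columns)
    row_order: list = []
    col_order: list = []
    work = mat.to_numpy(dtype=float).copy()
    live_r = {r: i for i, r in enumerate(rows)}
    live_c = {c: j for j, c in enumerate(cols)}
    while live_r and live_c:
        sub_r = list(live_r)
        sub_c = list(live_c)
        block = work[np.ix_([live_r[r] for r in sub_r], [live_c[c] for c in sub_c])]
        i, j = np.unravel_index(int(block.argmax()), block.shape)
        row_order.append(sub_r[i])
        col_order.append(sub_c[j])
        del live_r[sub_r[i]], live_c[sub_c[j]]
    row_order += sorted(live_r, key=lambda r: -mat.loc[r].sum())
    col_order += sorted(live_c, key=lambda c: -mat[c].sum())
    return mat.loc[row_order, col_order]


def occupancy_matrix(
    genome: Genome,
    linkage_groups: list[LinkageGroup],
    single_groups: list[OrthoGroup],
    dup_by_mlg: dict[int, list[OrthoGroup]] | None = None,
) -> pd.DataFrame:
    """Chromosome x linkage-group ortholog counts for one genome.

    Rows are the genome's chromosomes, columns mlg_ids; each placed gene
    copy counts once (duplicate paralog copies included, which is what
    makes large-scale duplications visible as doubled rows). Rows and
    columns are greedily reordered, largest cell first, for display.
    """
    gid = genome.genome_id
    member_mlg = {
        og_id: lg.mlg_id for lg in linkage_groups for og_id in lg.member_og_ids
    }
    counts: dict[tuple[str, int], int] = {}
    for og in single_groups:
        mlg = member_mlg.get(og.og_id)
        if mlg is None or gid not in og.members:
            continue
        gene = genome.genes.get(og.members[gid][0])
        if gene is not None:
            counts[(gene.chrom_id, mlg)] = counts.get((gene.chrom_id, mlg), 0) + 1
    for mlg, ogs in (dup_by_mlg or {}).items():
        for og in ogs:
            for gene_id in og.members.get(gid, []):
                gene = genome.genes.get(gene_id)
                if gene is not None:
                    counts[(gene.chrom_id, mlg)] = counts.get((gene.chrom_id, mlg), 0) + 1
    mlg_ids = sorted({lg.mlg_id for lg in linkage_groups})
    mat = pd.DataFrame(0, index=genome.chrom_ids, columns=mlg_ids)
    for (chrom, mlg), n in counts.items():
        mat.loc[chrom, mlg] = n
    mat.index.name = "chrom_id"
    mat.columns.name = "mlg_id"
    return _greedy_order(mat)


def dotplot_table(
    genome: Genome,
    linkage_groups: list[LinkageGroup],
    single_groups: list[OrthoGroup],
) -> pd.DataFrame:
    """Long-format Oxford-plot source: one row per placed ortholog.

    Position rank is by gene midpoint within each chromosome (1..n,
    contiguous); output order is deterministic regardless of input
    ordering.
    """
    gid = genome.genome_id
    member_mlg = {
        og_id: lg.mlg_id for lg in linkage_groups for og_id in lg.member_og_ids
    }
    rows = []
    for og in single_groups:
        mlg = member_mlg.get(og.og_id)
        if mlg is None or gid not in og.members:
            continue
        gene = genome.genes.get(og.members[gid][0])
        if gene is not None:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "chrom_id": gene.chrom_id,
                    "midpoint": gene.midpoint,
                    "mlg_id": mlg,
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom_id", "midpoint", "mlg_id"])
    if df.empty:
        return df.assign(position_rank=pd.Series(dtype=int)).drop(columns=["midpoint"])
    df = df.sort_values(["chrom_id", "midpoint", "gene_id"], kind="mergesort")
    df["position_rank"] = df.groupby("chrom_id").cumcount() + 1
    return df.drop(columns=["midpoint"]).reset_index(drop=True)


def plot_oxford(dotplot: pd.DataFrame, path: str, title: str | None = None) -> None:
    """Render a dot-plot table as an Oxford-style PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(dotplot["chrom_id"]))
    offsets = {}
    running = 0
    for c in chroms:
        offsets[c] = running
        running += int((dotplot["chrom_id"] == c).sum())
    x = dotplot["chrom_id"].map(offsets) + dotplot["position_rank"]
    fig, ax = plt.subplots(figsize=(8, 4))
    scatter = ax.scatter(x, dotplot["mlg_id"], s=3, c=dotplot["mlg_id"], cmap="tab20")
    for c in chroms:
        ax.axvline(offsets[c], color="0.85", lw=0.5)
    ax.set_xlabel("gene rank along chromosomes")
    ax.set_ylabel("linkage group")
    if title:
        ax.set_title(title)
    fig.colorbar(scatter, ax=ax, label="mlg_id")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
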