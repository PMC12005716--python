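"""File formats and core domain containers.

All genomic intervals are stored 0-based half-open (the BED convention).
GFF3 input (1-based, inclusive) is converted on read and restored on
write, so a GFF3 round-trip reproduces the original coordinates.
Chromosomes are kept in descending length order, the display convention
used throughout karyotype figures ("in order of size").

Gene position for any ordering purpose is the interval midpoint
``(start + end) / 2``, which is robust to gene-length differences.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneLocus",
    "Genome",
    "Phylogeny",
    "read_gene_table",
    "write_gene_table",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_tree",
    "write_tree",
    "write_mlg_assignments",
    "read_mlg_assignments",
]


class FormatError(ValueError):
    """A malformed record in an input file; names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


@dataclass(frozen=True)
class GeneLocus:
    """One gene's placement on a chromosome of one genome (0-based half-open)."""

    gene_id: str
    genome_id: str
    chrom_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValidationError(f"gene {self.gene_id!r}: empty chrom_id")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class Genome:
    """A chromosome-level assembly: named chromosomes plus placed genes.

    ``chromosomes`` is ordered by descending length; gene lookup is by
    gene_id (unique within the genome).
    """

    genome_id: str
    chromosomes: list[tuple[str, int]]
    genes: dict[str, GeneLocus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"{self.genome_id}: duplicate chromosome IDs")
        self.chromosomes = sorted(self.chromosomes, key=lambda c: (-c[1], c[0]))
        lengths = dict(self.chromosomes)
        for g in self.genes.values():
            if g.chrom_id not in lengths:
                raise ValidationError(
                    f"{self.genome_id}: gene {g.gene_id!r} on unknown chromosome {g.chrom_id!r}"
                )
            if g.end > lengths[g.chrom_id]:
                raise ValidationError(
                    f"{self.genome_id}: gene {g.gene_id!r} extends past end of {g.chrom_id!r}"
                )

    @property
    def chrom_ids(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def genes_on(self, chrom_id: str) -> list[GeneLocus]:
        """Genes on one chromosome, ordered by midpoint."""
        found = [g for g in self.genes.values() if g.chrom_id == chrom_id]
        return sorted(found, key=lambda g: (g.midpoint, g.gene_id))

    @classmethod
    def from_gene_list(
        cls,
        genome_id: str,
        genes: Iterable[GeneLocus],
        sizes: dict[str, int] | None = None,
    ) -> "Genome":
        by_id: dict[str, GeneLocus] = {}
        max_end: dict[str, int] = {}
        for g in genes:
            if g.gene_id in by_id:
                raise ValidationError(f"{genome_id}: duplicate gene_id {g.gene_id!r}")
            by_id[g.gene_id] = g
            max_end[g.chrom_id] = max(max_end.get(g.chrom_id, 0), g.end)
        if sizes is None:
            chroms = list(max_end.items())
        else:
            chroms = list(sizes.items())
        return cls(genome_id=genome_id, chromosomes=chroms, genes=by_id)


class Phylogeny:
    """A rooted, dated tree with uniquely labelled nodes.

    Branch lengths are in My. Unlabelled internal nodes are auto-named
    ``N<i>`` by preorder index on read, so every node can be addressed
    by a stable string label.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._autoname()
        self._validate()

    def _autoname(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if not node.label:
                node.label = f"N{i}"
            i += 1

    def _validate(self) -> None:
        root = self.tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValidationError(
                "tree root is not bifurcating; root the tree (exactly two children "
                "at the root) before use"
            )
        tips = self.tip_labels
        if len(tips) != len(set(tips)):
            raise ValidationError("duplicate tip labels in tree")
        labels = [n.label for n in self.tree.preorder_node_iter() if not n.is_leaf()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate internal node labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None or edge.length < 0:
                raise ValidationError(
                    f"branch to {self._label(edge.head_node)!r} has missing or "
                    "negative length"
                )

    @staticmethod
    def _label(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    @property
    def root_label(self) -> str:
        return self._label(self.tree.seed_node)

    def node_labels(self) -> list[str]:
        return [self._label(n) for n in self.tree.preorder_node_iter()]

    def preorder_edges(self) -> list[tuple[str, str, float]]:
        """(parent_label, child_label, branch_length) in preorder."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append(
                (self._label(node.parent_node), self._label(node), float(node.edge.length))
            )
        return out

    def children(self, label: str) -> list[str]:
        node = self._find(label)
        return [self._label(c) for c in node.child_nodes()]

    def tips_below(self, label: str) -> set[str]:
        node = self._find(label)
        return {t.taxon.label for t in node.leaf_iter()}

    def _find(self, label: str) -> dendropy.Node:
        for n in self.tree.preorder_node_iter():
            if self._label(n) == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def divergence_time(self, tip_a: str, tip_b: str) -> float:
        """Time since the two tips' common ancestor (half the patristic distance)."""
        if tip_a == tip_b:
            raise ValidationError("divergence time needs two distinct tips")
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(tip_a)
        tb = self.tree.taxon_namespace.get_taxon(tip_b)
        if ta is None or tb is None:
            missing = [t for t, tax in ((tip_a, ta), (tip_b, tb)) if tax is None]
            raise ValidationError(f"tips not in tree: {missing}")
        return pdm.patristic_distance(ta, tb) / 2.0

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()


# ---------------------------------------------------------------------------
# gene tables


def _read_bed(path: str, genome_id: str) -> list[GeneLocus]:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
            names=[f"c{i}" for i in range(12)],  # BED has at most 12 fields
        )
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.empty or df["c3"].isna().all():
        raise FormatError(f"{path}: BED needs >=4 columns (chrom, start, end, name)")
    loci = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end, name = row[0], row[1], row[2], row[3]
        if pd.isna(name):
            raise FormatError(f"{path}, line {line_no}: fewer than 4 columns")
        strand = row[5] if isinstance(row[5], str) and row[5] in {"+", "-", "."} else "."
        try:
            locus = GeneLocus(
                gene_id=str(name),
                genome_id=genome_id,
                chrom_id=str(chrom),
                start=int(start),
                end=int(end),
                strand=strand,
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
        loci.append(locus)
    return loci


def _read_gff3(path: str, genome_id: str) -> list[GeneLocus]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    loci = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            raise FormatError(f"{path}: gene feature at {feat.seqid}:{feat.start} lacks ID")
        try:
            locus = GeneLocus(
                gene_id=gid,
                genome_id=genome_id,
                chrom_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: gene {gid!r}: {exc}") from exc
        loci.append(locus)
    return loci


def read_gene_table(
    path: str,
    format: str = "bed",
    genome_id: str | None = None,
    sizes: dict[str, int] | None = None,
) -> Genome:
    """Read one genome's gene coordinates from BED4+ or GFF3.

    Chromosome lengths are taken from ``sizes`` when given, otherwise
    inferred as the maximum gene end per chromosome.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(path))[0]
    if format == "bed":
        loci = _read_bed(path, genome_id)
    elif format == "gff3":
        loci = _read_gff3(path, genome_id)
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    return Genome.from_gene_list(genome_id, loci, sizes=sizes)


def write_gene_table(genome: Genome, path: str, format: str = "bed") -> None:
    """Write a genome's genes as BED4+2 or GFF3, sorted by (chrom, midpoint)."""
    order = {c: i for i, c in enumerate(genome.chrom_ids)}
    rows = sorted(
        genome.genes.values(), key=lambda g: (order[g.chrom_id], g.midpoint, g.gene_id)
    )
    with open(path, "w") as fh:
        if format == "bed":
            for g in rows:
                fh.write(f"{g.chrom_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for g in rows:
                fh.write(
                    f"{g.chrom_id}\tkaryolg\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        else:
            raise ValueError(f"unknown gene-table format {format!r}")


# ---------------------------------------------------------------------------
# ortholog tables


def read_ortholog_table(path: str):
    """Read a long-format ortholog table (og_id, genome_id, gene_id).

    Returns a list of :class:`~karyolg.orthology.OrthoGroup`, sorted by og_id.
    A gene listed under two different groups is a validation error.
    """
    from .orthology import OrthoGroup

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"og_id", "genome_id", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: ortholog table needs columns {sorted(required)}")
    if df.empty:
        return []
    dup = df.duplicated(subset=["genome_id", "gene_id"], keep=False)
    if dup.any():
        seen = df.loc[dup].drop_duplicates(["genome_id", "gene_id"])
        multi = df.merge(seen[["genome_id", "gene_id"]]).groupby(
            ["genome_id", "gene_id"]
        )["og_id"].nunique()
        if (multi > 1).any():
            bad = multi[multi > 1].index[0]
            raise ValidationError(
                f"{path}: gene {bad[1]!r} of genome {bad[0]!r} listed under multiple og_ids"
            )
    groups = []
    for og_id, sub in df.groupby("og_id", sort=True):
        members = {
            gid: sorted(g["gene_id"].tolist()) for gid, g in sub.groupby("genome_id")
        }
        groups.append(OrthoGroup(og_id=og_id, members=members))
    return groups


def write_ortholog_table(groups, path: str) -> None:
    rows = []
    for og in sorted(groups, key=lambda g: g.og_id):
        for genome_id in sorted(og.members):
            for gene_id in sorted(og.members[genome_id]):
                rows.append((og.og_id, genome_id, gene_id))
    pd.DataFrame(rows, columns=["og_id", "genome_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# trees


def read_tree(source: str) -> Phylogeny:
    """Read a rooted newick tree (file path or literal newick string)."""
    kwargs: dict = {"schema": "newick", "preserve_underscores": True}
    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    return Phylogeny(tree)


def write_tree(phylo: Phylogeny, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(phylo.as_newick() + "\n")


# ---------------------------------------------------------------------------
# linkage-group assignment tables


def write_mlg_assignments(groups, path: str) -> None:
    """Write inferred linkage groups as a long TSV.

    One row per (mlg, ortholog, genome) carrying the group's consensus
    chromosome for that genome; stable sort by (mlg_id, og_id, genome_id).
    """
    groups = list(groups)
    if not groups:
        raise ValidationError("no linkage groups to write")
    rows = []
    for lg in groups:
        for og_id in sorted(lg.member_og_ids):
            for genome_id in sorted(lg.consensus_chrom):
                rows.append((lg.mlg_id, og_id, genome_id, lg.consensus_chrom[genome_id]))
    df = pd.DataFrame(rows, columns=["mlg_id", "og_id", "genome_id", "chrom_id"])
    df = df.sort_values(["mlg_id", "og_id", "genome_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_mlg_assignments(path: str):
    """Inverse of :func:`write_mlg_assignments`."""
    from .mlg_infer import LinkageGroup

    df = pd.read_csv(path, sep="\t", dtype={"mlg_id": int})
    groups = []
    for mlg_id, sub in df.groupby("mlg_id", sort=True):
        members = sorted(sub["og_id"].unique().tolist())
        consensus = (
            sub.drop_duplicates(["genome_id"]).set_index("genome_id")["chrom_id"].to_dict()
        )
        purity = {g: 1.0 for g in consensus}
        groups.append(
            LinkageGroup(
                mlg_id=int(mlg_id),
                member_og_ids=members,
                consensus_chrom=consensus,
                purity=purity,
            )
        )
    return groups
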