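"""Ancestral karyotypes, rearrangement-event calls, and fusion mixing.

Tip genomes are summarised as binary co-localization characters, one per
unordered linkage-group pair (1 iff the two groups share that tip's
consensus chromosome). Fitch parsimony (down-pass + up-pass, ambiguity
at the root resolved to the unfused state) reconstructs each internal
node; a Dollo variant treating fusion as irreversible is available. A
node's chromosomes are the connected components of its fused-pair
graph, so the haploid number falls out as the component count.

Comparing parent and child states yields per-branch event calls:
component merges are fusions (multi-way merges decomposed into n-1
pairwise steps but reported as one merged set), splits are fission
candidates, and second copies appearing at a tip are duplications.
Duplication is told from fission by the share of the affected group's
orthologs retained in two copies split one-per-chromosome.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .formats_io import Genome, Phylogeny, ValidationError
from .mlg_infer import LinkageGroup
from .orthology import OrthoGroup

log = logging.getLogger(__name__)

__all__ = [
    "ChromosomeState",
    "KaryotypeState",
    "EventCall",
    "colocalization_characters",
    "reconstruct_states",
    "build_tip_state",
    "call_events",
    "annotate_synapomorphies",
    "classify_duplication_vs_fission",
    "mixing_index",
    "attach_duplication_evidence",
]

WELL_MIXED_THRESHOLD = 0.5


@dataclass(frozen=True)
class ChromosomeState:
    """One chromosome of a karyotype: its (mlg, copy) content and mixing flag."""

    mlgs: frozenset[tuple[int, int]]
    well_mixed: bool | None = None  # None: single-group or unknown (internal node)


@dataclass
class KaryotypeState:
    """A node's reconstructed or observed karyotype."""

    node_id: str
    chromosomes: list[ChromosomeState] = field(default_factory=list)

    @property
    def chromosome_count(self) -> int:
        return len(self.chromosomes)

    def copy1_partition(self) -> list[frozenset[int]]:
        """First-copy linkage-group content per chromosome (dup copies excluded).

        Chromosomes sharing a first-copy group (an intra-group fission
        fragment) are merged so the result is a true partition.
        """
        parts: list[set[int]] = []
        for chrom in self.chromosomes:
            prim = {m for m, cp in chrom.mlgs if cp == 1}
            if not prim:
                continue
            overlapping = [p for p in parts if p & prim]
            for p in overlapping:
                prim |= p
                parts.remove(p)
            parts.append(prim)
        return sorted((frozenset(p) for p in parts), key=lambda s: sorted(s))

    def mlg_ids(self) -> set[int]:
        return {m for chrom in self.chromosomes for m, _ in chrom.mlgs}


@dataclass(frozen=True)
class EventCall:
    """A typed rearrangement call on one branch.

    ``mlgs`` is the full affected linkage-group set; ``parts`` the
    operand subsets (parent components merged by a fusion, or fragments
    of a fission). A multi-way fusion is one call whose pairwise
    decomposition has ``pairwise_count`` = len(parts) - 1 steps.
    """

    branch: str
    event_type: str  # FUSION | FISSION | DUPLICATION
    mlgs: frozenset[int]
    parts: tuple[frozenset[int], ...] = ()
    pairwise_count: int = 1
    synapomorphy: bool | None = None


# ---------------------------------------------------------------------------
# characters


def pair_column(i: int, j: int) -> str:
    """Stable column label for the unordered linkage-group pair (i, j)."""
    i, j = sorted((i, j))
    return f"{i:03d}|{j:03d}"


def parse_pair_column(col: str) -> tuple[int, int]:
    a, b = col.split("|")
    return int(a), int(b)


def colocalization_characters(
    fused_sets_by_tip: dict[str, list[frozenset[int]]], mlg_count: int
) -> pd.DataFrame:
    """Binary tip x pair matrix: 1 iff the two groups share a chromosome.

    Columns are all C(L, 2) unordered pairs, labelled ``"iii|jjj"``.
    """
    if not fused_sets_by_tip:
        raise ValidationError("no fused sets supplied")
    pairs = list(itertools.combinations(range(1, mlg_count + 1), 2))
    rows = {}
    for tip, partition in fused_sets_by_tip.items():
        fused_pairs = set()
        for group in partition:
            fused_pairs.update(itertools.combinations(sorted(group), 2))
        rows[tip] = [1 if p in fused_pairs else 0 for p in pairs]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[pair_column(*p) for p in pairs]
    )
    df.index.name = "tip"
    return df.sort_index()


# ---------------------------------------------------------------------------
# parsimony


def _tree_maps(tree: Phylogeny):
    children: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    for p, c, _ in tree.preorder_edges():
        children.setdefault(p, []).append(c)
        parent[c] = p
    preorder = [tree.root_label] + [c for _, c, _ in tree.preorder_edges()]
    postorder = list(reversed(preorder))
    return children, parent, preorder, postorder


def _fitch_character(
    tip_states: dict[str, int], children, preorder, postorder, root: str
) -> dict[str, int]:
    prelim: dict[str, frozenset[int]] = {}
    for node in postorder:
        kids = children.get(node, [])
        if not kids:
            prelim[node] = frozenset({tip_states[node]})
        else:
            inter = frozenset.intersection(*(prelim[k] for k in kids))
            prelim[node] = inter if inter else frozenset.union(*(prelim[k] for k in kids))
    final: dict[str, int] = {}
    for node in preorder:
        s = prelim[node]
        if len(s) == 1:
            final[node] = next(iter(s))
        elif node == root:
            final[node] = 0  # ambiguity at the root resolved to unfused
        else:
            final[node] = final[_parent_of(node, children)]
    return final


def _parent_of(node: str, children: dict[str, list[str]]) -> str:
    for p, kids in children.items():
        if node in kids:
            return p
    raise KeyError(node)


def _dollo_character(
    tip_states: dict[str, int], children, preorder, postorder, root: str
) -> dict[str, int]:
    """Single-gain (fusion-irreversible) labeling minimizing losses."""
    ones_below: dict[str, int] = {}
    for node in postorder:
        kids = children.get(node, [])
        if not kids:
            ones_below[node] = tip_states[node]
        else:
            ones_below[node] = sum(ones_below[k] for k in kids)
    total_ones = ones_below[root]
    final = {node: 0 for node in preorder}
    if total_ones == 0:
        return final
    # gain at the MRCA of the 1-tips: deepest node containing all of them
    gain = root
    changed = True
    while changed:
        changed = False
        for kid in children.get(gain, []):
            if ones_below[kid] == total_ones:
                gain = kid
                changed = True
                break
    in_gain_subtree = {gain}
    for node in preorder:
        if node in in_gain_subtree:
            for kid in children.get(node, []):
                in_gain_subtree.add(kid)
    for node in preorder:
        if node in in_gain_subtree and (ones_below[node] > 0 or node == gain):
            final[node] = 1
    return final


def reconstruct_states(
    characters: pd.DataFrame, tree: Phylogeny, mode: str = "fitch"
) -> dict[str, KaryotypeState]:
    """Parsimony karyotype reconstruction at every node of the tree.

    ``characters`` is the tip x pair matrix from
    :func:`colocalization_characters`. Returns one
    :class:`KaryotypeState` per node; chromosomes are the connected
    components of each node's fused-pair graph.
    """
    tips = set(tree.tip_labels)
    if tips != set(characters.index):
        raise ValidationError("character-matrix rows do not match tree tips")
    if characters.isna().any().any():
        raise ValidationError("characters contain missing states")
    if mode not in {"fitch", "dollo"}:
        raise ValidationError(f"unknown reconstruction mode {mode!r}")
    children, _parent, preorder, postorder = _tree_maps(tree)
    root = tree.root_label
    solve = _fitch_character if mode == "fitch" else _dollo_character
    pairs = [parse_pair_column(c) for c in characters.columns]
    mlg_ids = sorted({m for pair in pairs for m in pair})
    node_edges: dict[str, list[tuple[int, int]]] = {n: [] for n in preorder}
    for col, pair in zip(characters.columns, pairs):
        column = characters[col]
        tip_states = {t: int(column[t]) for t in characters.index}
        final = solve(tip_states, children, preorder, postorder, root)
        for node, state in final.items():
            if state == 1:
                node_edges[node].append(pair)
    states = {}
    for node in preorder:
        graph = nx.Graph()
        graph.add_nodes_from(mlg_ids)
        graph.add_edges_from(node_edges[node])
        chroms = [
            ChromosomeState(mlgs=frozenset((m, 1) for m in comp))
            for comp in nx.connected_components(graph)
        ]
        chroms.sort(key=lambda c: sorted(c.mlgs))
        states[node] = KaryotypeState(node_id=node, chromosomes=chroms)
    return states


# ---------------------------------------------------------------------------
# tip states with duplication evidence


def attach_duplication_evidence(
    dup_groups: list[OrthoGroup],
    linkage_groups: list[LinkageGroup],
    vectors_single: pd.DataFrame,
    genomes: dict[str, Genome],
) -> dict[int, list[OrthoGroup]]:
    """Assign duplication-evidence ortholog groups to linkage groups.

    A two-copy group is attached to the linkage group whose consensus
    matches its placements in all genomes where it is single-copy
    (majority vote, unique winner required).
    """
    consensus = {
        lg.mlg_id: lg.consensus_chrom for lg in linkage_groups
    }
    attached: dict[int, list[OrthoGroup]] = {lg.mlg_id: [] for lg in linkage_groups}
    for og in dup_groups:
        scores: dict[int, int] = {}
        for mlg_id, cons in consensus.items():
            hits = 0
            for gid, genes in og.members.items():
                if len(genes) != 1:
                    continue
                gene = genomes[gid].genes.get(genes[0])
                if gene is not None and cons.get(gid) == gene.chrom_id:
                    hits += 1
            scores[mlg_id] = hits
        best = max(scores.values())
        winners = [m for m, s in scores.items() if s == best]
        if best > 0 and len(winners) == 1:
            attached[winners[0]].append(og)
    return attached


def classify_duplication_vs_fission(
    duplicated_split: int, informative: int, threshold: float = 0.5
) -> str:
    """DUPLICATION iff the duplicated-and-split share of orthologs >= threshold.

    ``duplicated_split`` counts the focal linkage group's ortholog
    groups present in two copies, one per candidate chromosome;
    ``informative`` is the group's total placed ortholog count there.
    Zero informative orthologs returns FISSION with a warning.
    """
    if informative == 0:
        warnings.warn(
            "no informative orthologs for duplication-vs-fission call; "
            "returning FISSION with low confidence",
            stacklevel=2,
        )
        return "FISSION"
    return "DUPLICATION" if duplicated_split / informative >= threshold else "FISSION"


def build_tip_state(
    genome: Genome,
    linkage_groups: list[LinkageGroup],
    single_groups: list[OrthoGroup],
    dup_by_mlg: dict[int, list[OrthoGroup]],
    dup_threshold: float = 0.5,
    min_cell_frac: float = 0.05,
) -> KaryotypeState:
    """Observed karyotype of one tip, including duplicate copies and mixing.

    A chromosome carries a linkage group when it holds at least
    ``max(2, min_cell_frac x group placements)`` of its genes — small
    counts are translocation noise, not karyotype structure. A second
    carrying chromosome is a duplicate copy when the group's
    duplicated-and-split ortholog share reaches ``dup_threshold``
    (otherwise it is a fission fragment and stays copy 1).
    """
    gid = genome.genome_id
    member_mlg = {
        og_id: lg.mlg_id for lg in linkage_groups for og_id in lg.member_og_ids
    }
    single_by_id = {og.og_id: og for og in single_groups}
    # per-(chromosome, mlg) placement counts, and per-gene mlg labels
    cells: dict[tuple[str, int], int] = {}
    gene_label: dict[str, int] = {}
    informative_ogs: dict[int, int] = {}  # distinct placed ortholog groups per mlg
    for og_id, mlg_id in member_mlg.items():
        og = single_by_id.get(og_id)
        if og is None or gid not in og.members:
            continue
        gene = genome.genes.get(og.members[gid][0])
        if gene is None:
            continue
        cells[(gene.chrom_id, mlg_id)] = cells.get((gene.chrom_id, mlg_id), 0) + 1
        gene_label[gene.gene_id] = mlg_id
        informative_ogs[mlg_id] = informative_ogs.get(mlg_id, 0) + 1
    dup_split: dict[int, dict[frozenset[str], int]] = {}
    for mlg_id, ogs in dup_by_mlg.items():
        for og in ogs:
            genes = [genome.genes.get(g) for g in og.members.get(gid, [])]
            genes = [g for g in genes if g is not None]
            if not genes:
                continue
            for gene in genes:
                cells[(gene.chrom_id, mlg_id)] = cells.get((gene.chrom_id, mlg_id), 0) + 1
                gene_label[gene.gene_id] = mlg_id
            informative_ogs[mlg_id] = informative_ogs.get(mlg_id, 0) + 1
            if len(genes) == 2 and genes[0].chrom_id != genes[1].chrom_id:
                key = frozenset({genes[0].chrom_id, genes[1].chrom_id})
                dup_split.setdefault(mlg_id, {})
                dup_split[mlg_id][key] = dup_split[mlg_id].get(key, 0) + 1
    placements_per_mlg: dict[int, int] = {}
    for (_, mlg_id), n in cells.items():
        placements_per_mlg[mlg_id] = placements_per_mlg.get(mlg_id, 0) + n
    consensus = {
        lg.mlg_id: lg.consensus_chrom[gid] for lg in linkage_groups
    }
    # decide what each chromosome carries
    content: dict[str, set[tuple[int, int]]] = {}
    for (chrom, mlg_id), n in cells.items():
        floor = max(2, int(round(min_cell_frac * placements_per_mlg[mlg_id])))
        if n < floor and chrom != consensus[mlg_id]:
            continue
        if chrom == consensus[mlg_id]:
            content.setdefault(chrom, set()).add((mlg_id, 1))
        else:
            pair = frozenset({chrom, consensus[mlg_id]})
            dup_n = dup_split.get(mlg_id, {}).get(pair, 0)
            verdict = classify_duplication_vs_fission(
                dup_n, informative_ogs.get(mlg_id, 0), threshold=dup_threshold
            )
            copy = 2 if verdict == "DUPLICATION" else 1
            content.setdefault(chrom, set()).add((mlg_id, copy))
    chroms = []
    for chrom_id in genome.chrom_ids:
        if chrom_id not in content:
            continue
        mlgs = frozenset(content[chrom_id])
        mixed = None
        if len({m for m, _ in mlgs}) >= 2:
            order = [
                gene_label[g.gene_id]
                for g in genome.genes_on(chrom_id)
                if g.gene_id in gene_label
            ]
            idx = mixing_index(order)
            mixed = None if idx is None else idx >= WELL_MIXED_THRESHOLD
        chroms.append(ChromosomeState(mlgs=mlgs, well_mixed=mixed))
    chroms.sort(key=lambda c: sorted(c.mlgs))
    return KaryotypeState(node_id=gid, chromosomes=chroms)


# ---------------------------------------------------------------------------
# event calling


def call_events(
    parent: KaryotypeState, child: KaryotypeState, branch: str | None = None
) -> list[EventCall]:
    """Rearrangement calls turning the parent karyotype into the child's.

    Fissions are detected first (parent components straddling child
    components); the resulting fragments are then grouped into fusions.
    Linkage groups appearing with copy 2 in the child only are
    duplications, grouped by carrying chromosome.
    """
    branch = branch or child.node_id
    p_parts = parent.copy1_partition()
    c_parts = child.copy1_partition()
    p_mlgs = set().union(*p_parts) if p_parts else set()
    c_mlgs = set().union(*c_parts) if c_parts else set()
    if not p_mlgs <= c_mlgs:
        raise ValidationError(
            f"child {child.node_id!r} lost linkage groups {sorted(p_mlgs - c_mlgs)}"
        )
    child_of: dict[int, int] = {}
    for i, comp in enumerate(c_parts):
        for m in comp:
            child_of[m] = i
    calls: list[EventCall] = []
    fragments: list[frozenset[int]] = []
    for comp in p_parts:
        targets = {child_of[m] for m in comp}
        if len(targets) == 1:
            fragments.append(comp)
        else:
            parts = tuple(
                sorted(
                    (frozenset(m for m in comp if child_of[m] == t) for t in targets),
                    key=lambda s: sorted(s),
                )
            )
            calls.append(
                EventCall(
                    branch=branch,
                    event_type="FISSION",
                    mlgs=frozenset(comp),
                    parts=parts,
                    pairwise_count=len(parts) - 1,
                )
            )
            fragments.extend(parts)
    by_target: dict[int, list[frozenset[int]]] = {}
    for frag in fragments:
        by_target.setdefault(child_of[next(iter(frag))], []).append(frag)
    for idx, frags in sorted(by_target.items()):
        if len(frags) < 2:
            continue
        frags = tuple(sorted(frags, key=lambda s: sorted(s)))
        calls.append(
            EventCall(
                branch=branch,
                event_type="FUSION",
                mlgs=frozenset().union(*frags),
                parts=frags,
                pairwise_count=len(frags) - 1,
            )
        )
    parent_cp2 = {
        (m, cp) for chrom in parent.chromosomes for m, cp in chrom.mlgs if cp >= 2
    }
    for chrom in child.chromosomes:
        dup = frozenset(m for m, cp in chrom.mlgs if cp >= 2 and (m, cp) not in parent_cp2)
        if dup:
            calls.append(
                EventCall(
                    branch=branch, event_type="DUPLICATION", mlgs=dup, parts=(dup,)
                )
            )
    return sorted(calls, key=lambda c: (c.event_type, sorted(c.mlgs)))


def annotate_synapomorphies(
    calls_by_branch: dict[str, list[EventCall]],
    tree: Phylogeny,
    characters: pd.DataFrame,
) -> dict[str, list[EventCall]]:
    """Flag fusion calls present in every tip below the branch and nowhere else."""
    all_tips = set(tree.tip_labels)
    out: dict[str, list[EventCall]] = {}
    for branch, calls in calls_by_branch.items():
        below = tree.tips_below(branch)
        others = all_tips - below
        annotated = []
        for call in calls:
            if call.event_type != "FUSION":
                annotated.append(call)
                continue
            pairs = [
                pair_column(a, b)
                for i, part in enumerate(call.parts)
                for j in range(i + 1, len(call.parts))
                for a in part
                for b in call.parts[j]
            ]
            ok = all(
                all(characters.loc[t, p] == 1 for t in below)
                and all(characters.loc[t, p] == 0 for t in others)
                for p in pairs
            )
            annotated.append(replace(call, synapomorphy=bool(ok)))
        out[branch] = annotated
    return out


def replay_events_on_state(state: KaryotypeState, calls: list[EventCall]) -> int:
    """Haploid chromosome count after applying event calls to a karyotype.

    Deterministic bookkeeping on the state's first-copy partition:
    fusions merge their operand sets, fissions split them, duplications
    add one chromosome.
    """
    parts = [set(p) for p in state.copy1_partition()]
    extra = 0
    for call in calls:
        if call.event_type == "FUSION":
            merged = set().union(*call.parts)
            touched = [p for p in parts if p & merged]
            parts = [p for p in parts if not (p & merged)]
            parts.append(set().union(merged, *touched))
        elif call.event_type == "FISSION":
            whole = set(call.mlgs)
            parts = [p for p in parts if p != whole] + [set(x) for x in call.parts]
        elif call.event_type == "DUPLICATION":
            extra += 1
    return len(parts) + extra


# ---------------------------------------------------------------------------
# mixing


def mixing_index(labels) -> float | None:
    """Observed / expected heterogeneous adjacencies of a fused chromosome.

    Expectation is exact over random label permutations given the label
    multiplicities: E = (n-1) * (1 - sum n_i (n_i - 1) / (n (n-1))).
    Returns None (not applicable) for a single-label chromosome; a
    chromosome needs at least three genes.
    """
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValidationError("mixing index needs at least three genes")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        return None
    same_prob = float((counts * (counts - 1)).sum()) / (n * (n - 1))
    expected = (n - 1) * (1.0 - same_prob)
    observed = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    return observed / expected
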