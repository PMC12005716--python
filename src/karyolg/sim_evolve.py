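"""Genome-rearrangement simulator with a ground-truth event ledger.

An ancestral genome of L linkage groups (one chromosome each) evolves
along a dated tree under five event types:

* FUSION      — concatenate two chromosomes, then interleave genes by a
                mixing parameter pi in [0, 1] (0 = pure block
                concatenation, 1 = full random interleave);
* FISSION     — split one chromosome at a gene-index breakpoint;
* DUPLICATION — copy a chromosome onto a new one; each copied gene
                becomes a new paralog copy of its ortholog group. A
                ``fraction`` < 1 copies only that share of genes
                (partial duplication);
* TRANSLOCATION — move k randomly chosen genes, each to a random other
                chromosome;
* SHUFFLE     — permute within-chromosome gene order.

Every applied event is recorded, fully resolved, in a ledger together
with its own RNG seed, so replaying the ledger from the ancestor
reproduces every tip genome exactly. Per-branch RNG substreams are
derived by hashing the child-node label with the global seed, so adding
events on one branch never perturbs another.
"""
from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    Genome,
    GeneLocus,
    Phylogeny,
    ValidationError,
    write_gene_table,
    write_ortholog_table,
    write_tree,
)

__all__ = [
    "FUSION",
    "FISSION",
    "DUPLICATION",
    "TRANSLOCATION",
    "SHUFFLE",
    "RearrangementEvent",
    "SimGenome",
    "SimTruth",
    "make_ancestor",
    "apply_event",
    "evolve",
    "replay",
    "to_genome",
    "emit_dataset",
    "emit_similarity_scores",
]

FUSION = "FUSION"
FISSION = "FISSION"
DUPLICATION = "DUPLICATION"
TRANSLOCATION = "TRANSLOCATION"
SHUFFLE = "SHUFFLE"

EVENT_TYPES = {FUSION, FISSION, DUPLICATION, TRANSLOCATION, SHUFFLE}

GENE_SPACING = 1_000  # bp between successive gene starts in emitted layouts
GENE_LENGTH = 800

_SEED_MOD = 2**31


def _substream_seed(seed: int, tag: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{tag}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % _SEED_MOD


@dataclass(frozen=True)
class RearrangementEvent:
    """One typed, fully resolved rearrangement placed on a branch.

    ``operands`` names chromosomes present when the event fires; when
    None the event resolves its own operands from its seeded RNG (used
    for rate-drawn events), which keeps the ledger replayable.
    """

    event_type: str
    branch: str | None  # child-node label; None for standalone application
    seed: int
    operands: tuple[str, ...] | None = None
    pi: float | None = None
    k: int | None = None
    breakpoint: int | None = None
    fraction: float | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.pi is not None and not (0.0 <= self.pi <= 1.0):
            raise ValidationError(f"mixing parameter pi={self.pi} outside [0, 1]")
        if self.k is not None and self.k < 1:
            raise ValidationError("translocation gene count k must be >= 1")
        if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
            raise ValidationError("duplication fraction must lie in (0, 1]")


@dataclass
class SimGenome:
    """Evolving genome state: ordered chromosomes of (og_id, copy) genes."""

    genome_id: str
    chroms: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chroms.values())

    def clone(self, genome_id: str | None = None) -> "SimGenome":
        return SimGenome(
            genome_id=genome_id or self.genome_id,
            chroms={c: list(genes) for c, genes in self.chroms.items()},
        )


@dataclass
class SimTruth:
    """Ground truth for one simulation: LG membership plus the event ledger."""

    seed: int
    n_lgs: int
    genes_per_lg: int
    mlg_map: dict[str, int]  # og_id -> true linkage group (1-based)
    events: list[RearrangementEvent] = field(default_factory=list)
    tip_ids: list[str] = field(default_factory=list)

    def events_on(self, branch: str) -> list[RearrangementEvent]:
        return [e for e in self.events if e.branch == branch]


# ---------------------------------------------------------------------------
# ancestor construction


def make_ancestor(
    n_lgs: int, genes_per_lg: int, seed: int
) -> tuple[SimGenome, dict[str, int]]:
    """Build the ancestral genome: one chromosome per linkage group.

    Gene identities are sequential ortholog-group labels; the returned
    map records each gene's true linkage group.
    """
    if n_lgs < 1 or genes_per_lg < 1:
        raise ValidationError("n_lgs and genes_per_lg must be positive")
    width = max(4, len(str(n_lgs * genes_per_lg)))
    chroms: dict[str, list[tuple[str, int]]] = {}
    mlg_map: dict[str, int] = {}
    counter = 0
    for lg in range(1, n_lgs + 1):
        genes = []
        for _ in range(genes_per_lg):
            counter += 1
            og = f"og{counter:0{width}d}"
            genes.append((og, 1))
            mlg_map[og] = lg
        chroms[f"LG{lg:02d}"] = genes
    return SimGenome(genome_id="ancestor", chroms=chroms), mlg_map


# ---------------------------------------------------------------------------
# event application


def _require_chrom(sg: SimGenome, chrom: str) -> None:
    if chrom not in sg.chroms:
        raise ValidationError(
            f"{sg.genome_id}: event names missing chromosome {chrom!r}"
        )


def _apply_fusion(sg: SimGenome, c1: str, c2: str, pi: float, rng) -> None:
    if c1 == c2:
        raise ValidationError(f"cannot fuse chromosome {c1!r} with itself")
    _require_chrom(sg, c1)
    _require_chrom(sg, c2)
    merged = sg.chroms[c1] + sg.chroms[c2]
    n = len(merged)
    m = int(round(pi * n))
    if m > 1:
        idx = np.sort(rng.choice(n, size=m, replace=False))
        perm = rng.permutation(m)
        selected = [merged[i] for i in idx]
        for slot, p in zip(idx, perm):
            merged[slot] = selected[p]
    new_id = f"{c1}+{c2}"
    out: dict[str, list[tuple[str, int]]] = {}
    for cid, genes in sg.chroms.items():
        if cid == c1:
            out[new_id] = merged
        elif cid != c2:
            out[cid] = genes
    sg.chroms = out


def _apply_fission(sg: SimGenome, c: str, breakpoint: int) -> None:
    _require_chrom(sg, c)
    n = len(sg.chroms[c])
    if not (1 <= breakpoint <= n - 1):
        raise ValidationError(
            f"fission breakpoint {breakpoint} outside [1, {n - 1}] for {c!r}"
        )
    genes = sg.chroms[c]
    out: dict[str, list[tuple[str, int]]] = {}
    for cid, g in sg.chroms.items():
        if cid == c:
            out[f"{c}/1"] = genes[:breakpoint]
            out[f"{c}/2"] = genes[breakpoint:]
        else:
            out[cid] = g
    sg.chroms = out


def _apply_duplication(sg: SimGenome, c: str, fraction: float, rng) -> None:
    _require_chrom(sg, c)
    genes = sg.chroms[c]
    n = len(genes)
    ndup = int(round(fraction * n))
    if ndup < 1:
        raise ValidationError(f"duplication of {c!r} would copy zero genes")
    idx = np.sort(rng.choice(n, size=ndup, replace=False))
    max_copy: dict[str, int] = {}
    for chrom_genes in sg.chroms.values():
        for og, cp in chrom_genes:
            max_copy[og] = max(max_copy.get(og, 0), cp)
    dup = [(genes[i][0], max_copy[genes[i][0]] + 1) for i in idx]
    sg.chroms[f"{c}*"] = dup


def _apply_translocation(sg: SimGenome, k: int, rng) -> None:
    if len(sg.chroms) < 2:
        raise ValidationError("translocation needs at least two chromosomes")
    flat = [
        (cid, i) for cid, genes in sg.chroms.items() for i in range(len(genes))
    ]
    if k > len(flat):
        raise ValidationError(f"cannot translocate {k} of {len(flat)} genes")
    chosen = rng.choice(len(flat), size=k, replace=False)
    moving = [(flat[i][0], sg.chroms[flat[i][0]][flat[i][1]]) for i in chosen]
    # remove by identity, then reinsert
    for src, gene in moving:
        sg.chroms[src].remove(gene)
    for src, gene in moving:
        targets = [c for c in sg.chroms if c != src]
        dest = targets[int(rng.integers(len(targets)))]
        pos = int(rng.integers(len(sg.chroms[dest]) + 1))
        sg.chroms[dest].insert(pos, gene)


def _apply_shuffle(sg: SimGenome, c: str, rng) -> None:
    _require_chrom(sg, c)
    genes = sg.chroms[c]
    perm = rng.permutation(len(genes))
    sg.chroms[c] = [genes[i] for i in perm]


def apply_event(genome: SimGenome, event: RearrangementEvent) -> SimGenome:
    """Apply one event, returning a new genome; RNG is the event's own seed."""
    sg = genome.clone()
    rng = np.random.default_rng(event.seed)
    if event.event_type == FUSION:
        if event.operands is None:
            c1, c2 = (list(sg.chroms)[i] for i in rng.choice(len(sg.chroms), 2, False))
        else:
            c1, c2 = event.operands
        _apply_fusion(sg, c1, c2, event.pi if event.pi is not None else 0.0, rng)
    elif event.event_type == FISSION:
        if event.operands is None:
            c = list(sg.chroms)[int(rng.integers(len(sg.chroms)))]
            bp = int(rng.integers(1, max(2, len(sg.chroms[c]))))
        else:
            (c,) = event.operands
            bp = event.breakpoint
        _apply_fission(sg, c, bp)
    elif event.event_type == DUPLICATION:
        if event.operands is None:
            c = list(sg.chroms)[int(rng.integers(len(sg.chroms)))]
        else:
            (c,) = event.operands
        _apply_duplication(sg, c, event.fraction if event.fraction else 1.0, rng)
    elif event.event_type == TRANSLOCATION:
        _apply_translocation(sg, event.k or 1, rng)
    elif event.event_type == SHUFFLE:
        if event.operands is None:
            c = list(sg.chroms)[int(rng.integers(len(sg.chroms)))]
        else:
            (c,) = event.operands
        _apply_shuffle(sg, c, rng)
    return sg


def chrom_carrying_lg(sg: SimGenome, lg: int, mlg_map: dict[str, int]) -> str:
    """Chromosome carrying the majority of a linkage group's first-copy genes."""
    counts: dict[str, int] = {}
    for cid, genes in sg.chroms.items():
        counts[cid] = sum(1 for og, cp in genes if cp == 1 and mlg_map[og] == lg)
    best = max(counts, key=lambda c: (counts[c], c))
    if counts[best] == 0:
        raise ValidationError(f"no chromosome carries linkage group {lg}")
    return best


# ---------------------------------------------------------------------------
# evolution along a tree


def _resolve_scripted(
    spec: dict, sg: SimGenome, mlg_map: dict[str, int], branch: str, seed: int
) -> list[RearrangementEvent]:
    """Expand one scripted-event spec into resolved events for the current state.

    Multi-way fusions (``lgs: [a, b, c]``) expand to sequential pairwise
    fusions, mirroring how multi-chromosome fusions are reported.
    """
    etype = spec["type"].upper()
    events: list[RearrangementEvent] = []
    if etype == FUSION:
        lgs = spec["lgs"]
        if len(lgs) < 2:
            raise ValidationError(f"fusion on {branch!r} needs >=2 linkage groups")
        pi = float(spec.get("pi", 0.5))
        current = sg
        for i, lg in enumerate(lgs[1:], start=1):
            c1 = chrom_carrying_lg(current, lgs[0], mlg_map)
            c2 = chrom_carrying_lg(current, lg, mlg_map)
            ev = RearrangementEvent(
                FUSION, branch, seed=_substream_seed(seed, f"{branch}:fuse:{lgs}:{i}"),
                operands=(c1, c2), pi=pi,
            )
            current = apply_event(current, ev)
            events.append(ev)
    elif etype == FISSION:
        c = chrom_carrying_lg(sg, spec["lg"], mlg_map)
        events.append(
            RearrangementEvent(
                FISSION, branch, seed=_substream_seed(seed, f"{branch}:fission:{spec['lg']}"),
                operands=(c,), breakpoint=int(spec["breakpoint"]),
            )
        )
    elif etype == DUPLICATION:
        c = chrom_carrying_lg(sg, spec["lg"], mlg_map)
        events.append(
            RearrangementEvent(
                DUPLICATION, branch, seed=_substream_seed(seed, f"{branch}:dup:{spec['lg']}"),
                operands=(c,), fraction=float(spec.get("fraction", 1.0)),
            )
        )
    elif etype == SHUFFLE:
        c = chrom_carrying_lg(sg, spec["lg"], mlg_map)
        events.append(
            RearrangementEvent(
                SHUFFLE, branch, seed=_substream_seed(seed, f"{branch}:shuffle:{spec['lg']}"),
                operands=(c,),
            )
        )
    elif etype == TRANSLOCATION:
        events.append(
            RearrangementEvent(
                TRANSLOCATION, branch,
                seed=_substream_seed(seed, f"{branch}:transloc"),
                k=int(spec.get("k", 1)),
            )
        )
    else:
        raise ValidationError(f"unknown scripted event type {spec['type']!r}")
    return events


def evolve(
    ancestor: SimGenome,
    mlg_map: dict[str, int],
    tree: Phylogeny,
    script: list[dict] | None = None,
    rates: dict[str, float] | None = None,
    seed: int = 0,
    translocation_k: int = 1,
) -> tuple[dict[str, SimGenome], SimTruth]:
    """Evolve the ancestor along the tree: scripted events, then rate events.

    ``script`` entries are dicts with a ``branch`` (child-node label) and
    an event spec in linkage-group coordinates; ``rates`` maps event-type
    name (lowercase) to events per My. Rate-event counts are Poisson in
    rate x branch length. Returns the tip genomes and the ground truth.
    """
    script = script or []
    rates = dict(rates or {})
    for etype, r in rates.items():
        if etype.upper() not in EVENT_TYPES:
            raise ValidationError(f"unknown rate event type {etype!r}")
        if r < 0:
            raise ValidationError(f"negative rate for {etype!r}")
    branch_labels = {child for _, child, _ in tree.preorder_edges()}
    for spec in script:
        if spec.get("branch") not in branch_labels:
            raise ValidationError(
                f"scripted event names missing branch {spec.get('branch')!r}"
            )

    n_genes = ancestor.n_genes
    genes_per_lg = n_genes // max(1, len(set(mlg_map.values())))
    truth = SimTruth(
        seed=seed,
        n_lgs=len(set(mlg_map.values())),
        genes_per_lg=genes_per_lg,
        mlg_map=dict(mlg_map),
    )
    states: dict[str, SimGenome] = {tree.root_label: ancestor}
    tips: dict[str, SimGenome] = {}
    for parent, child, length in tree.preorder_edges():
        sg = states[parent].clone(genome_id=child)
        branch_seed = _substream_seed(seed, child)
        branch_rng = np.random.default_rng(branch_seed)
        # scripted events first, in listed order
        for spec in script:
            if spec["branch"] != child:
                continue
            for ev in _resolve_scripted(spec, sg, mlg_map, child, seed):
                sg = apply_event(sg, ev)
                truth.events.append(ev)
        # then rate-drawn events, grouped by type name
        for etype in sorted(rates):
            count = int(branch_rng.poisson(rates[etype] * length))
            for _ in range(count):
                ev = RearrangementEvent(
                    etype.upper(),
                    child,
                    seed=int(branch_rng.integers(_SEED_MOD)),
                    k=translocation_k if etype.upper() == TRANSLOCATION else None,
                )
                sg = apply_event(sg, ev)
                truth.events.append(ev)
        states[child] = sg
        if child in tree.tip_labels:
            tips[child] = sg
    truth.tip_ids = sorted(tips)
    return tips, truth


def replay(truth: SimTruth, tree: Phylogeny) -> dict[str, SimGenome]:
    """Re-derive every tip genome from the ancestor and the event ledger alone."""
    ancestor, _ = make_ancestor(truth.n_lgs, truth.genes_per_lg, truth.seed)
    states: dict[str, SimGenome] = {tree.root_label: ancestor}
    tips: dict[str, SimGenome] = {}
    for parent, child, _length in tree.preorder_edges():
        sg = states[parent].clone(genome_id=child)
        for ev in truth.events_on(child):
            sg = apply_event(sg, ev)
        states[child] = sg
        if child in tree.tip_labels:
            tips[child] = sg
    return tips


def replay_states(truth: SimTruth, tree: Phylogeny) -> dict[str, SimGenome]:
    """As :func:`replay` but returning every node's genome, not only tips."""
    ancestor, _ = make_ancestor(truth.n_lgs, truth.genes_per_lg, truth.seed)
    states: dict[str, SimGenome] = {tree.root_label: ancestor}
    for parent, child, _length in tree.preorder_edges():
        sg = states[parent].clone(genome_id=child)
        for ev in truth.events_on(child):
            sg = apply_event(sg, ev)
        states[child] = sg
    return states


# ---------------------------------------------------------------------------
# emission


def to_genome(sg: SimGenome) -> Genome:
    """Materialize a simulated genome as a coordinate-bearing :class:`Genome`.

    Chromosomes are renamed ``chr01..`` by descending gene count (the
    size-order display convention); genes are laid out at even spacing.
    """
    ranked = sorted(sg.chroms.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    width = max(2, len(str(len(ranked))))
    loci = []
    sizes = {}
    for i, (_, genes) in enumerate(ranked, start=1):
        chrom_id = f"chr{i:0{width}d}"
        sizes[chrom_id] = len(genes) * GENE_SPACING
        for j, (og, cp) in enumerate(genes):
            start = j * GENE_SPACING
            loci.append(
                GeneLocus(
                    gene_id=f"{sg.genome_id}|{og}.{cp}",
                    genome_id=sg.genome_id,
                    chrom_id=chrom_id,
                    start=start,
                    end=start + GENE_LENGTH,
                )
            )
    return Genome.from_gene_list(sg.genome_id, loci, sizes=sizes)


def _ortho_groups_from_tips(tips: dict[str, SimGenome]):
    from .orthology import OrthoGroup

    members: dict[str, dict[str, list[str]]] = {}
    for tip_id, sg in tips.items():
        for genes in sg.chroms.values():
            for og, cp in genes:
                members.setdefault(og, {}).setdefault(tip_id, []).append(
                    f"{tip_id}|{og}.{cp}"
                )
    return [OrthoGroup(og_id=og, members=m) for og, m in sorted(members.items())]


def ledger_frame(truth: SimTruth) -> pd.DataFrame:
    rows = []
    for order, ev in enumerate(truth.events):
        rows.append(
            {
                "order": order,
                "branch": ev.branch,
                "event_type": ev.event_type,
                "operands": "|".join(ev.operands) if ev.operands else "",
                "pi": "" if ev.pi is None else ev.pi,
                "k": "" if ev.k is None else ev.k,
                "breakpoint": "" if ev.breakpoint is None else ev.breakpoint,
                "fraction": "" if ev.fraction is None else ev.fraction,
                "seed": ev.seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "order", "branch", "event_type", "operands",
            "pi", "k", "breakpoint", "fraction", "seed",
        ],
    )


def emit_dataset(
    tips: dict[str, SimGenome],
    truth: SimTruth,
    tree: Phylogeny,
    outdir: str,
    force: bool = False,
    scores: bool = False,
) -> None:
    """Write per-genome BED files, the ortholog table, the tree, and the truth.

    Paralogs created by DUPLICATION share their og_id (copy number 2 in
    the affected genome). The emitted dataset reloads cleanly through
    the format readers.
    """
    if not tips:
        raise ValidationError("no tip genomes to emit")
    if os.path.exists(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"{outdir} exists and is non-empty; pass force=True")
    os.makedirs(os.path.join(outdir, "genomes"), exist_ok=True)
    for tip_id in sorted(tips):
        genome = to_genome(tips[tip_id])
        write_gene_table(genome, os.path.join(outdir, "genomes", f"{tip_id}.bed"))
    write_ortholog_table(
        _ortho_groups_from_tips(tips), os.path.join(outdir, "orthologs.tsv")
    )
    write_tree(tree, os.path.join(outdir, "tree.nwk"))
    ledger_frame(truth).to_csv(os.path.join(outdir, "event_ledger.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.mlg_map.items()), columns=["og_id", "true_lg"]
    ).to_csv(os.path.join(outdir, "true_linkage_groups.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "seed.txt"), "w") as fh:
        fh.write(f"{truth.seed}\n")
    if scores:
        os.makedirs(os.path.join(outdir, "scores"), exist_ok=True)
        tip_ids = sorted(tips)
        for i, a in enumerate(tip_ids):
            for b in tip_ids[i + 1 :]:
                df = emit_similarity_scores(tips[a], tips[b], truth.seed)
                df.to_csv(
                    os.path.join(outdir, "scores", f"{a}__{b}.tsv"),
                    sep="\t",
                    index=False,
                )


def emit_similarity_scores(
    sg_a: SimGenome, sg_b: SimGenome, seed: int, background: float = 0.05
) -> pd.DataFrame:
    """Synthetic pairwise bitscores for the MBH route.

    True ortholog pairs score high, with first copies scoring above
    later paralog copies so mutual best hits resolve to copy-1 pairs;
    a sprinkling of low-score background hits emulates spurious
    similarity.
    """
    rng = np.random.default_rng(_substream_seed(seed, f"scores:{sg_a.genome_id}:{sg_b.genome_id}"))
    genes_a: dict[str, list[tuple[str, int]]] = {}
    genes_b: dict[str, list[tuple[str, int]]] = {}
    for store, sg in ((genes_a, sg_a), (genes_b, sg_b)):
        for genes in sg.chroms.values():
            for og, cp in genes:
                store.setdefault(og, []).append((f"{sg.genome_id}|{og}.{cp}", cp))
    rows = []
    shared = sorted(set(genes_a) & set(genes_b))
    for og in shared:
        base = 400.0 + float(rng.uniform(0, 200))
        for ga, ca in genes_a[og]:
            for gb, cb in genes_b[og]:
                penalty = 20.0 * (ca + cb - 2) + float(rng.uniform(0, 5))
                rows.append((ga, gb, round(base - penalty, 2)))
    flat_a = [g for lst in genes_a.values() for g, _ in lst]
    flat_b = [g for lst in genes_b.values() for g, _ in lst]
    n_bg = int(background * len(flat_a))
    if n_bg and flat_b:
        qa = rng.choice(len(flat_a), size=n_bg, replace=False)
        tb = rng.integers(len(flat_b), size=n_bg)
        for i, j in zip(qa, tb):
            rows.append((flat_a[i], flat_b[j], round(float(rng.uniform(50, 150)), 2)))
    return pd.DataFrame(rows, columns=["query_gene", "target_gene", "bitscore"])
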