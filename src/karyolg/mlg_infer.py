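"""Ancestral linkage-group inference from ortholog chromosome assignments.

Each universal single-copy ortholog yields a vector of chromosome
assignments, one slot per genome. Orthologs sharing an identical vector
form a candidate linkage group; classes reaching ``min_support`` members
become linkage groups, remaining orthologs attach to the unique group
whose vector differs in at most ``floor(epsilon * G)`` slots if one
exists, and everything else lands in the noise set — these are the
translocated genes later counted by the rate estimator.

Chromosome-pair homology between two genomes is backed by a
hypergeometric upper-tail test on shared ortholog counts, BH-corrected
across all chromosome pairs of the genome pair.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .formats_io import Genome, ValidationError
from .orthology import OrthoGroup

log = logging.getLogger(__name__)

__all__ = [
    "LinkageGroup",
    "HomologyTest",
    "assignment_vectors",
    "test_chromosome_homology",
    "cluster_linkage_groups",
    "fused_sets",
    "homology_tests_frame",
]


@dataclass
class LinkageGroup:
    """An inferred ancestral linkage group.

    ``mlg_id`` is a 1-based rank by descending member count (1 =
    largest); ``consensus_chrom`` maps each genome to the chromosome the
    group's members occupy there; ``purity`` is the fraction of members
    on the consensus chromosome per genome.
    """

    mlg_id: int
    member_og_ids: list[str]
    consensus_chrom: dict[str, str]
    purity: dict[str, float] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.member_og_ids)


@dataclass(frozen=True)
class HomologyTest:
    """Hypergeometric chromosome-pair homology test between two genomes."""

    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    shared: int
    n_a: int
    n_b: int
    total: int
    p_value: float
    q_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return bool(self.q_value <= 0.05)


def assignment_vectors(
    groups: list[OrthoGroup], genomes: dict[str, Genome]
) -> pd.DataFrame:
    """One chromosome-assignment vector per single-copy ortholog.

    Returns a DataFrame indexed by og_id with one column per genome
    (sorted genome order, fixed and recorded in the columns).
    """
    genome_ids = sorted(genomes)
    rows = {}
    for og in groups:
        vec = []
        for gid in genome_ids:
            genes = og.members.get(gid, [])
            if len(genes) != 1:
                raise ValidationError(
                    f"group {og.og_id!r} is not single-copy in {gid!r}; "
                    "filter before building vectors"
                )
            gene = genomes[gid].genes.get(genes[0])
            if gene is None:
                raise ValidationError(
                    f"group {og.og_id!r}: gene {genes[0]!r} missing from {gid!r}"
                )
            vec.append(gene.chrom_id)
        rows[og.og_id] = vec
    df = pd.DataFrame.from_dict(rows, orient="index", columns=genome_ids)
    df.index.name = "og_id"
    return df.sort_index()


def test_chromosome_homology(
    vectors: pd.DataFrame, genome_a: str, genome_b: str, alpha: float = 0.05
) -> list[HomologyTest]:
    """Hypergeometric upper-tail homology test for every chromosome pair.

    For chromosomes (i, j) with n_a and n_b assigned orthologs out of N
    total and s shared, p = P[X >= s] with X ~ Hypergeom(N, n_a, n_b).
    BH correction is applied across all chromosome pairs of the genome
    pair; a pair is significant iff q <= alpha.
    """
    for g in (genome_a, genome_b):
        if g not in vectors.columns:
            raise ValidationError(f"genome {g!r} not in assignment vectors")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    n_total = len(vectors)
    if n_total == 0:
        raise ValidationError("no orthologs to test")
    table = pd.crosstab(vectors[genome_a], vectors[genome_b])
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    tests = []
    for ca in table.index:
        for cb in table.columns:
            shared = int(table.loc[ca, cb])
            na, nb = int(row_sums[ca]), int(col_sums[cb])
            p = float(hypergeom.sf(shared - 1, n_total, na, nb))
            tests.append(
                HomologyTest(
                    genome_a=genome_a, genome_b=genome_b,
                    chrom_a=str(ca), chrom_b=str(cb),
                    shared=shared, n_a=na, n_b=nb, total=n_total,
                    p_value=min(1.0, p),
                )
            )
    _, q_values, _, _ = multipletests([t.p_value for t in tests], method="fdr_bh")
    return [
        HomologyTest(
            genome_a=t.genome_a, genome_b=t.genome_b,
            chrom_a=t.chrom_a, chrom_b=t.chrom_b,
            shared=t.shared, n_a=t.n_a, n_b=t.n_b, total=t.total,
            p_value=t.p_value, q_value=float(q),
        )
        for t, q in zip(tests, q_values)
    ]


def homology_tests_frame(tests: list[HomologyTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_a": t.genome_a, "genome_b": t.genome_b,
                "chrom_a": t.chrom_a, "chrom_b": t.chrom_b,
                "shared": t.shared, "n_a": t.n_a, "n_b": t.n_b,
                "total": t.total, "p_value": t.p_value, "q_value": t.q_value,
            }
            for t in tests
        ]
    )


def cluster_linkage_groups(
    vectors: pd.DataFrame,
    min_support: int = 5,
    epsilon: float = 0.05,
) -> tuple[list[LinkageGroup], list[str]]:
    """Cluster assignment vectors into linkage groups.

    Exact-identity vector classes with >= ``min_support`` members become
    groups. Each leftover ortholog attaches to the unique group whose
    consensus differs in <= floor(epsilon * G) genome slots if exactly
    one such group exists; otherwise it joins the returned noise list.
    Groups are renumbered 1..L by descending support (ties broken by the
    consensus vector, so numbering is invariant to input row order).
    """
    if vectors.isna().any().any():
        raise ValidationError("assignment vectors contain missing placements")
    n_genomes = vectors.shape[1]
    max_mismatch = int(np.floor(epsilon * n_genomes))
    key = pd.Series(map(tuple, vectors.to_numpy()), index=vectors.index)
    classes = key.groupby(key).groups  # consensus tuple -> og index
    cores = {vec: list(ogs) for vec, ogs in classes.items() if len(ogs) >= min_support}
    if not cores:
        raise ValidationError(
            f"no vector class reaches min_support={min_support}; lower the threshold"
        )
    noise: list[str] = []
    leftovers = {vec: list(ogs) for vec, ogs in classes.items() if len(ogs) < min_support}
    core_vecs = list(cores)
    core_mat = np.array(core_vecs, dtype=object)
    for vec, ogs in leftovers.items():
        arr = np.array(vec, dtype=object)
        mismatches = (core_mat != arr).sum(axis=1)
        hits = np.flatnonzero(mismatches <= max_mismatch)
        if len(hits) == 1:
            cores[core_vecs[int(hits[0])]].extend(ogs)
        else:
            noise.extend(ogs)
    ordered = sorted(cores.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    genome_ids = list(vectors.columns)
    groups = []
    for rank, (vec, ogs) in enumerate(ordered, start=1):
        members = sorted(map(str, ogs))
        sub = vectors.loc[members]
        purity = {
            gid: float((sub[gid] == vec[i]).mean())
            for i, gid in enumerate(genome_ids)
        }
        groups.append(
            LinkageGroup(
                mlg_id=rank,
                member_og_ids=members,
                consensus_chrom=dict(zip(genome_ids, vec)),
                purity=purity,
            )
        )
    bad = [
        (lg.mlg_id, gid)
        for lg in groups
        for gid, p in lg.purity.items()
        if p < 1.0 - epsilon
    ]
    if bad:
        raise ValidationError(f"linkage-group purity below 1 - epsilon for {bad[:3]}")
    log.info(
        "clustered %d orthologs into %d linkage groups (%d noise)",
        len(vectors), len(groups), len(noise),
    )
    return groups, sorted(map(str, noise))


def fused_sets(groups: list[LinkageGroup], genome_id: str) -> list[frozenset[int]]:
    """Partition mlg_ids of one genome by shared consensus chromosome.

    Groups whose consensus chromosome coincides form one fused set;
    singletons are unfused. The partition covers every mlg_id once.
    """
    by_chrom: dict[str, set[int]] = {}
    for lg in groups:
        if genome_id not in lg.consensus_chrom:
            raise ValidationError(f"group {lg.mlg_id} has no consensus for {genome_id!r}")
        by_chrom.setdefault(lg.consensus_chrom[genome_id], set()).add(lg.mlg_id)
    return sorted(
        (frozenset(s) for s in by_chrom.values()), key=lambda s: sorted(s)
    )
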