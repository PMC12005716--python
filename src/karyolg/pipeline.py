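"""End-to-end orchestration: simulate -> orthology -> linkage groups ->
ancestral karyotypes -> rates, with a checksummed run manifest.

Every threshold the analysis depends on is recorded in the manifest, so
a run self-documents its choices; rerunning an identical config and
seed reproduces identical output checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .formats_io import (
    Genome,
    Phylogeny,
    ValidationError,
    read_gene_table,
    read_ortholog_table,
    read_tree,
    write_mlg_assignments,
)
from .karyo_ancestry import (
    KaryotypeState,
    annotate_synapomorphies,
    attach_duplication_evidence,
    build_tip_state,
    call_events,
    colocalization_characters,
    reconstruct_states,
)
from .mlg_infer import (
    assignment_vectors,
    cluster_linkage_groups,
    fused_sets,
    homology_tests_frame,
    test_chromosome_homology,
)
from .orthology import filter_universal_single_copy
from .rates_occupancy import dotplot_table, occupancy_matrix, rates_table
from .scenarios import Scenario, chiton_scenario, load_scenario, simulate_scenario
from .sim_evolve import emit_dataset

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: str
    seed: int = 0
    scenario: str | None = None  # "builtin:chiton" or a YAML path
    genomes_dir: str | None = None
    orthologs: str | None = None
    tree: str | None = None
    min_support: int = 5
    epsilon: float = 0.05
    alpha: float = 0.05
    dup_threshold: float = 0.5
    mixing_threshold: float = 0.5
    reconstruction: str = "fitch"
    force: bool = False

    def validate(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValidationError("epsilon must lie in [0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.dup_threshold < 1.0:
            raise ValidationError("dup_threshold must lie in (0, 1)")
        if self.reconstruction not in {"fitch", "dollo"}:
            raise ValidationError("reconstruction must be 'fitch' or 'dollo'")
        has_sim = self.scenario is not None
        has_inputs = all(
            x is not None for x in (self.genomes_dir, self.orthologs, self.tree)
        )
        if has_sim == has_inputs:
            raise ValidationError(
                "configure exactly one input mode: a simulation scenario, or "
                "genomes_dir + orthologs + tree"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        thresholds = doc.pop("thresholds", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = (set(doc) | set(thresholds)) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{**doc, **thresholds})
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    """In-memory handles on a completed run, plus its output directory."""

    outdir: str
    genomes: dict[str, Genome]
    tree: Phylogeny
    linkage_groups: list
    noise: list[str]
    vectors: pd.DataFrame
    states: dict[str, KaryotypeState]
    events: dict[str, list]
    rates: pd.DataFrame
    manifest: dict
    truth: object | None = None


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_scenario(spec: str) -> Scenario:
    if spec == "builtin:chiton":
        return chiton_scenario()
    return load_scenario(spec)


def _states_frame(states: dict[str, KaryotypeState]) -> pd.DataFrame:
    rows = []
    for node in sorted(states):
        st = states[node]
        for i, chrom in enumerate(st.chromosomes, start=1):
            mlgs = ",".join(f"{m}:{cp}" for m, cp in sorted(chrom.mlgs))
            rows.append(
                {
                    "node": node,
                    "chromosome": i,
                    "mlgs": mlgs,
                    "well_mixed": "" if chrom.well_mixed is None else chrom.well_mixed,
                    "chromosome_count": st.chromosome_count,
                }
            )
    return pd.DataFrame(rows)


def _events_frame(events: dict[str, list]) -> pd.DataFrame:
    rows = []
    for branch in sorted(events):
        for call in events[branch]:
            rows.append(
                {
                    "branch": branch,
                    "event_type": call.event_type,
                    "mlgs": ",".join(map(str, sorted(call.mlgs))),
                    "parts": ";".join(
                        ",".join(map(str, sorted(p))) for p in call.parts
                    ),
                    "pairwise_count": call.pairwise_count,
                    "synapomorphy": "" if call.synapomorphy is None else call.synapomorphy,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "branch", "event_type", "mlgs", "parts", "pairwise_count", "synapomorphy",
        ],
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage in order and write a checksummed manifest."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    truth = None

    # stage 1: obtain input data
    try:
        if config.scenario is not None:
            scenario = _load_scenario(config.scenario)
            tips, truth, tree = simulate_scenario(scenario, config.seed)
            dataset = os.path.join(outdir, "dataset")
            emit_dataset(tips, truth, tree, dataset, force=True)
            genomes_dir = os.path.join(dataset, "genomes")
            orthologs_path = os.path.join(dataset, "orthologs.tsv")
            tree_path = os.path.join(dataset, "tree.nwk")
        else:
            genomes_dir = config.genomes_dir
            orthologs_path = config.orthologs
            tree_path = config.tree
        genomes = {}
        for name in sorted(os.listdir(genomes_dir)):
            if name.endswith(".bed"):
                g = read_gene_table(os.path.join(genomes_dir, name), format="bed")
                genomes[g.genome_id] = g
            elif name.endswith((".gff3", ".gff")):
                g = read_gene_table(os.path.join(genomes_dir, name), format="gff3")
                genomes[g.genome_id] = g
        if not genomes:
            raise ValidationError(f"no gene tables found in {genomes_dir!r}")
        tree = read_tree(tree_path)
        missing = set(tree.tip_labels) - set(genomes)
        if missing:
            raise ValidationError(f"tree tips without genomes: {sorted(missing)}")
        all_groups = read_ortholog_table(orthologs_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # stage 2: orthology filtering
    try:
        single, dup_evidence = filter_universal_single_copy(all_groups, genomes)
    except Exception as exc:
        raise RuntimeError(f"stage 'orthology' failed: {exc}") from exc

    # stage 3: linkage-group inference
    try:
        vectors = assignment_vectors(single, genomes)
        groups, noise = cluster_linkage_groups(
            vectors, min_support=config.min_support, epsilon=config.epsilon
        )
        write_mlg_assignments(groups, os.path.join(outdir, "mlg_assignments.tsv"))
        written.append("mlg_assignments.tsv")
        pd.DataFrame({"og_id": noise}).to_csv(
            os.path.join(outdir, "noise_orthologs.tsv"), sep="\t", index=False
        )
        written.append("noise_orthologs.tsv")
        genome_ids = sorted(genomes)
        tests = []
        for i, a in enumerate(genome_ids):
            for b in genome_ids[i + 1 :]:
                tests.extend(
                    test_chromosome_homology(vectors, a, b, alpha=config.alpha)
                )
        homology_tests_frame(tests).to_csv(
            os.path.join(outdir, "homology_tests.tsv"), sep="\t", index=False
        )
        written.append("homology_tests.tsv")
        fused_rows = []
        for gid in genome_ids:
            for fs in fused_sets(groups, gid):
                fused_rows.append(
                    {"genome_id": gid, "mlgs": ",".join(map(str, sorted(fs)))}
                )
        pd.DataFrame(fused_rows).to_csv(
            os.path.join(outdir, "fused_sets.tsv"), sep="\t", index=False
        )
        written.append("fused_sets.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'mlg_infer' failed: {exc}") from exc

    # stage 4: ancestral karyotypes and events
    try:
        fused_by_tip = {gid: fused_sets(groups, gid) for gid in genomes}
        characters = colocalization_characters(fused_by_tip, len(groups))
        states = reconstruct_states(characters, tree, mode=config.reconstruction)
        dup_by_mlg = attach_duplication_evidence(
            dup_evidence, groups, vectors, genomes
        )
        for gid, genome in genomes.items():
            states[gid] = build_tip_state(
                genome, groups, single, dup_by_mlg,
                dup_threshold=config.dup_threshold,
            )
        events = {}
        for parent, child, _len in tree.preorder_edges():
            events[child] = call_events(states[parent], states[child], branch=child)
        events = annotate_synapomorphies(events, tree, characters)
        _states_frame(states).to_csv(
            os.path.join(outdir, "ancestral_karyotypes.tsv"), sep="\t", index=False
        )
        written.append("ancestral_karyotypes.tsv")
        _events_frame(events).to_csv(
            os.path.join(outdir, "events.tsv"), sep="\t", index=False
        )
        written.append("events.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'karyo_ancestry' failed: {exc}") from exc

    # stage 5: rates and occupancy
    try:
        rates = rates_table(vectors, groups, noise, tree)
        rates.to_csv(os.path.join(outdir, "rates.tsv"), sep="\t", index=False)
        written.append("rates.tsv")
        for gid, genome in genomes.items():
            occupancy_matrix(genome, groups, single, dup_by_mlg).to_csv(
                os.path.join(outdir, f"occupancy_{gid}.tsv"), sep="\t"
            )
            written.append(f"occupancy_{gid}.tsv")
            dotplot_table(genome, groups, single).to_csv(
                os.path.join(outdir, f"dotplot_{gid}.tsv"), sep="\t", index=False
            )
            written.append(f"dotplot_{gid}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'rates_occupancy' failed: {exc}") from exc

    config_doc = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_doc,
        "config_sha256": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            name: _sha256(os.path.join(outdir, name)) for name in sorted(written)
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(
        outdir=outdir,
        genomes=genomes,
        tree=tree,
        linkage_groups=groups,
        noise=noise,
        vectors=vectors,
        states=states,
        events=events,
        rates=rates,
        manifest=manifest,
        truth=truth,
    )


def make_report(run_dir: str) -> str:
    """Render a human-readable markdown summary from a completed run.

    Numbers come only from the stage outputs on disk; regeneration is
    idempotent. Returns the report path.
    """
    needed = ["ancestral_karyotypes.tsv", "events.tsv", "rates.tsv", "manifest.json"]
    for name in needed:
        if not os.path.exists(os.path.join(run_dir, name)):
            raise FileNotFoundError(f"missing stage output {name!r} in {run_dir!r}")
    karyo = pd.read_csv(os.path.join(run_dir, "ancestral_karyotypes.tsv"), sep="\t")
    events = pd.read_csv(os.path.join(run_dir, "events.tsv"), sep="\t")
    rates = pd.read_csv(os.path.join(run_dir, "rates.tsv"), sep="\t")
    with open(os.path.join(run_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    lines = ["# Karyotype-evolution run report", ""]
    lines.append(f"Seed: {manifest['seed']}; config hash: {manifest['config_sha256'][:12]}")
    lines.append("")
    lines.append("## Haploid chromosome counts (1n) per node")
    lines.append("")
    counts = (
        karyo.groupby("node")["chromosome_count"].first().sort_index()
    )
    for node, n in counts.items():
        lines.append(f"- {node}: 1n = {n}")
    lines.append("")
    lines.append("## Rearrangement events")
    lines.append("")
    if events.empty:
        lines.append("No rearrangements detected.")
    else:
        for _, row in events.iterrows():
            syn = " (synapomorphy)" if row.get("synapomorphy") is True or str(
                row.get("synapomorphy")
            ) == "True" else ""
            lines.append(
                f"- {row['branch']}: {row['event_type']} of MLG {{{row['mlgs']}}}{syn}"
            )
    lines.append("")
    lines.append("## Translocation rates (r = c / t per My)")
    lines.append("")
    for _, row in rates.iterrows():
        lines.append(
            f"- {row['genome_a']} vs {row['genome_b']}: c = "
            f"{row['nonsyntenic_fraction']:.4f}, t = {row['divergence_time_my']:.0f} My, "
            f"r = {row['rate_per_my']:.2e} per My"
        )
    lines.append("")
    path = os.path.join(run_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path
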