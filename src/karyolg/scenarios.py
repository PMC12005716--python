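"""Executable evolutionary scenarios for the rearrangement simulator.

A scenario bundles the ancestor configuration, the dated tree, scripted
events (in linkage-group coordinates), and background event rates. The
bundled chiton-radiation scenario encodes the reconstructed molluscan
route: 20 ancestral linkage groups, the three chiton-stem fusion
synapomorphies, lineage-specific fusions reproducing each tip's haploid
count, and the Liolophura fuse-then-partially-duplicate pattern.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .formats_io import Phylogeny, ValidationError, read_tree
from .sim_evolve import SimGenome, SimTruth, evolve, make_ancestor

__all__ = ["Scenario", "load_scenario", "chiton_scenario", "simulate_scenario"]


@dataclass
class Scenario:
    name: str
    n_lgs: int
    genes_per_lg: int
    tree_newick: str
    rates: dict[str, float] = field(default_factory=dict)
    translocation_k: int = 1
    events: list[dict] = field(default_factory=list)

    def tree(self) -> Phylogeny:
        return read_tree(self.tree_newick)

    def validate(self) -> None:
        if self.n_lgs < 1 or self.genes_per_lg < 1:
            raise ValidationError("scenario needs positive n_lgs and genes_per_lg")
        tree = self.tree()
        branches = {child for _, child, _ in tree.preorder_edges()}
        for ev in self.events:
            if "branch" not in ev or "type" not in ev:
                raise ValidationError(f"scripted event missing branch/type: {ev}")
            if ev["branch"] not in branches:
                raise ValidationError(f"scripted event names unknown branch {ev['branch']!r}")
        for r in self.rates.values():
            if r < 0:
                raise ValidationError("negative event rate in scenario")


def _parse(doc: dict) -> Scenario:
    tree_newick = re.sub(r"\s+", "", doc["tree"])
    sc = Scenario(
        name=doc.get("name", "scenario"),
        n_lgs=int(doc["n_lgs"]),
        genes_per_lg=int(doc["genes_per_lg"]),
        tree_newick=tree_newick,
        rates={k: float(v) for k, v in (doc.get("rates") or {}).items()},
        translocation_k=int(doc.get("translocation_k", 1)),
        events=list(doc.get("events") or []),
    )
    sc.validate()
    return sc


def load_scenario(path: str) -> Scenario:
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def chiton_scenario() -> Scenario:
    """The bundled seven-genome chiton-radiation scenario."""
    text = resources.files("karyolg").joinpath("data/chiton_scenario.yaml").read_text()
    return _parse(yaml.safe_load(text))


def simulate_scenario(
    scenario: Scenario, seed: int
) -> tuple[dict[str, SimGenome], SimTruth, Phylogeny]:
    """Run a scenario end to end: ancestor, evolution, tips plus ground truth."""
    tree = scenario.tree()
    ancestor, mlg_map = make_ancestor(scenario.n_lgs, scenario.genes_per_lg, seed)
    tips, truth = evolve(
        ancestor,
        mlg_map,
        tree,
        script=scenario.events,
        rates=scenario.rates,
        seed=seed,
        translocation_k=scenario.translocation_k,
    )
    return tips, truth, tree
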