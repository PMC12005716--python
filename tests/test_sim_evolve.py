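"""Simulator semantics: event algebra, determinism, ledger replay."""
import numpy as np
import pytest

from karyolg.formats_io import ValidationError, read_gene_table, read_ortholog_table, read_tree
from karyolg.karyo_ancestry import mixing_index
from karyolg.scenarios import simulate_scenario
from karyolg.sim_evolve import (
    DUPLICATION,
    FISSION,
    FUSION,
    SHUFFLE,
    TRANSLOCATION,
    RearrangementEvent,
    apply_event,
    emit_dataset,
    evolve,
    make_ancestor,
    replay,
    replay_states,
)


def ev(etype, **kw):
    kw.setdefault("seed", 7)
    return RearrangementEvent(etype, branch=None, **kw)


class TestMakeAncestor:
    def test_counts(self):
        anc, mlg_map = make_ancestor(20, 200, seed=1)
        assert len(anc.chroms) == 20
        assert anc.n_genes == 4000
        assert len(mlg_map) == 4000
        assert sorted(set(mlg_map.values())) == list(range(1, 21))

    def test_single_chromosome(self):
        anc, _ = make_ancestor(1, 5, seed=3)
        assert list(anc.chroms) == ["LG01"]
        assert len(anc.chroms["LG01"]) == 5

    def test_deterministic(self):
        a, ma = make_ancestor(4, 10, seed=9)
        b, mb = make_ancestor(4, 10, seed=9)
        assert a.chroms == b.chroms and ma == mb

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            make_ancestor(0, 5, seed=1)


class TestApplyEvent:
    def test_pure_block_fusion_preserves_order(self):
        anc, _ = make_ancestor(20, 10, seed=1)
        out = apply_event(anc, ev(FUSION, operands=("LG01", "LG02"), pi=0.0))
        assert len(out.chroms) == 19
        fused = out.chroms["LG01+LG02"]
        assert fused == anc.chroms["LG01"] + anc.chroms["LG02"]

    def test_self_fusion_rejected(self):
        anc, _ = make_ancestor(3, 5, seed=1)
        with pytest.raises(ValidationError, match="itself"):
            apply_event(anc, ev(FUSION, operands=("LG01", "LG01"), pi=0.0))

    def test_fission_splits_at_breakpoint(self):
        anc, _ = make_ancestor(2, 10, seed=1)
        out = apply_event(anc, ev(FISSION, operands=("LG01",), breakpoint=3))
        assert len(out.chroms["LG01/1"]) == 3
        assert len(out.chroms["LG01/2"]) == 7
        assert out.n_genes == anc.n_genes

    @pytest.mark.parametrize("bp", [0, 10, 99])
    def test_fission_breakpoint_out_of_range(self, bp):
        anc, _ = make_ancestor(2, 10, seed=1)
        with pytest.raises(ValidationError, match="breakpoint"):
            apply_event(anc, ev(FISSION, operands=("LG01",), breakpoint=bp))

    def test_duplication_adds_chromosome_and_genes(self):
        anc, _ = make_ancestor(5, 12, seed=1)
        out = apply_event(anc, ev(DUPLICATION, operands=("LG03",), fraction=1.0))
        assert len(out.chroms) == 6
        assert out.n_genes == anc.n_genes + 12
        assert [cp for _, cp in out.chroms["LG03*"]] == [2] * 12

    def test_partial_duplication_copies_fraction(self):
        anc, _ = make_ancestor(2, 100, seed=1)
        out = apply_event(anc, ev(DUPLICATION, operands=("LG01",), fraction=0.6))
        assert len(out.chroms["LG01*"]) == 60
        assert len(out.chroms["LG01"]) == 100  # originals untouched

    def test_translocation_moves_exactly_k_genes(self):
        anc, _ = make_ancestor(10, 50, seed=2)
        out = apply_event(anc, ev(TRANSLOCATION, k=5))
        home = {
            g: c for c, genes in anc.chroms.items() for g in genes
        }
        new_home = {
            g: c for c, genes in out.chroms.items() for g in genes
        }
        moved = [g for g in home if new_home[g] != home[g]]
        assert len(moved) == 5
        assert out.n_genes == anc.n_genes
        # untouched chromosomes keep internal order
        untouched = {home[g] for g in home} - {home[g] for g in moved} - {
            new_home[g] for g in moved
        }
        for c in untouched:
            assert out.chroms[c] == anc.chroms[c]

    def test_shuffle_preserves_content(self):
        anc, _ = make_ancestor(2, 30, seed=5)
        out = apply_event(anc, ev(SHUFFLE, operands=("LG02",)))
        assert sorted(out.chroms["LG02"]) == sorted(anc.chroms["LG02"])
        assert out.chroms["LG01"] == anc.chroms["LG01"]

    @pytest.mark.parametrize(
        "event",
        [
            ev(FUSION, operands=("LG01", "LG02"), pi=0.7),
            ev(FISSION, operands=("LG01",), breakpoint=4),
            ev(TRANSLOCATION, k=3),
            ev(SHUFFLE, operands=("LG02",)),
        ],
    )
    def test_gene_conservation_outside_duplication(self, event):
        anc, _ = make_ancestor(4, 25, seed=11)
        out = apply_event(anc, event)
        flat = sorted(g for genes in out.chroms.values() for g in genes)
        assert flat == sorted(g for genes in anc.chroms.values() for g in genes)


class TestEvolve:
    def _tree(self):
        return read_tree("((A:10,B:10)AB:5,(C:12,D:12)CD:3)R;")

    def test_no_events_leaves_tips_equal_to_ancestor(self):
        anc, mlg_map = make_ancestor(5, 10, seed=1)
        tips, truth = evolve(anc, mlg_map, self._tree(), seed=1)
        for tip in tips.values():
            assert tip.chroms == anc.chroms
        assert truth.events == []

    def test_scripted_fusion_reduces_one_tip(self):
        anc, mlg_map = make_ancestor(5, 10, seed=1)
        script = [{"branch": "A", "type": "fusion", "lgs": [1, 2], "pi": 0.0}]
        tips, truth = evolve(anc, mlg_map, self._tree(), script=script, seed=1)
        assert len(tips["A"].chroms) == 4
        assert all(len(tips[t].chroms) == 5 for t in "BCD")
        assert len(truth.events) == 1

    def test_script_on_missing_branch_rejected(self):
        anc, mlg_map = make_ancestor(3, 5, seed=1)
        with pytest.raises(ValidationError, match="missing branch"):
            evolve(
                anc, mlg_map, self._tree(),
                script=[{"branch": "Z", "type": "fusion", "lgs": [1, 2]}],
                seed=1,
            )

    def test_ledger_replay_reproduces_tips_exactly(self, small_scenario):
        tips, truth, tree = simulate_scenario(small_scenario, seed=5)
        replayed = replay(truth, tree)
        assert set(replayed) == set(tips)
        for t in tips:
            assert replayed[t].chroms == tips[t].chroms

    def test_chiton_ancestor_loses_four_chromosomes(self, small_scenario):
        """Replaying the three stem fusions (one three-way) gives 1n = 20 - 4."""
        _, truth, tree = simulate_scenario(small_scenario, seed=2)
        states = replay_states(truth, tree)
        assert len(states["Mollusca"].chroms) == 20
        assert len(states["Polyplacophora"].chroms) == 16
        assert len(states["Acanthochitona"].chroms) == 10
        assert len(states["Acanthochitona_discrepans"].chroms) == 8
        assert len(states["Acanthochitona_rubrolineata"].chroms) == 8

    def test_same_seed_byte_identical_outputs(self, small_scenario, tmp_path):
        import hashlib, os

        digests = []
        for sub in ("a", "b"):
            tips, truth, tree = simulate_scenario(small_scenario, seed=4)
            out = tmp_path / sub
            emit_dataset(tips, truth, tree, str(out))
            h = hashlib.sha256()
            for root, _, files in sorted(os.walk(out)):
                for f in sorted(files):
                    rel = os.path.relpath(os.path.join(root, f), out)
                    h.update(rel.encode())
                    h.update(open(os.path.join(root, f), "rb").read())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]


class TestEmit:
    def test_dataset_reloads_cleanly(self, small_scenario, tmp_path):
        tips, truth, tree = simulate_scenario(small_scenario, seed=3)
        out = tmp_path / "ds"
        emit_dataset(tips, truth, tree, str(out))
        beds = sorted((out / "genomes").glob("*.bed"))
        assert len(beds) == 7
        genomes = {
            g.genome_id: g
            for g in (read_gene_table(str(p), format="bed") for p in beds)
        }
        groups = read_ortholog_table(str(out / "orthologs.tsv"))
        phylo = read_tree(str(out / "tree.nwk"))
        assert set(phylo.tip_labels) == set(genomes)
        assert len(groups) == small_scenario.n_lgs * small_scenario.genes_per_lg
        # ledger row count equals applied events
        import pandas as pd

        ledger = pd.read_csv(out / "event_ledger.tsv", sep="\t")
        assert len(ledger) == len(truth.events)

    def test_refuses_overwrite_without_force(self, small_scenario, tmp_path):
        tips, truth, tree = simulate_scenario(small_scenario, seed=3)
        out = tmp_path / "ds"
        emit_dataset(tips, truth, tree, str(out))
        with pytest.raises(FileExistsError):
            emit_dataset(tips, truth, tree, str(out))
        emit_dataset(tips, truth, tree, str(out), force=True)

    def test_duplication_paralogs_share_og_id(self, tmp_path):
        anc, mlg_map = make_ancestor(3, 10, seed=1)
        tree = read_tree("((A:5,B:5)AB:1,C:6)R;")
        script = [{"branch": "A", "type": "duplication", "lg": 1, "fraction": 1.0}]
        tips, truth = evolve(anc, mlg_map, tree, script=script, seed=1)
        out = tmp_path / "ds"
        emit_dataset(tips, truth, tree, str(out))
        groups = read_ortholog_table(str(out / "orthologs.tsv"))
        dups = [g for g in groups if g.copy_number.get("A") == 2]
        assert len(dups) == 10


class TestMixingMonotonicity:
    def test_expected_mixing_nondecreasing_in_pi(self):
        """Mean mixing index of fusion output rises with the interleave pi."""
        means = []
        for pi in (0.0, 0.3, 0.6, 1.0):
            vals = []
            for seed in range(20):
                anc, mlg_map = make_ancestor(2, 40, seed=1)
                out = apply_event(
                    anc,
                    RearrangementEvent(
                        FUSION, None, seed=seed, operands=("LG01", "LG02"), pi=pi
                    ),
                )
                labels = [mlg_map[og] for og, _ in out.chroms["LG01+LG02"]]
                vals.append(mixing_index(labels))
            means.append(float(np.mean(vals)))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
        assert means[0] < 0.1 and means[-1] > 0.8
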