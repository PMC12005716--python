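"""Parsimony reconstruction, event calling, duplication calls, mixing."""
import itertools

import numpy as np
import pytest

from conftest import truth_mapping
from helpers import (
    brute_force_parsimony_cost,
    exact_expected_het_adjacencies,
    labeling_cost,
)
from karyolg.formats_io import ValidationError, read_tree
from karyolg.karyo_ancestry import (
    ChromosomeState,
    KaryotypeState,
    call_events,
    classify_duplication_vs_fission,
    colocalization_characters,
    mixing_index,
    pair_column,
    reconstruct_states,
)
from karyolg.sim_evolve import (
    DUPLICATION,
    FISSION,
    TRANSLOCATION,
    RearrangementEvent,
    apply_event,
    make_ancestor,
)


def state_of(node_id, *parts):
    return KaryotypeState(
        node_id=node_id,
        chromosomes=[ChromosomeState(mlgs=frozenset(p)) for p in parts],
    )


class TestCharacters:
    def test_three_way_fused_set_sets_all_pairs(self):
        chars = colocalization_characters(
            {"tipA": [frozenset({4, 16, 18})] + [frozenset({m}) for m in (1, 2)]},
            mlg_count=18,
        )
        row = chars.loc["tipA"]
        for pair in [(4, 16), (4, 18), (16, 18)]:
            assert row[pair_column(*pair)] == 1
        assert row.sum() == 3

    def test_all_singletons_zero_row_and_column_count(self):
        L = 6
        chars = colocalization_characters(
            {"t": [frozenset({m}) for m in range(1, L + 1)]}, mlg_count=L
        )
        assert chars.shape == (1, L * (L - 1) // 2)
        assert chars.loc["t"].sum() == 0


class TestFitch:
    def test_hand_case_sister_pair_fused(self):
        """((A,B),C): a pair fused in A and B only is fused at their ancestor,
        unfused at the root."""
        tree = read_tree("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;")
        fused = frozenset({1, 2})
        tips = {
            "A": [fused], "B": [fused],
            "C": [frozenset({1}), frozenset({2})],
            "D": [frozenset({1}), frozenset({2})],
        }
        states = reconstruct_states(colocalization_characters(tips, 2), tree)
        assert states["AB"].chromosome_count == 1
        assert states["R"].chromosome_count == 2
        assert states["CD"].chromosome_count == 2

    def test_invariant_character_fused_everywhere(self):
        tree = read_tree("((A:1,B:1)AB:1,C:2)R;")
        tips = {t: [frozenset({1, 2})] for t in "ABC"}
        states = reconstruct_states(colocalization_characters(tips, 2), tree)
        assert all(states[n].chromosome_count == 1 for n in states)

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;",
            "(((A:1,B:1)AB:1,C:1)ABC:1,(D:1,E:1)DE:1)R;",
            "((((A:1,B:1)n1:1,C:1)n2:1,(D:1,E:1)n3:1)n4:1,F:1)R;",
        ],
    )
    def test_fitch_cost_equals_brute_force_minimum(self, newick):
        """Fitch final labelings reach the exhaustive minimum-change cost."""
        tree = read_tree(newick)
        tips = sorted(tree.tip_labels)
        rng = np.random.default_rng(17)
        for _ in range(20):
            tip_states = {t: int(rng.integers(2)) for t in tips}
            fused_by_tip = {
                t: [frozenset({1, 2})] if s else [frozenset({1}), frozenset({2})]
                for t, s in tip_states.items()
            }
            states = reconstruct_states(
                colocalization_characters(fused_by_tip, 2), tree
            )
            labels = {
                n: 1 if states[n].chromosome_count == 1 else 0 for n in states
            }
            assert labeling_cost(tree, labels) == brute_force_parsimony_cost(
                tree, tip_states
            )

    def test_dollo_places_single_gain(self):
        """Fusion seen in A and C of ((A,B),C),D under Dollo: gained at the
        MRCA(A, C) with one loss in B, never regained."""
        tree = read_tree("(((A:1,B:1)AB:1,C:1)ABC:1,D:1)R;")
        fused = frozenset({1, 2})
        split = [frozenset({1}), frozenset({2})]
        tips = {"A": [fused], "B": split, "C": [fused], "D": split}
        states = reconstruct_states(
            colocalization_characters(tips, 2), tree, mode="dollo"
        )
        assert states["ABC"].chromosome_count == 1
        assert states["AB"].chromosome_count == 1  # on the path, has a 1-tip below
        assert states["R"].chromosome_count == 2


class TestEventCalls:
    def test_identical_states_no_events(self):
        s = state_of("x", {(1, 1), (2, 1)}, {(3, 1)})
        assert call_events(s, s) == []

    def test_three_way_merge_single_call_two_pairwise_steps(self):
        parent = state_of("p", {(4, 1)}, {(16, 1)}, {(18, 1)}, {(7, 1)})
        child = state_of("c", {(4, 1), (16, 1), (18, 1)}, {(7, 1)})
        calls = call_events(parent, child)
        assert len(calls) == 1
        assert calls[0].event_type == "FUSION"
        assert calls[0].mlgs == frozenset({4, 16, 18})
        assert calls[0].pairwise_count == 2

    def test_split_reported_as_fission(self):
        parent = state_of("p", {(1, 1), (2, 1)})
        child = state_of("c", {(1, 1)}, {(2, 1)})
        calls = call_events(parent, child)
        assert [c.event_type for c in calls] == ["FISSION"]
        assert calls[0].mlgs == frozenset({1, 2})

    def test_new_second_copy_reported_as_duplication(self):
        parent = state_of("p", {(1, 1), (2, 1)})
        child = state_of("c", {(1, 1), (2, 1)}, {(1, 2), (2, 2)})
        calls = call_events(parent, child)
        assert [c.event_type for c in calls] == ["DUPLICATION"]
        assert calls[0].mlgs == frozenset({1, 2})

    def test_child_losing_group_is_error(self):
        parent = state_of("p", {(1, 1)}, {(2, 1)})
        child = state_of("c", {(1, 1)})
        with pytest.raises(ValidationError, match="lost"):
            call_events(parent, child)


class TestDuplicationVsFission:
    def test_rule_arithmetic(self):
        assert classify_duplication_vs_fission(80, 100, threshold=0.5) == "DUPLICATION"
        assert classify_duplication_vs_fission(0, 100, threshold=0.5) == "FISSION"
        assert classify_duplication_vs_fission(50, 100, threshold=0.5) == "DUPLICATION"

    def test_zero_informative_warns_fission(self):
        with pytest.warns(UserWarning, match="low confidence"):
            assert classify_duplication_vs_fission(0, 0) == "FISSION"

    @staticmethod
    def _counts_after(event, noise_moves, seed):
        """Simulate one event on LG1 of a two-LG genome (100 genes each) plus
        translocation noise, then count duplication evidence for LG1."""
        anc, mlg_map = make_ancestor(2, 100, seed=seed)
        out = apply_event(anc, event)
        if noise_moves:
            out = apply_event(
                out,
                RearrangementEvent(TRANSLOCATION, None, seed=seed + 1, k=noise_moves),
            )
        chrom_of: dict[str, list[str]] = {}
        for cid, genes in out.chroms.items():
            for og, _cp in genes:
                chrom_of.setdefault(og, []).append(cid)
        lg1 = [og for og, lg in mlg_map.items() if lg == 1]
        informative = sum(1 for og in lg1 if chrom_of.get(og))
        dup_split = sum(
            1
            for og in lg1
            if len(chrom_of.get(og, [])) == 2 and len(set(chrom_of[og])) == 2
        )
        return dup_split, informative

    def test_simulated_events_classified_perfectly_without_noise(self):
        dup, info = self._counts_after(
            RearrangementEvent(DUPLICATION, None, seed=3, operands=("LG01",), fraction=1.0),
            noise_moves=0, seed=1,
        )
        assert classify_duplication_vs_fission(dup, info) == "DUPLICATION"
        dup, info = self._counts_after(
            RearrangementEvent(FISSION, None, seed=3, operands=("LG01",), breakpoint=50),
            noise_moves=0, seed=1,
        )
        assert classify_duplication_vs_fission(dup, info) == "FISSION"

    def test_classifier_accuracy_under_two_percent_noise(self):
        """>= 95% correct over 100 seeded trials with 2% of genes translocated."""
        correct = 0
        trials = 0
        for seed in range(50):
            dup, info = self._counts_after(
                RearrangementEvent(
                    DUPLICATION, None, seed=seed, operands=("LG01",), fraction=1.0
                ),
                noise_moves=4, seed=seed,  # 4 of 200 genes = 2%
            )
            correct += classify_duplication_vs_fission(dup, info) == "DUPLICATION"
            trials += 1
            dup, info = self._counts_after(
                RearrangementEvent(
                    FISSION, None, seed=seed, operands=("LG01",), breakpoint=50
                ),
                noise_moves=4, seed=seed,
            )
            correct += classify_duplication_vs_fission(dup, info) == "FISSION"
            trials += 1
        assert trials == 100
        assert correct / trials >= 0.95


class TestMixingIndex:
    def test_two_blocks(self):
        assert mixing_index(list("AABB")) == pytest.approx(0.5)

    def test_perfect_alternation(self):
        assert mixing_index(list("ABAB")) == pytest.approx(1.5)

    def test_matches_enumeration_over_all_arrangements(self):
        """Mean observed het adjacencies over all distinct arrangements equals
        the closed-form expectation used by the index."""
        labels = list("AABBB")
        total, count = 0, 0
        for perm in set(itertools.permutations(labels)):
            total += sum(1 for a, b in zip(perm, perm[1:]) if a != b)
            count += 1
        assert total / count == pytest.approx(exact_expected_het_adjacencies(labels))

    def test_large_pure_blocks_near_zero(self):
        labels = ["A"] * 200 + ["B"] * 200
        assert mixing_index(labels) < 0.02

    def test_single_label_not_applicable(self):
        assert mixing_index(list("AAAA")) is None

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            mixing_index(list("AB"))

    def test_mean_index_under_random_permutation_is_one(self):
        """Randomly permuted labels average to index 1.0 +- 0.05."""
        rng = np.random.default_rng(0)
        labels = np.array(["A"] * 30 + ["B"] * 20 + ["C"] * 10)
        vals = []
        for _ in range(1000):
            vals.append(mixing_index(list(rng.permutation(labels))))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestChitonReconstruction:
    def test_route_node_counts(self, chiton_run):
        """The reconstructed route: 20 -> 16 -> 15 -> 15 -> 10 chromosomes."""
        st = chiton_run.states
        assert st["Mollusca"].chromosome_count == 20
        assert st["Polyplacophora"].chromosome_count == 16
        assert st["Chitonida_sl"].chromosome_count == 15
        assert st["Chitonida_ss"].chromosome_count == 15
        assert st["Acanthochitona"].chromosome_count == 10

    def test_root_is_twenty_singletons(self, chiton_run):
        root = chiton_run.states["Mollusca"]
        assert all(len(c.mlgs) == 1 for c in root.chromosomes)

    def test_liolophura_fusion_then_duplication(self, chiton_run):
        """The fused-then-partially-duplicated pair is called FUSION plus
        DUPLICATION of the same two groups, never FISSION."""
        calls = chiton_run.events["Liolophura_japonica"]
        types = sorted(c.event_type for c in calls)
        assert types == ["DUPLICATION", "FUSION"]
        fusion = next(c for c in calls if c.event_type == "FUSION")
        dup = next(c for c in calls if c.event_type == "DUPLICATION")
        assert fusion.mlgs == dup.mlgs
        to_truth = truth_mapping(
            chiton_run.linkage_groups, chiton_run.truth.mlg_map
        )
        assert {to_truth[m] for m in dup.mlgs} == {11, 17}

    def test_poorly_mixed_fusion_flagged(self, chiton_run):
        """The Liolophura fused chromosome (interleave 0.05) is not well mixed,
        while the well-interleaved stem fusions are."""
        lio = chiton_run.states["Liolophura_japonica"]
        to_truth = truth_mapping(
            chiton_run.linkage_groups, chiton_run.truth.mlg_map
        )
        flags = {}
        for chrom in lio.chromosomes:
            truth_set = frozenset(to_truth[m] for m, _cp in chrom.mlgs)
            if chrom.well_mixed is not None:
                flags[truth_set] = chrom.well_mixed
        assert flags[frozenset({11, 17})] is False
        assert flags[frozenset({7, 10})] is True
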