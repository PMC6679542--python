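"""Missing-locus calls, truncation calls, and Dollo loss placement."""

import pytest

from genecomplement.alignment_io import parse_tree
from genecomplement.loss_inference import (
    FlankPlacement,
    PhyloProfile,
    call_missing_locus,
    call_truncation,
    place_loss,
)
import genecomplement.synthetic_data as syn
from test_orthology import make_hit


class TestCallMissingLocus:
    def test_adjacent_gapless_no_hit_is_high_confidence(self):
        verdict, reason = call_missing_locus(FlankPlacement(), [], gapless=True)
        assert verdict == "missing-high"

    def test_gaps_degrade_to_tentative(self):
        verdict, _ = call_missing_locus(FlankPlacement(), [], gapless=False)
        assert verdict == "missing-tentative"

    def test_flanks_at_different_scaffold_ends_undetermined(self):
        flanks = FlankPlacement(same_scaffold=False, at_different_scaffold_ends=True)
        verdict, reason = call_missing_locus(flanks, [], gapless=True)
        assert verdict == "undetermined"
        assert reason == "flanks-on-different-scaffolds"

    def test_significant_intergenic_hit_undetermined(self, rng):
        verdict, reason = call_missing_locus(
            FlankPlacement(), [make_hit(rng, 120)], gapless=True
        )
        assert verdict == "undetermined" and reason == "significant-intergenic-hit"

    def test_flanks_not_found(self):
        verdict, reason = call_missing_locus(
            FlankPlacement(both_found=False), [], gapless=True
        )
        assert verdict == "undetermined" and reason == "flanks-not-found"


class TestCallTruncation:
    @pytest.mark.parametrize(
        "fraction,gapless,ests,expected",
        [
            (0.02, True, False, "truncated-pseudogene"),
            (0.02, False, False, "partial-model"),
            (0.02, True, True, "partial-model"),
            (0.95, True, True, "intact"),
        ],
    )
    def test_routing(self, fraction, gapless, ests, expected):
        assert call_truncation(fraction, gapless, ests) == expected

    def test_fraction_must_be_a_fraction(self):
        with pytest.raises(ValueError):
            call_truncation(1.5, True, False)


class TestPlaceLoss:
    def test_neognath_style_loss(self):
        tree = parse_tree("(alligator,(ratite,(chicken,finch)Neognathae));")
        profile = PhyloProfile(
            "G",
            {"finch": "absent", "chicken": "absent", "ratite": "present",
             "alligator": "present"},
            {"finch": "gapless", "chicken": "gapless"},
        )
        placement = place_loss(profile, tree)
        assert placement.lossBranches == {frozenset({"chicken", "finch"})}
        assert placement.confidence == "high"

    def test_whole_clade_loss_with_outgroup_present(self):
        tree = parse_tree("(alligator,(ratite,(chicken,finch))Aves);")
        profile = PhyloProfile(
            "G",
            {"finch": "absent", "chicken": "absent", "ratite": "absent",
             "alligator": "present"},
            {"finch": "gapless", "chicken": "gapless", "ratite": "gappy"},
        )
        placement = place_loss(profile, tree)
        assert placement.lossBranches == {frozenset({"chicken", "finch", "ratite"})}
        assert placement.confidence == "tentative"

    def test_unknown_leaves_create_ambiguity_set(self):
        tree = parse_tree(
            "(tit,(medium_ground_finch,(bengalese_finch,zebra_finch))finches);"
        )
        profile = PhyloProfile(
            "G",
            {"zebra_finch": "absent", "bengalese_finch": "unknown",
             "medium_ground_finch": "unknown", "tit": "present"},
            {"zebra_finch": "gapless"},
        )
        placement = place_loss(profile, tree)
        assert placement.lossBranches == {
            frozenset({"zebra_finch"}),
            frozenset({"zebra_finch", "bengalese_finch"}),
            frozenset({"zebra_finch", "bengalese_finch", "medium_ground_finch"}),
        }

    def test_all_present_yields_empty_placement(self):
        tree = parse_tree("(a,(b,c));")
        placement = place_loss(
            PhyloProfile("G", {"a": "present", "b": "present", "c": "present"}), tree
        )
        assert placement.lossBranches == set()

    def test_no_present_leaf_rejected(self):
        tree = parse_tree("(a,(b,c));")
        with pytest.raises(ValueError, match="not placeable"):
            place_loss(PhyloProfile("G", {"a": "absent", "b": "absent", "c": "absent"}), tree)

    def test_two_independent_losses_reported_as_two_clades(self):
        tree = parse_tree("((a,b)AB,((c,d)CD,e));")
        profile = PhyloProfile(
            "G",
            {"a": "absent", "b": "absent", "c": "absent", "d": "absent",
             "e": "present"},
        )
        placement = place_loss(profile, tree)
        assert placement.lossBranches == {
            frozenset({"a", "b"}), frozenset({"c", "d"}),
        }

    def test_matches_exhaustive_enumeration_on_small_trees(self, rng):
        """Full-knowledge placement equals an independent enumeration of the
        maximal all-absent branches, over random trees of up to 8 leaves."""
        for _ in range(200):
            n = int(rng.integers(3, 9))
            leaves = [f"L{i}" for i in range(n)]
            tree = parse_tree(syn._random_ingroup_tree(leaves, rng) + ";")
            states = {
                lf: ("absent" if rng.random() < 0.4 else "present") for lf in leaves
            }
            if all(s == "absent" for s in states.values()):
                states[leaves[0]] = "present"
            # independent oracle: enumerate every branch, keep all-absent
            # branches, reduce to maximal ones by set inclusion
            branches = []
            for node in tree.preorder_node_iter():
                bl = frozenset(x.taxon.label for x in node.leaf_iter())
                if bl != frozenset(leaves) and all(states[x] == "absent" for x in bl):
                    branches.append(bl)
            expected = {
                b for b in branches if not any(b < o for o in branches)
            }
            if not any(s == "absent" for s in states.values()):
                expected = set()
            placement = place_loss(PhyloProfile("G", states), tree)
            assert placement.lossBranches == expected

    def test_masking_leaves_never_shrinks_the_ambiguity_set(self, rng):
        """Turning present leaves unknown can only widen the candidate set
        around a planted single-clade loss."""
        for _ in range(50):
            n = int(rng.integers(4, 9))
            leaves = [f"L{i}" for i in range(n)]
            tree = parse_tree(syn._random_ingroup_tree(leaves, rng) + ";")
            internal = [
                nd for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and nd is not tree.seed_node
            ]
            if not internal:
                continue
            clade = {
                x.taxon.label
                for x in internal[int(rng.integers(0, len(internal)))].leaf_iter()
            }
            states = {lf: ("absent" if lf in clade else "present") for lf in leaves}
            prev = place_loss(PhyloProfile("G", dict(states)), tree).lossBranches
            maskable = [lf for lf in leaves if states[lf] == "present"]
            rng.shuffle(maskable)
            for lf in maskable[:-1]:  # keep one present leaf
                states[lf] = "unknown"
                cur = place_loss(PhyloProfile("G", dict(states)), tree).lossBranches
                assert prev <= cur
                prev = cur

    def test_planted_losses_always_contained_with_unknown_leaves(self):
        config = syn.SimulationConfig(seed=11, nSpecies=8, lossRate=0.2, unknownRate=0.1)
        dataset = syn.simulate_dataset(config)
        checked = 0
        for gene, branch in dataset.truth.loss_branch.items():
            if branch is None:
                continue
            profile = next(p for p in dataset.profiles if p.gene == gene)
            if not profile.leaves_in("present"):
                continue
            placement = place_loss(profile, dataset.tree)
            assert branch in placement.lossBranches, gene
            checked += 1
        assert checked > 0
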