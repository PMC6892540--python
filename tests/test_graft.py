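"""Rescale-and-graft assembly."""

import numpy as np
import pytest

from chronograft.graft import (
    GraftError,
    GraftPlan,
    PatchDefinition,
    graft_one,
    graft_sets,
    patch_relative_scale,
)
from chronograft.simulate import (
    SyntheticScenario,
    decompose_scenario,
    simulate_bd_tree,
)
from chronograft.trees import (
    TreeSet,
    clade_tips,
    is_ultrametric,
    mrca,
    node_ages,
    parse_tree,
)


def ages_by_clade(tree):
    return {clade_tips(n): a for n, a in node_ages(tree).items() if not n.is_leaf}


def toy_patch_def(**kw):
    defaults = dict(
        name="p1",
        representative="Rep",
        outgroup="Out",
        ingroup=frozenset({"a", "b"}),
    )
    defaults.update(kw)
    return PatchDefinition(**defaults)


class TestPatchRelativeScale:
    def test_hand_ages(self):
        patch = parse_tree("(Out:1,(a:0.6,b:0.6):0.4);", units="relative")
        scale = patch_relative_scale(patch, toy_patch_def())
        assert scale.root_rel_age == pytest.approx(1.0)
        assert scale.crown_rel_age == pytest.approx(0.6)
        assert scale.ratio == pytest.approx(0.6)

    def test_zero_stem_gives_ratio_one(self):
        patch = parse_tree("(Out:1,(a:1,b:1):0);", units="relative")
        assert patch_relative_scale(patch, toy_patch_def()).ratio == pytest.approx(1.0)

    def test_non_ultrametric_patch_rejected(self):
        patch = parse_tree("(Out:1,(a:0.6,b:0.9):0.4);", units="relative")
        with pytest.raises(GraftError, match="ultrametric"):
            patch_relative_scale(patch, toy_patch_def())

    def test_singleton_ingroup_flagged_degenerate(self):
        patch = parse_tree("(Out:1,a:1);", units="relative")
        scale = patch_relative_scale(
            patch, toy_patch_def(ingroup=frozenset({"a"}))
        )
        assert scale.degenerate and scale.ratio == 0.0


class TestGraftOne:
    def backbone(self):
        return parse_tree("((Rep:10,Out:10):5,Z:15);")

    def test_hand_execution_of_steps(self):
        patch = parse_tree("(Out:1,(a:0.6,b:0.6):0.4);", units="relative")
        full = graft_one(self.backbone(), {"p1": (toy_patch_def(), patch)})
        by_clade = ages_by_clade(full)
        assert by_clade[frozenset({"a", "b"})] == pytest.approx(6.0)
        assert by_clade[frozenset({"a", "b", "Out"})] == pytest.approx(10.0)
        assert by_clade[frozenset({"a", "b", "Out", "Z"})] == pytest.approx(15.0)
        assert is_ultrametric(full)

    def test_ratio_one_crown_equals_backbone_mrca_age(self):
        patch = parse_tree("(Out:1,(a:1,b:1):0);", units="relative")
        full = graft_one(self.backbone(), {"p1": (toy_patch_def(), patch)})
        assert ages_by_clade(full)[frozenset({"a", "b"})] == pytest.approx(10.0)

    def test_degenerate_patch_is_pure_relabel(self):
        patch = parse_tree("(Out:1,a:1);", units="relative")
        definition = toy_patch_def(ingroup=frozenset({"a"}))
        full = graft_one(self.backbone(), {"p1": (definition, patch)})
        assert sorted(full.tip_labels) == ["Out", "Z", "a"]
        relabeled = {
            frozenset("a" if lab == "Rep" else lab for lab in clade): age
            for clade, age in ages_by_clade(self.backbone()).items()
        }
        assert ages_by_clade(full) == pytest.approx(relabeled)

    def test_placeholder_taxa_pruned_before_rescaling(self):
        patch = parse_tree(
            "(Out:1,((a:0.3,ph:0.3):0.3,b:0.6):0.4);", units="relative"
        )
        definition = toy_patch_def(placeholders=frozenset({"ph"}))
        full = graft_one(self.backbone(), {"p1": (definition, patch)})
        assert "ph" not in full.tip_labels
        assert ages_by_clade(full)[frozenset({"a", "b"})] == pytest.approx(6.0)

    def test_crown_mode_anchors_to_named_backbone_node(self):
        backbone = parse_tree("((Rep:10,Out:10):5,Z:15);")
        patch = parse_tree("(Dist:1,(a:0.2,b:0.2):0.8);", units="relative")
        definition = toy_patch_def(
            outgroup="Dist",
            rescale_mode="crown",
            crown_anchor=("Rep", "Out"),
        )
        full = graft_one(backbone, {"p1": (definition, patch)})
        # in-group crown placed exactly at the anchored node age
        assert ages_by_clade(full)[frozenset({"a", "b"})] == pytest.approx(10.0)

    def test_negative_branch_guard(self):
        # representative pendant spans ages [0, 15]; stem node at 15 with
        # ratio 1 grafts at the parent age boundary; deeper is an error
        backbone = parse_tree("((Rep:10,Out:10):5,Z:15);")
        patch = parse_tree("(Dist:1,(a:0.9,b:0.9):0.1);", units="relative")
        definition = toy_patch_def(
            outgroup="Dist", rescale_mode="crown", crown_anchor=("Out", "Z")
        )
        with pytest.raises(GraftError, match="negative branch"):
            graft_one(backbone, {"p1": (definition, patch)})

    def test_backbone_ages_conserved(self):
        patch = parse_tree("(Out:1,(a:0.6,b:0.6):0.4);", units="relative")
        backbone = parse_tree("(((Rep:10,Out:10):5,Z:15):3,W:18);")
        before = ages_by_clade(backbone)
        full = graft_one(backbone, {"p1": (toy_patch_def(), patch)})
        after = ages_by_clade(full)
        for clade, age in before.items():
            mapped = frozenset().union(
                *({"a", "b"} if lab == "Rep" else {lab} for lab in clade)
            )
            assert after[mapped] == pytest.approx(age, abs=1e-9)


class TestGraftSets:
    def make_plan(self, n):
        backbone = TreeSet(
            [parse_tree("((Rep:10,Out:10):5,Z:15);") for _ in range(n)]
        )
        patches = TreeSet(
            [
                parse_tree("(Out:1,(a:0.6,b:0.6):0.4);", units="relative")
                for _ in range(n)
            ]
        )
        return GraftPlan(backbone, {"p1": (toy_patch_def(), patches)})

    def test_single_sample(self):
        full = graft_sets(self.make_plan(1))
        assert len(full) == 1 and full[0].n_tips == 4

    def test_sample_count_mismatch_detected_before_work(self):
        plan = self.make_plan(2)
        with pytest.raises(GraftError, match="mismatch"):
            GraftPlan(plan.backbone, {"p1": (toy_patch_def(), TreeSet(
                plan.patches["p1"][1].trees[:1]))})

    def test_overlapping_ingroups_rejected(self):
        backbone = TreeSet([parse_tree("((Rep:10,Out:10):5,Z:15);")])
        ts = TreeSet([parse_tree("(Out:1,(a:0.6,b:0.6):0.4);", units="relative")])
        with pytest.raises(GraftError, match="overlap"):
            GraftPlan(
                backbone,
                {
                    "p1": (toy_patch_def(), ts),
                    "p2": (toy_patch_def(name="p2", representative="Z"), ts),
                },
            )


class TestRoundTrip:
    """Decompose a known true tree and graft it back (the master oracle)."""

    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_zero_jitter_recovers_truth(self, seed):
        scenario = SyntheticScenario(
            seed=seed, n_tips=40, n_patches=3, posterior_size=1, age_jitter=0.0
        )
        true = simulate_bd_tree(
            scenario.birth, scenario.death, scenario.n_tips, rng=scenario.rng()
        )
        _, _, plan, truth = decompose_scenario(true, scenario)
        full = graft_sets(plan)[0]
        want, got = ages_by_clade(truth.tree), ages_by_clade(full)
        assert set(want) == set(got)
        for clade in want:
            assert got[clade] == pytest.approx(want[clade], abs=1e-6)

    def test_jittered_sets_stay_ultrametric_and_conserve_backbone(self):
        scenario = SyntheticScenario(
            seed=3, n_tips=40, n_patches=3, posterior_size=20, age_jitter=0.05
        )
        true = simulate_bd_tree(
            scenario.birth, scenario.death, scenario.n_tips, rng=scenario.rng()
        )
        backbone_ts, patches, plan, _ = decompose_scenario(true, scenario)
        full = graft_sets(plan)
        assert len(full) == len(backbone_ts)
        reps = {d.representative: d.ingroup for d, _ in patches.values()}
        for bb, tree in zip(backbone_ts, full):
            assert is_ultrametric(tree, 1e-6)
            before = ages_by_clade(bb)
            after = ages_by_clade(tree)
            for clade, age in before.items():
                mapped = frozenset().union(
                    *(reps.get(lab, {lab}) for lab in clade)
                )
                assert after[mapped] == pytest.approx(age, abs=1e-9)

    def test_tip_conservation(self):
        scenario = SyntheticScenario(
            seed=4, n_tips=30, n_patches=2, posterior_size=5, age_jitter=0.03
        )
        true = simulate_bd_tree(
            scenario.birth, scenario.death, scenario.n_tips, rng=scenario.rng()
        )
        backbone_ts, patches, plan, _ = decompose_scenario(true, scenario)
        n_ingroup = sum(len(d.ingroup) for d, _ in patches.values())
        n_backbone = backbone_ts[0].n_tips
        for tree in graft_sets(plan):
            assert tree.n_tips == n_backbone - len(patches) + n_ingroup
            assert len(set(tree.tip_labels)) == tree.n_tips
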