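"""Synthetic generators: determinism, contracts, and consistency oracles."""

import numpy as np
import pytest

from chronograft.paleo import max_stem_age, zombie_check
from chronograft.simulate import (
    RankThresholds,
    SimulationError,
    SyntheticScenario,
    attach_outgroup,
    choose_patches,
    decompose_scenario,
    impute_missing_species,
    jittered_tree_set,
    simulate_bd_tree,
    simulate_gene_alignments,
    simulate_occurrences,
    simulate_taxonomy_and_sampling,
)
from chronograft.constraints import PatchInputBundle, build_constraints
from chronograft.taxonomy import classify_sampling_types
from chronograft.trees import (
    clade_tips,
    is_ultrametric,
    mrca,
    node_ages,
    prune_to,
)


class TestBDTree:
    def test_exact_tip_count_and_ultrametricity(self):
        for n in (2, 5, 17):
            t = simulate_bd_tree(0.3, 0.1, n, seed=1)
            assert t.n_tips == n
            assert is_ultrametric(t)

    def test_two_tips_is_a_cherry(self):
        t = simulate_bd_tree(0.5, 0.0, 2, seed=0)
        assert t.n_tips == 2 and len(t.root.children) == 2

    def test_same_seed_identical(self):
        a = simulate_bd_tree(0.3, 0.1, 10, seed=42)
        b = simulate_bd_tree(0.3, 0.1, 10, seed=42)
        assert a.write() == b.write()

    def test_invalid_rates_rejected(self):
        with pytest.raises(SimulationError):
            simulate_bd_tree(0.1, 0.2, 5)

    def test_yule_crown_age_matches_closed_form(self):
        """Mean crown age of a pure-birth clade of n extant species is
        sum_{k=2..n} 1/(k*lambda); check within 3 SE at modest replication."""
        lam, n, reps = 0.3, 10, 300
        rng = np.random.default_rng(123)
        crowns = [
            max(node_ages(simulate_bd_tree(lam, 0.0, n, rng=rng)).values())
            for _ in range(reps)
        ]
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        se = np.std(crowns, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(crowns) - expected) < 3 * se


class TestDecompose:
    def scenario(self, **kw):
        base = dict(seed=2, n_tips=40, n_patches=3, posterior_size=4,
                    age_jitter=0.05)
        base.update(kw)
        return SyntheticScenario(**base)

    def test_patches_are_disjoint_clades(self):
        sc = self.scenario()
        true = simulate_bd_tree(sc.birth, sc.death, sc.n_tips, rng=sc.rng())
        patches = choose_patches(true, sc.n_patches, sc.min_patch_size)
        seen = set()
        for tips in patches.values():
            assert not (tips & seen)
            seen |= tips
            assert clade_tips(mrca(true, tips)) == tips

    def test_relative_patch_roots_are_unity(self):
        sc = self.scenario()
        true = simulate_bd_tree(sc.birth, sc.death, sc.n_tips, rng=sc.rng())
        _, patch_sets, _, _ = decompose_scenario(true, sc)
        for name, (definition, ts) in patch_sets.items():
            for tree in ts:
                assert max(node_ages(tree).values()) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_zero_jitter_sets_are_constant(self):
        sc = self.scenario(age_jitter=0.0, posterior_size=3)
        true = simulate_bd_tree(sc.birth, sc.death, sc.n_tips, rng=sc.rng())
        backbone_ts, _, _, _ = decompose_scenario(true, sc)
        texts = {t.write() for t in backbone_ts}
        assert len(texts) == 1

    def test_jitter_preserves_node_order(self):
        sc = self.scenario(age_jitter=0.3, posterior_size=5)
        true = simulate_bd_tree(sc.birth, sc.death, sc.n_tips, rng=sc.rng())
        ts = jittered_tree_set(true, 5, 0.3, sc.rng())
        for tree in ts:
            ages = node_ages(tree)
            for node, age in ages.items():
                for child in node.children:
                    assert age >= ages[child]
            assert is_ultrametric(tree)


class TestTaxonomySampling:
    def build(self, fraction, seed=3):
        tree = simulate_bd_tree(0.3, 0.05, 30, seed=5)
        return simulate_taxonomy_and_sampling(
            tree, RankThresholds(2.0, 5.0, 50.0), fraction, seed=seed
        )

    def test_zero_fraction_all_type_one(self):
        _, master, sampled = self.build(0.0)
        typing = classify_sampling_types(master, sampled)
        assert typing.counts() == {1: len(master)}

    def test_all_types_represented_at_moderate_fraction(self):
        _, master, sampled = self.build(0.3)
        typing = classify_sampling_types(master, sampled)
        counts = typing.counts()
        assert all(counts.get(k, 0) >= 1 for k in (1, 2, 3, 4))

    def test_typing_partitions_missing_set(self):
        _, master, sampled = self.build(0.3)
        typing = classify_sampling_types(master, sampled)
        counts = typing.counts()
        n_missing = len(master) - len(sampled)
        assert (
            counts.get(2, 0) + counts.get(3, 0) + counts.get(4, 0)
            + len(typing.orphans)
            == n_missing
        )

    def test_binomials_encode_genus(self):
        _, master, _ = self.build(0.2)
        for sp, genus in zip(master.table["species"], master.table["genus"]):
            assert sp.split("_")[0] == genus


class TestImputation:
    def completed_setup(self, n_samples=20):
        tree = simulate_bd_tree(0.25, 0.1, 40, seed=11)
        rt, master, sampled = simulate_taxonomy_and_sampling(
            tree, RankThresholds(3.0, 8.0, 100.0), 0.25, seed=7
        )
        typing = classify_sampling_types(master, sampled)
        missing = [
            m for m in typing.missing_species() if m not in set(typing.orphans)
        ]
        guide = attach_outgroup(prune_to(rt, sampled), "OUTG")
        bundle = PatchInputBundle(
            "p", guide, set(sampled), typing, outgroup="OUTG", taxonomy=master
        )
        cs = build_constraints(bundle)
        base = prune_to(rt, sampled)
        ts = jittered_tree_set(base, n_samples, 0.0, np.random.default_rng(3))
        return ts, cs, missing, sampled

    def test_completed_tip_counts_and_ultrametricity(self):
        ts, cs, missing, sampled = self.completed_setup()
        completed = impute_missing_species(ts, cs, missing, seed=13)
        for tree in completed:
            assert tree.n_tips == len(sampled) + len(missing)
            assert is_ultrametric(tree, 1e-6)

    def test_missing_species_attach_inside_placement_clade(self):
        ts, cs, missing, _ = self.completed_setup(n_samples=5)
        completed = impute_missing_species(ts, cs, missing, seed=13)
        for sp in missing:
            clade = cs.placement_clade(sp)
            anchor = {t for t in clade if t not in missing}
            for tree in completed:
                # the species' sister group must lie within the clade's span
                node = tree.find_tip(sp)
                sisters = clade_tips(node.parent) - {sp}
                span = clade_tips(mrca(tree, anchor)) | set(missing)
                assert sisters <= span

    def test_single_edge_clade_attachment_height_uniform(self):
        """One missing species whose placement clade is a single pendant edge:
        the attachment height must be uniform on (0, pendant length)."""
        from chronograft.constraints import Constraint, ConstraintSet
        from chronograft.trees import TreeSet, parse_tree

        t = parse_tree("((A:2,B:2):8,C:10);")
        cs = ConstraintSet(
            [Constraint("c_x", "partial", frozenset({"C", "X"}), frozenset({"A", "B"}))]
        )
        ts = TreeSet([t.copy() for _ in range(400)])
        completed = impute_missing_species(ts, cs, ["X"], seed=5)
        heights = [
            node_ages(tree)[tree.find_tip("X").parent] for tree in completed
        ]
        assert 0 < min(heights) and max(heights) < 10
        # uniform on (0, 10): mean 5, sd 10/sqrt(12)
        assert np.mean(heights) == pytest.approx(5.0, abs=3 * 10 / np.sqrt(12 * 400))


class TestOccurrences:
    def ranked_tree(self):
        tree = simulate_bd_tree(0.3, 0.05, 30, seed=5)
        return simulate_taxonomy_and_sampling(
            tree, RankThresholds(2.0, 5.0, 50.0), 0.0, seed=1
        )

    def test_high_rate_approaches_stem_age(self):
        rt, master, _ = self.ranked_tree()
        occ = simulate_occurrences(rt, master, 50.0, seed=2)
        ages = node_ages(rt)
        tab = master.table
        for order in tab["order"].unique():
            tips = set(tab.loc[tab["order"] == order, "species"])
            node = (
                mrca(rt, tips) if len(tips) > 1 else rt.find_tip(min(tips))
            )
            stem_age = (
                ages[node.parent] if node.parent is not None else ages[node]
            )
            got = max_stem_age(occ, order)
            assert got is not None
            assert got <= stem_age * 1.02 + 1e-9
            assert got >= (ages[node] if not node.is_leaf else 0.0) - 1e-9

    def test_zero_occurrences_reported_as_no_data(self):
        rt, master, _ = self.ranked_tree()
        occ = simulate_occurrences(rt, master, 50.0, seed=2)
        assert max_stem_age(occ, "NotAClade") is None

    def test_zombie_never_fires_on_crown_consistent_data(self):
        """Crown-restricted occurrences can never imply a crown older than
        the true molecular crown age."""
        rt, master, _ = self.ranked_tree()
        occ = simulate_occurrences(
            rt, master, 20.0, seed=3, include_stem=False
        )
        ages = node_ages(rt)
        tab = master.table
        for order in tab["order"].unique():
            tips = set(tab.loc[tab["order"] == order, "species"])
            if len(tips) < 2:
                continue
            crown_age = ages[mrca(rt, tips)]
            fossil_min = None
            sub = occ.filtered()
            sub = sub.loc[sub["clade"] == order]
            if sub.empty:
                continue
            fossil_min = float(sub["min_ma"].max())
            assert not zombie_check((0.0, crown_age), fossil_min).flagged


class TestGeneAlignments:
    def test_structure_and_coverage(self):
        taxa = [f"t{i}" for i in range(10)]
        alns = simulate_gene_alignments(
            taxa, [("g1", 120), ("g2", 300)], coverage=0.5, seed=4
        )
        assert [a.name for a in alns] == ["g1", "g2"]
        for aln, length in zip(alns, (120, 300)):
            assert aln.n_sites == length
            assert 2 <= len(aln.taxa) <= 10
            assert set(aln.taxa) <= set(taxa)
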