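from __future__ import annotations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from panphage.ancestral import extract_events, reconstruct_fitch
from panphage.association import (
    AnalysisConfig,
    bh_adjust,
    dissociation_score,
    null_distribution,
    pair_pvalue,
    sample_placements,
    simultaneous_score,
    summarize_results,
)
from panphage.association import test_all_pairs as run_all_pairs

from _oracles import exact_null_tails
from conftest import gene_matrix, star_tree, tree_from_newick


class TestScores:
    def test_simultaneous(self):
        ev_i = {("b1", "gain"), ("b4", "loss")}
        ev_j = {("b1", "gain"), ("b2", "gain")}
        assert simultaneous_score(ev_i, ev_j) == 1

    def test_identical_histories_score_their_size(self):
        ev = {("b1", "gain"), ("b2", "loss"), ("b3", "gain")}
        assert simultaneous_score(ev, ev) == 3
        assert dissociation_score(ev, ev) == 0

    def test_disjoint_branches_zero(self):
        assert simultaneous_score({("b1", "gain")}, {("b2", "gain")}) == 0

    def test_dissociation(self):
        assert dissociation_score({("b1", "gain")}, {("b1", "loss")}) == 1
        ev_i = {("b1", "gain"), ("b2", "loss")}
        ev_j = {("b1", "loss"), ("b2", "gain")}
        assert dissociation_score(ev_i, ev_j) == 2

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        branches = [f"b{i}" for i in range(10)]
        for _ in range(20):
            ev_i = {(b, rng.choice(["gain", "loss"])) for b in rng.choice(branches, 3)}
            ev_j = {(b, rng.choice(["gain", "loss"])) for b in rng.choice(branches, 4)}
            assert simultaneous_score(ev_i, ev_j) == simultaneous_score(ev_j, ev_i)
            assert dissociation_score(ev_i, ev_j) == dissociation_score(ev_j, ev_i)


class TestNull:
    def test_equal_star_single_gain_match_prob(self):
        tree = star_tree([1, 1, 1, 1])
        g = 20000
        nd = null_distribution({("L1", "gain")}, 1, 0, tree, g, seed=11)
        p = nd.pvalue(1)
        se = np.sqrt(0.25 * 0.75 / g)
        assert abs(p - 0.25) <= 3 * se

    def test_weighted_star_zero_length_never_drawn(self):
        tree = star_tree([2, 1, 1, 0])
        g = 20000
        branches, _ = sample_placements(tree, 1, 0, g, seed=2)
        assert (branches != 4).all()  # node 4 has the zero-length branch
        nd = null_distribution({("L1", "gain")}, 1, 0, tree, g, seed=2)
        se = np.sqrt(0.5 * 0.5 / g)
        assert abs(nd.pvalue(1) - 0.5) <= 3 * se

    def test_type_mismatch_gives_zero_scores(self):
        tree = star_tree([1, 1, 1, 1])
        nd = null_distribution({("L1", "gain")}, 0, 1, tree, 1000, seed=3)
        assert nd.sim_counts[0] == 1000  # losses never match fixed gains

    def test_too_many_events_rejected(self):
        tree = star_tree([1, 1, 0])
        with pytest.raises(ValueError, match="positive-length"):
            sample_placements(tree, 2, 1, 100, seed=0)

    def test_exact_enumeration_agreement_multi_event(self):
        """Monte Carlo tails match exhaustive enumeration on a 5-branch star."""
        tree = star_tree([2.0, 1.0, 1.0, 0.5, 0.0])
        weights = np.concatenate([[0.0], tree.blen[1:]])
        g = 20000
        ev_i = {("L1", "gain"), ("L2", "loss")}
        gain_b, loss_b = {1}, {2}
        for kg, kl in [(1, 0), (1, 1), (2, 1)]:
            sim_tails, dis_tails = exact_null_tails(weights, gain_b, loss_b, kg, kl)
            nd = null_distribution(ev_i, kg, kl, tree, g, seed=kg * 10 + kl)
            for s, exact in sim_tails.items():
                if s == 0:
                    continue
                mc = nd.pvalue(s, "association")
                se = np.sqrt(exact * (1 - exact) / g)
                assert abs(mc - exact) <= 3 * se + 2 / g, (kg, kl, s)


class TestPValue:
    def test_observed_zero_is_one(self):
        scores = np.array([0, 1, 0, 2])
        assert pair_pvalue(0, scores) == 1.0

    def test_unreachable_observed_is_min(self):
        scores = np.zeros(999, dtype=int)
        assert pair_pvalue(50, scores) == 1 / 1000

    def test_monotone_in_observed(self):
        tree = star_tree([1, 1, 1, 1, 1])
        nd = null_distribution(
            {("L1", "gain"), ("L2", "gain")}, 2, 0, tree, 5000, seed=4
        )
        ps = [nd.pvalue(s) for s in range(4)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBH:
    def test_hand_computed_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04], m=4)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.3], m=1)[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_statsmodels_when_family_is_full(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        ours = bh_adjust(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs)

    def test_larger_family_inflates_q(self):
        p = [0.001, 0.02, 0.5]
        assert (bh_adjust(p, m=30) >= bh_adjust(p, m=3)).all()


def _events_from_patterns(patterns: dict[str, list[int]], newick: str):
    tree = tree_from_newick(newick)
    leaves = tree.leaf_labels
    m = gene_matrix(patterns, leaves)
    ev = extract_events(reconstruct_fitch(m, tree), tree)
    return tree, m, ev


class TestTestAllPairs:
    def test_identical_histories_significant(self):
        from panphage.simulate import simulate_neutral_genes, simulate_tree

        tree = simulate_tree(26, seed=42)  # 50 branches
        m, _ = simulate_neutral_genes(tree, 30, seed=1)
        # force two entities to share the exact leaf pattern of a gene
        # with >= 3 events
        ev0 = extract_events(reconstruct_fitch(m, tree), tree)
        counts = ev0.counts()
        src = int(np.argmax(counts))
        assert counts[src] >= 3
        vals = m.values.copy()
        vals[0] = vals[src]
        m2 = gene_matrix(
            {g: vals[i].tolist() for i, g in enumerate(m.entity_ids)}, m.strain_ids
        )
        ev = extract_events(reconstruct_fitch(m2, tree), tree)
        cfg = AnalysisConfig(null_samples=1000, seed=9, min_events=2, coincidence="association")
        res = run_all_pairs(ev, m2.entity_category, tree, cfg)
        target = [
            r for r in res
            if {r.entity_a, r.entity_b} == {m.entity_ids[0], m.entity_ids[src]}
        ]
        assert len(target) == 1
        assert target[0].p_value <= 0.01

    def test_association_only_mode_has_no_dissociation_rows(self, tree5):
        m = gene_matrix(
            {"a": [1, 1, 0, 0, 0], "b": [1, 1, 0, 0, 1], "c": [0, 0, 1, 1, 0]},
            tree5.leaf_labels,
        )
        ev = extract_events(reconstruct_fitch(m, tree5), tree5)
        cfg = AnalysisConfig(
            null_samples=200, seed=1, min_events=1, coincidence="association"
        )
        res = run_all_pairs(ev, m.entity_category, tree5, cfg)
        assert res and all(r.score_type == "association" for r in res)

    def test_results_independent_of_entity_order(self, tree5):
        patterns = {"a": [1, 1, 0, 0, 0], "b": [1, 1, 0, 0, 1], "c": [0, 1, 1, 1, 0]}
        _, m, ev = _events_from_patterns(patterns, "((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);")
        cfg = AnalysisConfig(null_samples=500, seed=3, min_events=1)
        res1 = run_all_pairs(ev, m.entity_category, ev.tree, cfg)
        reversed_patterns = dict(reversed(list(patterns.items())))
        _, m2, ev2 = _events_from_patterns(
            reversed_patterns, "((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);"
        )
        res2 = run_all_pairs(ev2, m2.entity_category, ev2.tree, cfg)
        key = lambda r: (r.entity_a, r.entity_b, r.score_type)
        assert sorted(
            [(r.entity_a, r.entity_b, r.score_type, r.p_value) for r in res1]
        ) == sorted([(r.entity_a, r.entity_b, r.score_type, r.p_value) for r in res2])

    def test_deterministic_across_runs(self, tree5):
        _, m, ev = _events_from_patterns(
            {"a": [1, 0, 0, 1, 0], "b": [1, 1, 0, 0, 1], "c": [0, 1, 1, 0, 0]},
            "((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);",
        )
        cfg = AnalysisConfig(null_samples=300, seed=7, min_events=1)
        r1 = run_all_pairs(ev, m.entity_category, ev.tree, cfg)
        r2 = run_all_pairs(ev, m.entity_category, ev.tree, cfg)
        assert [(x.p_value, x.q_value) for x in r1] == [(x.p_value, x.q_value) for x in r2]

    def test_min_events_excludes_entities(self, tree5):
        _, m, ev = _events_from_patterns(
            {"a": [1, 0, 0, 0, 0], "b": [1, 1, 0, 0, 1], "c": [0, 1, 1, 0, 0]},
            "((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);",
        )
        cfg = AnalysisConfig(null_samples=200, seed=1, min_events=2)
        res = run_all_pairs(ev, m.entity_category, ev.tree, cfg)
        tested = {r.entity_a for r in res} | {r.entity_b for r in res}
        assert "a" not in tested

    def test_no_eligible_entities_empty_result(self, tree5):
        _, m, ev = _events_from_patterns(
            {"a": [1, 1, 1, 1, 1], "b": [0, 0, 0, 0, 0]},
            "((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);",
        )
        cfg = AnalysisConfig(null_samples=200, seed=1, min_events=1)
        assert run_all_pairs(ev, m.entity_category, ev.tree, cfg) == []


class TestSummarize:
    def test_counts_by_category_pair(self):
        from panphage.association import AssociationResult

        def res(a, b, ca, cb, sig=True):
            return AssociationResult(a, b, ca, cb, "association", 2, 0.01, 0.01, sig)

        rows = [
            res("g1", "g2", "bacterial_gene", "bacterial_gene"),
            res("g1", "p1", "bacterial_gene", "phage"),
            res("g2", "p1", "bacterial_gene", "phage"),
            res("g3", "p2", "bacterial_gene", "phage", sig=False),
        ]
        df = summarize_results(rows)
        counts = dict(zip(df["category_pair"], df["significant_pairs"]))
        assert counts == {"gene-gene": 1, "gene-phage": 2}
        assert df["significant_pairs"].sum() == 3

    def test_empty(self):
        assert len(summarize_results([])) == 0
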