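"""Partially linear tree: growth, nested sequence, selection, summaries."""

import numpy as np
import pandas as pd
import pytest

from pltr_immuno.cohort import CohortTable, VariableSpec
from pltr_immuno.glm import fit_logistic
from pltr_immuno.gpltr import (GpltrError, PLTree, SplitRule, TreeNode,
                               assign_leaves, default_min_leaf, fit_gpltr,
                               forward_nested_sequence, grow_maximal_tree,
                               leaf_summaries, parse_tree, render_tree,
                               select_tree)
from pltr_immuno.simulate import (DEFAULT_LINEAR_TERMS, SimConfig,
                                  default_tree_vars, generate_cohort)
from tests.conftest import make_binary_cohort


def planted_split_cohort(rng, n=1000, beta=np.log(5)):
    x = rng.binomial(1, 0.4, n)
    noise = {f"z{i}": rng.binomial(1, 0.3, n) for i in range(3)}
    prob = 1 / (1 + np.exp(-(-1.0 + beta * x)))
    y = (rng.random(n) < prob).astype(int)
    return make_binary_cohort(y, {"x": x, **noise})


class TestGrowMaximalTree:
    def test_min_leaf_above_half_n_gives_root_only(self):
        rng = np.random.default_rng(0)
        cohort = planted_split_cohort(rng, n=200)
        mt = grow_maximal_tree(cohort, [], ["x", "z0"], min_leaf=101)
        assert mt.tree.n_leaves == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_binary_split_found_first(self, seed):
        rng = np.random.default_rng(100 + seed)
        cohort = planted_split_cohort(rng, n=1000)
        mt = grow_maximal_tree(cohort, [], ["x", "z0", "z1", "z2"])
        root = mt.tree.node(0)
        assert not root.is_leaf
        assert root.rule.variable == "x"

    def test_leaves_partition_the_analysis_set(self, medium_cohort):
        cohort, _ = medium_cohort
        mt = grow_maximal_tree(cohort, list(DEFAULT_LINEAR_TERMS),
                               default_tree_vars())
        leaf_n = sum(nd.n for nd in mt.tree.nodes if nd.is_leaf)
        assert leaf_n == mt.tree.node(0).n

    def test_tree_part_never_hurts_in_sample_fit(self, medium_cohort):
        cohort, _ = medium_cohort
        lin = list(DEFAULT_LINEAR_TERMS)
        mt = grow_maximal_tree(cohort, lin, default_tree_vars())
        linear_only = fit_logistic(cohort, lin)
        assert mt.tree.joint_fit.deviance <= linear_only.deviance + 1e-8


class TestForwardSequence:
    def test_root_only_tree_gives_length_one_sequence(self):
        rng = np.random.default_rng(1)
        cohort = planted_split_cohort(rng, n=200)
        mt = grow_maximal_tree(cohort, [], ["x"], min_leaf=150)
        seq = forward_nested_sequence(mt)
        assert len(seq.trees) == 1

    def test_deviance_non_increasing_along_sequence(self, medium_cohort):
        cohort, _ = medium_cohort
        mt = grow_maximal_tree(cohort, list(DEFAULT_LINEAR_TERMS),
                               default_tree_vars())
        seq = forward_nested_sequence(mt)
        devs = seq.deviances
        assert len(devs) == len(mt.tree.nodes) // 2 + 1  # one step per split
        assert all(d2 <= d1 + 1e-6 for d1, d2 in zip(devs, devs[1:]))

    def test_each_member_extends_previous_by_one_split(self, medium_cohort):
        cohort, _ = medium_cohort
        mt = grow_maximal_tree(cohort, list(DEFAULT_LINEAR_TERMS),
                               default_tree_vars())
        seq = forward_nested_sequence(mt)
        for t1, t2 in zip(seq.trees, seq.trees[1:]):
            ids1 = {nd.id for nd in t1.nodes}
            ids2 = {nd.id for nd in t2.nodes}
            assert ids1 < ids2 and len(ids2 - ids1) == 2


class TestSelectTree:
    def test_aic_of_selection_never_exceeds_root(self, medium_cohort):
        cohort, _ = medium_cohort
        res = fit_gpltr(cohort, list(DEFAULT_LINEAR_TERMS),
                        default_tree_vars(), criterion="AIC")
        assert (res.optimal.joint_fit.aic
                <= res.sequence.records[0]["aic"] + 1e-9)

    def test_null_tree_problem_selects_root(self):
        # outcome depends only on the linear part: BIC keeps the root in the
        # vast majority of cohorts (two-sided noise splits rarely clear log n)
        rng = np.random.default_rng(2)
        kept = 0
        for rep in range(10):
            n = 2000
            x = rng.binomial(1, 0.5, n)
            prob = 1 / (1 + np.exp(-(-0.5 + 1.0 * x)))
            y = (rng.random(n) < prob).astype(int)
            cols = {f"g{i}": rng.binomial(1, 0.4, n) for i in range(6)}
            cohort = make_binary_cohort(y, {**cols, "xlin": x})
            cohort.dictionary = [
                s if s.name != "xlin" else
                VariableSpec("xlin", "linear", "binary", ("no", "yes"))
                for s in cohort.dictionary]
            res = fit_gpltr(cohort, ["xlin"], sorted(cols))
            kept += res.optimal.n_leaves == 1
        assert kept >= 9

    def test_bic_definition_counts_linear_plus_leaves(self, medium_cohort):
        cohort, _ = medium_cohort
        res = fit_gpltr(cohort, list(DEFAULT_LINEAR_TERMS), default_tree_vars())
        fit = res.optimal.joint_fit
        n_lin = sum(1 for k in fit.coefficients
                    if k != "(intercept)" and not k.startswith("leaf["))
        assert fit.p == 1 + n_lin + (res.optimal.n_leaves - 1)
        assert fit.bic == pytest.approx(
            fit.deviance + fit.p * np.log(fit.n))


class TestLeafSummaries:
    def make_branch_cohort(self):
        # three branches with the published branch counts: 6/33, 29/62, 23/30
        rows = (["left"] * 33 + ["mid"] * 62 + ["right"] * 30)
        events = ([1] * 6 + [0] * 27 + [1] * 29 + [0] * 33 + [1] * 23 + [0] * 7)
        df = pd.DataFrame({
            "inhibitor": np.where(np.array(events) == 1, "inh+", "inh-"),
            "grp": rows})
        cohort = CohortTable(df, [
            VariableSpec("inhibitor", "outcome", "binary", ("inh-", "inh+")),
            VariableSpec("grp", "tree", "categorical",
                         ("left", "mid", "right"))])
        nodes = [
            TreeNode(0, 0, SplitRule("grp", ("left",)), 1, 2, 125),
            TreeNode(1, 1, None, n=33),
            TreeNode(2, 1, SplitRule("grp", ("mid",)), 3, 4, 92),
            TreeNode(3, 2, None, n=62),
            TreeNode(4, 2, None, n=30),
        ]
        return cohort, PLTree(nodes=nodes)

    def test_raw_rates_reproduce_published_branch_risks(self):
        cohort, tree = self.make_branch_cohort()
        t = leaf_summaries(tree, cohort).set_index("branch")
        assert round(t.loc["3", "raw_rate"], 2) == 0.47   # 29/62 intermediate
        assert round(t.loc["4", "raw_rate"], 2) == 0.77   # 23/30 right branch
        assert round(t.loc["1", "raw_rate"], 2) == 0.18   # 6/33 left branch

    def test_branch_merge_and_totals(self):
        cohort, tree = self.make_branch_cohort()
        t = leaf_summaries(tree, cohort,
                           group_spec={1: "low", 3: "mid", 4: "high"})
        assert t["n"].sum() == 125 and t["events"].sum() == 58

    def test_single_leaf_tree_or_is_an_error(self):
        cohort, _ = self.make_branch_cohort()
        single = PLTree(nodes=[TreeNode(0, 0, None, n=125)])
        with pytest.raises(GpltrError):
            leaf_summaries(single, cohort)

    def test_missing_values_follow_the_recorded_side(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        cohort = make_binary_cohort(y, {"x": np.r_[np.ones(30), np.zeros(30)]})
        cohort.data.loc[5, "x"] = np.nan
        tree = PLTree(nodes=[
            TreeNode(0, 0, SplitRule("x", ("yes",), missing_side="left"), 1, 2),
            TreeNode(1, 1, None), TreeNode(2, 1, None)])
        leaf_of = assign_leaves(tree, cohort)
        assert leaf_of[5] == 1


class TestRenderParse:
    def test_root_only_render(self):
        t = PLTree(nodes=[TreeNode(0, 0, None, n=10, events=4)])
        assert "leaf#0" in render_tree(t)

    def test_json_round_trip_idempotent(self, medium_cohort):
        cohort, _ = medium_cohort
        res = fit_gpltr(cohort, list(DEFAULT_LINEAR_TERMS), default_tree_vars())
        s1 = render_tree(res.optimal, "json")
        s2 = render_tree(parse_tree(s1), "json")
        assert json_nodes(s1) == json_nodes(s2)

    def test_selected_tree_structure_on_planted_cohort(self):
        cohort, _ = generate_cohort(SimConfig(n=2000, seed=0))
        res = fit_gpltr(cohort, list(DEFAULT_LINEAR_TERMS),
                        default_tree_vars())
        n_internal = sum(1 for nd in res.optimal.nodes if not nd.is_leaf)
        assert n_internal == 4
        assert res.optimal.depth <= 3


def json_nodes(s):
    import json
    d = json.loads(s)
    return d["linear_terms"], d["nodes"]


class TestDefaults:
    def test_min_leaf_scaling(self):
        assert default_min_leaf(125) == 10
        assert default_min_leaf(50) == 10
        assert default_min_leaf(2000) == 100
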