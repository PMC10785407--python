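"""CART: impurity, split enumeration/search, growth, pruning, node risks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nihlkit.cart import (
    CartConfig,
    CartFrame,
    CartVariable,
    best_split,
    candidate_splits,
    cart_frame,
    cv_prune,
    grow_tree,
    node_entropy,
    node_risk_table,
    partition_learning_testing,
    prune_at,
)
from nihlkit.simulate import (
    EffectSpec,
    Interaction,
    SimulationConfig,
    default_panel,
    simulate_case_control,
)


class TestEntropy:
    @pytest.mark.parametrize("cases,controls,expect", [
        (10, 0, 0.0),
        (25, 25, 1.0),
        (30, 10, 0.8113),
    ])
    def test_values(self, cases, controls, expect):
        assert node_entropy(cases, controls) == pytest.approx(expect, abs=1e-4)

    def test_empty_node_error(self):
        with pytest.raises(ValueError):
            node_entropy(0, 0)


class TestCandidateSplits:
    def test_genotype_three_bipartitions(self):
        var = CartVariable("snp", "genotype")
        values = np.array(["AA", "AB", "BB", "AB"], dtype=object)
        splits = candidate_splits(var, values)
        assert len(splits) == 3
        assert [sorted(s.left_levels) for s in splits] == [["AA"], ["BB"], ["AB"]]

    def test_boolean_single_split(self):
        var = CartVariable("ppe", "binary")
        assert len(candidate_splits(var, np.array([True, False, True]))) == 1
        assert candidate_splits(var, np.array([True, True])) == []

    def test_numeric_midpoints(self):
        var = CartVariable("age", "numeric")
        splits = candidate_splits(var, np.array([40.0, 45.0, 50.0]))
        assert [s.threshold for s in splits] == [42.5, 47.5]

    def test_numeric_fixed_cutpoints(self):
        var = CartVariable("age", "numeric", cutpoints=(45.0, 95.0))
        splits = candidate_splits(var, np.array([30.0, 50.0, 60.0]))
        assert [s.threshold for s in splits] == [45.0]

    def test_constant_variable_empty(self):
        var = CartVariable("age", "numeric")
        assert candidate_splits(var, np.array([41.0, 41.0])) == []


def brute_force_best(frame, idx, config):
    """Independent exhaustive search: all variables x all partitions,
    recomputing the weighted-entropy gain from first principles."""
    y = frame.y[idx]
    n = len(y)

    def ent(arr):
        k = arr.sum()
        h = 0.0
        for q in (k / len(arr), 1 - k / len(arr)):
            if q > 0:
                h -= q * math.log2(q)
        return h

    parent = ent(y)
    best_gain, best_desc = -1.0, None
    for var in frame.variables:
        values = frame.X[var.name].to_numpy()[idx]
        if var.kind == "genotype":
            partitions = [np.isin(values, [lv]) for lv in ("AA", "BB", "AB")]
        elif var.kind == "binary":
            partitions = [values.astype(bool) == False]  # noqa: E712
        else:
            uniq = np.unique(values.astype(float))
            partitions = [values.astype(float) < (a + b) / 2
                          for a, b in zip(uniq[:-1], uniq[1:])]
        for left in partitions:
            nl = int(left.sum())
            if nl < config.min_node_size or n - nl < config.min_node_size:
                continue
            if nl == 0 or nl == n:
                continue
            gain = parent - (nl * ent(y[left]) + (n - nl) * ent(y[~left])) / n
            if gain > best_gain + 1e-12:
                best_gain = gain
    return best_gain


class TestBestSplit:
    def _random_frame(self, rng, n=40, n_geno=3, n_num=2, n_bool=1):
        cols, variables = {}, []
        for i in range(n_geno):
            cols[f"g{i}"] = rng.choice(["AA", "AB", "BB"], size=n)
            variables.append(CartVariable(f"g{i}", "genotype"))
        for i in range(n_num):
            cols[f"x{i}"] = np.round(rng.normal(50, 8, n), 1)
            variables.append(CartVariable(f"x{i}", "numeric"))
        for i in range(n_bool):
            cols[f"b{i}"] = rng.random(n) < 0.5
            variables.append(CartVariable(f"b{i}", "binary"))
        y = rng.random(n) < 0.4
        return CartFrame(X=pd.DataFrame(cols), y=y, variables=tuple(variables))

    def test_agrees_with_brute_force_oracle(self, rng):
        config = CartConfig(min_node_size=3)
        for _ in range(25):
            frame = self._random_frame(rng)
            idx = np.arange(frame.n)
            found = best_split(frame, idx, config)
            oracle_gain = brute_force_best(frame, idx, config)
            if found is None:
                assert oracle_gain <= config.min_split_gain + 1e-12
            else:
                assert found[1] == pytest.approx(oracle_gain, abs=1e-10)

    def test_pure_node_returns_none(self):
        frame = CartFrame(
            X=pd.DataFrame({"g": np.array(["AA", "BB"] * 10, dtype=object)}),
            y=np.ones(20, dtype=bool),
            variables=(CartVariable("g", "genotype"),))
        assert best_split(frame, np.arange(20), CartConfig(min_node_size=2)) is None

    def test_informative_genotype_selected_among_noise(self, rng):
        """A single strong genotype effect wins the split race essentially always."""
        hits, reps = 0, 60
        panel = default_panel(4, seed=20)
        panel["maf"] = 0.4
        for rep in range(reps):
            cfg = SimulationConfig(
                n_cases=400, n_controls=400, panel=panel, intercept=-0.7,
                effects=(EffectSpec(panel.index[0], GeneticModel_REC, math.log(3)),),
                seed=1000 + rep)
            cohort = simulate_case_control(cfg)
            frame = cart_frame(cohort, list(panel.index), covariates=("smoking",))
            found = best_split(frame, np.arange(frame.n), CartConfig())
            hits += found is not None and found[0].variable == panel.index[0]
        assert hits / reps >= 0.95


# local alias to keep the parametrization short
from nihlkit.association import GeneticModel  # noqa: E402

GeneticModel_REC = GeneticModel.RECESSIVE


class TestGrowTree:
    def _frame(self, rng, n=200):
        cols = {
            "g0": rng.choice(["AA", "AB", "BB"], size=n, p=[0.36, 0.48, 0.16]),
            "age": np.round(rng.normal(48, 6, n), 1),
        }
        y = rng.random(n) < 0.4
        return CartFrame(X=pd.DataFrame(cols), y=y,
                         variables=(CartVariable("g0", "genotype"),
                                    CartVariable("age", "numeric")))

    def test_max_depth_zero_single_node(self, rng):
        frame = self._frame(rng)
        tree = grow_tree(frame, CartConfig(max_depth=0))
        assert tree.root.terminal and len(tree.nodes()) == 1

    def test_child_counts_sum_to_parent(self, rng):
        frame = self._frame(rng, n=400)
        tree = grow_tree(frame, CartConfig(max_depth=4, min_node_size=20))
        for node in tree.nodes():
            if not node.terminal:
                assert node.left.n + node.right.n == node.n
                assert node.left.n_cases + node.right.n_cases == node.n_cases

    def test_gain_non_negative_along_tree(self, rng):
        frame = self._frame(rng, n=400)
        tree = grow_tree(frame, CartConfig(max_depth=4))
        for node in tree.nodes():
            if not node.terminal:
                child = (node.left.n * node.left.impurity
                         + node.right.n * node.right.impurity) / node.n
                assert node.impurity - child >= -1e-12

    def test_deterministic_under_seed(self, rng):
        frame = self._frame(rng, n=300)
        t1 = grow_tree(frame, CartConfig(max_depth=3))
        t2 = grow_tree(frame, CartConfig(max_depth=3))
        assert t1.render() == t2.render()

    def test_terminal_nodes_partition_sample(self, rng):
        frame = self._frame(rng, n=300)
        tree = grow_tree(frame, CartConfig(max_depth=3))
        node_ids = tree.route_frame(frame.X)
        assert (node_ids >= 0).all()
        counts = pd.Series(node_ids).value_counts()
        for t in tree.terminal_nodes():
            assert counts.get(t.node_id, 0) == t.n


class TestPartition:
    def test_stratified_sizes(self):
        y = np.r_[np.ones(40, dtype=bool), np.zeros(60, dtype=bool)]
        learn, test = partition_learning_testing(y, CartConfig(seed=4))
        assert len(learn) + len(test) == 100
        assert np.intersect1d(learn, test).size == 0
        assert int(y[learn].sum()) == 26  # 65% of 40 cases
        assert len(learn) == 65

    def test_same_seed_same_split(self):
        y = np.r_[np.ones(30, dtype=bool), np.zeros(50, dtype=bool)]
        a = partition_learning_testing(y, CartConfig(seed=9))
        b = partition_learning_testing(y, CartConfig(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestPruning:
    def test_pure_noise_prunes_to_root(self):
        """Trees grown on label-independent predictors collapse under CV."""
        roots, reps = 0, 40
        panel = default_panel(5, seed=31)
        for rep in range(reps):
            # replication-stage case:control ratio; an exactly balanced null
            # makes the root classifier a coin toss in CV and is degenerate
            cfg = SimulationConfig(n_cases=153, n_controls=252, panel=panel,
                                   intercept=-0.5, effects=(), seed=2000 + rep)
            cohort = simulate_case_control(cfg)
            frame = cart_frame(cohort, list(panel.index), covariates=("age", "smoking"))
            config = CartConfig(max_depth=4, seed=rep)
            tree = grow_tree(frame, config)
            pruned, _ = cv_prune(tree, frame, config=config)
            roots += len(pruned.terminal_nodes()) == 1
        assert roots / reps >= 0.9

    def test_strong_split_survives_pruning(self):
        kept, reps = 0, 25
        panel = default_panel(3, seed=32)
        panel["maf"] = 0.4
        for rep in range(reps):
            cfg = SimulationConfig(
                n_cases=500, n_controls=500, panel=panel, intercept=-1.0,
                effects=(EffectSpec(panel.index[0], GeneticModel.DOMINANT, math.log(8)),),
                seed=3000 + rep)
            cohort = simulate_case_control(cfg)
            frame = cart_frame(cohort, list(panel.index), covariates=())
            config = CartConfig(max_depth=3, seed=rep)
            pruned, _ = cv_prune(grow_tree(frame, config), frame, config=config)
            kept += any((not n.terminal) and n.split.variable == panel.index[0]
                        for n in pruned.nodes())
        assert kept / reps >= 0.95

    def test_loo_cv_matches_brute_force_on_small_fixture(self, rng):
        """Leave-one-out CV error of the root equals its brute-force LOO error."""
        n = 30
        frame = CartFrame(
            X=pd.DataFrame({"g": rng.choice(["AA", "AB", "BB"], size=n)}),
            y=rng.random(n) < 0.4,
            variables=(CartVariable("g", "genotype"),))
        config = CartConfig(min_node_size=5, cv_folds=n, seed=0, max_depth=2)
        tree = grow_tree(frame, config)
        pruned, profile = cv_prune(tree, frame, config=config)
        # brute-force LOO of the majority-class rule at the root
        y = frame.y
        wrong = 0
        for i in range(n):
            rest = np.delete(y, i)
            pred = rest.sum() > (len(rest) - rest.sum())
            wrong += int(pred != y[i])
        root_row = profile.iloc[-1]
        assert root_row["n_leaves"] == 1
        assert root_row["cv_error"] == pytest.approx(wrong / n)

    def test_prune_at_infinite_alpha_gives_root(self, rng):
        frame = CartFrame(
            X=pd.DataFrame({"age": rng.normal(48, 6, 200)}),
            y=rng.random(200) < 0.5,
            variables=(CartVariable("age", "numeric"),))
        tree = grow_tree(frame, CartConfig(max_depth=3))
        assert len(prune_at(tree, math.inf).terminal_nodes()) == 1


class TestNodeRiskTable:
    def test_reference_is_lowest_case_fraction_and_ors_cross_products(self, rng):
        n = 300
        g = rng.choice(["AA", "AB", "BB"], size=n, p=[0.4, 0.4, 0.2])
        # risk concentrated in BB
        y = np.where(g == "BB", rng.random(n) < 0.7, rng.random(n) < 0.25)
        frame = CartFrame(X=pd.DataFrame({"g": g}), y=y,
                          variables=(CartVariable("g", "genotype"),))
        tree = grow_tree(frame, CartConfig(max_depth=1, min_node_size=10))
        table = node_risk_table(tree, frame)
        assert table["reference"].sum() == 1
        ref = table[table["reference"]].iloc[0]
        other = table[~table["reference"]].iloc[0]
        expect = (other["n_cases"] * ref["n_controls"]) / (other["n_controls"] * ref["n_cases"])
        assert other["or"] == pytest.approx(expect)
        assert ref["or"] == 1.0

    def test_single_terminal_node_is_error(self, rng):
        frame = CartFrame(X=pd.DataFrame({"age": rng.normal(48, 6, 50)}),
                          y=rng.random(50) < 0.5,
                          variables=(CartVariable("age", "numeric"),))
        tree = grow_tree(frame, CartConfig(max_depth=0))
        with pytest.raises(ValueError):
            node_risk_table(tree, frame)


class TestInteractionRecovery:
    def test_planted_snp_age_interaction_found(self):
        """Risk only for BB x age>=45 appears as a root/child split pair."""
        panel = default_panel(4, seed=41)
        panel["maf"] = 0.5
        hits, reps = 0, 30
        for rep in range(reps):
            eff = (EffectSpec(panel.index[0], GeneticModel.RECESSIVE, 0.0,
                              interactions=(Interaction("age", math.log(6),
                                                        threshold=45.0),)),)
            cfg = SimulationConfig(n_cases=500, n_controls=500, panel=panel,
                                   intercept=-1.0, effects=eff, seed=4000 + rep)
            cohort = simulate_case_control(cfg)
            frame = cart_frame(cohort, list(panel.index),
                               covariates=("age", "smoking"))
            tree = grow_tree(frame, CartConfig(max_depth=2, seed=rep))
            root = tree.root
            if root.terminal:
                continue
            vars_l1 = {root.split.variable}
            vars_l2 = {c.split.variable for c in (root.left, root.right)
                       if c is not None and not c.terminal}
            if ({panel.index[0]} <= vars_l1 and "age" in vars_l2) or \
               ("age" in vars_l1 and panel.index[0] in vars_l2):
                hits += 1
        assert hits / reps >= 0.9
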