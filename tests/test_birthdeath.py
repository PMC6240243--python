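"""Birth-death family-size model: kernel, likelihood, estimation, tests."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from famevo.birthdeath import (
    BirthDeathModel,
    GeneFamilyEvolution,
    GeneFamilyEvolutionResults,
    bd_transition_matrix,
    bd_transition_prob,
    estimate_lambda,
    family_log_likelihood,
    family_p_value,
)
from famevo.tables import FamilyCountTable, filter_families
from famevo.trees import DatedSpeciesTree
from famevo import simulate as sim


def expm_oracle(lam: float, t: float, cap: int) -> np.ndarray:
    """Truncated matrix exponential of the linear BD generator."""
    n = cap + 1
    Q = np.zeros((n, n))
    i = np.arange(1, n)
    Q[i, i - 1] = lam * i
    Q[i[:-1], i[:-1] + 1] = lam * i[:-1]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return expm(Q * t)


class TestTransitionKernel:
    @pytest.mark.parametrize("lam,t", [(0.017, 29.0), (0.05, 10.0), (0.2, 4.0), (1.0, 1.0)])
    def test_matches_matrix_exponential(self, lam, t):
        P = bd_transition_matrix(lam, t, 200)
        O = expm_oracle(lam, t, 200)
        assert np.abs(P[:11, :11] - O[:11, :11]).max() <= 1e-8

    def test_no_time_is_identity(self):
        assert bd_transition_prob(3, 3, 0.5, 0.0) == 1.0
        assert bd_transition_prob(3, 4, 0.5, 0.0) == 0.0

    def test_zero_is_absorbing(self):
        assert bd_transition_prob(0, 0, 0.7, 12.0) == 1.0
        assert bd_transition_prob(0, 2, 0.7, 12.0) == 0.0

    def test_rows_are_stochastic_under_truncation(self):
        for lam, t in [(0.017, 29), (0.1, 10), (0.5, 3)]:
            P = bd_transition_matrix(lam, t, 200)
            sums = P[:30].sum(axis=1)
            assert np.all(sums <= 1.0 + 1e-9)
            assert np.all(sums >= 1.0 - 1e-8)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            bd_transition_prob(-1, 2, 0.1, 1.0)
        with pytest.raises(ValueError):
            bd_transition_prob(1, 2, -0.1, 1.0)


def enumeration_loglike(tree, counts, model):
    """Brute-force sum over all internal-node state assignments."""
    mats = {
        n.index: bd_transition_matrix(model.lambda_rate, n.length or 0.0, model.count_cap)
        for n in tree.postorder()
        if n is not tree.root
    }
    internal = [n for n in tree.postorder() if not n.is_leaf]
    states = range(model.count_cap + 1)
    total = 0.0
    for combo in itertools.product(states, repeat=len(internal)):
        assign = {n.index: s for n, s in zip(internal, combo)}
        for n in tree.leaves:
            assign[n.index] = counts[n.label]
        p = model.root_prior[assign[tree.root.index]]
        for n in tree.postorder():
            if n is tree.root:
                continue
            p *= mats[n.index][assign[n.parent.index], assign[n.index]]
        total += p
    return np.log(total) if total > 0 else -np.inf


TREES = [
    "(A:1.5,B:2.5);",
    "((A:2,B:2):3,C:5);",
    "((A:1,B:1):1,(C:1,D:1):1);",
    "(((A:1,B:1):1,C:2):1,D:3);",
]


class TestPruningLikelihood:
    @pytest.mark.parametrize("nwk", TREES)
    def test_matches_enumeration(self, nwk, rng):
        tree = DatedSpeciesTree.from_newick(nwk)
        model = BirthDeathModel(0.08, 6)
        for _ in range(5):
            counts = {t: int(rng.integers(0, 4)) for t in tree.tip_labels}
            ll = family_log_likelihood(tree, counts, model)
            oracle = enumeration_loglike(tree, counts, model)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_point_mass_root_no_time(self):
        tree = DatedSpeciesTree.from_newick("(A:0,B:0);")
        prior = np.zeros(11)
        prior[3] = 1.0
        model = BirthDeathModel(0.1, 10, prior)
        assert family_log_likelihood(tree, {"A": 3, "B": 3}, model) == pytest.approx(0.0)
        assert family_log_likelihood(tree, {"A": 3, "B": 4}, model) == -np.inf

    def test_missing_tip_count_errors(self):
        tree = DatedSpeciesTree.from_newick("(A:1,B:1);")
        model = BirthDeathModel(0.1, 5)
        with pytest.raises(ValueError, match="missing"):
            family_log_likelihood(tree, {"A": 1}, model)


class TestFamilyFilter:
    def test_rules(self):
        table = FamilyCountTable.from_counts(
            ["all_ones", "single_species", "keeper", "zero"],
            ["X", "Y", "Z"],
            [[1, 1, 1], [5, 0, 0], [2, 1, 0], [0, 0, 0]],
        )
        kept = filter_families(table)
        assert kept.family_ids == ["keeper"]

    def test_order_preserved_and_empty_ok(self):
        table = FamilyCountTable.from_counts(
            ["b", "a"], ["X", "Y"], [[2, 1], [3, 2]]
        )
        assert filter_families(table).family_ids == ["b", "a"]
        empty = FamilyCountTable.from_counts(["x"], ["X", "Y"], [[1, 0]])
        assert filter_families(empty).n_families == 0


class TestLambdaEstimation:
    def test_constant_table_boundary(self, species_tree_11):
        counts = np.full((5, 11), 3)
        table = FamilyCountTable.from_counts(
            [f"F{i}" for i in range(5)], species_tree_11.tip_labels, counts
        )
        res = GeneFamilyEvolution(table, species_tree_11).fit()
        assert res.lambda_ == 0.0
        assert res.at_boundary

    def test_recovery_on_simulated_families(self, species_tree_11):
        table, _ = sim.simulate_family_counts(species_tree_11, 0.017, 500, seed=5)
        res = estimate_lambda(filter_families(table), species_tree_11)
        assert res.lambda_ == pytest.approx(0.017, rel=0.2)

    def test_doubling_branch_lengths_halves_lambda(self, species_tree_11):
        table, _ = sim.simulate_family_counts(species_tree_11, 0.017, 120, seed=9)
        table = filter_families(table)
        res1 = estimate_lambda(table, species_tree_11)
        stretched = species_tree_11.calibrate("HMI", "HSI", 58.0)
        res2 = estimate_lambda(table, stretched)
        assert res2.lambda_ == pytest.approx(res1.lambda_ / 2.0, rel=1e-2)


class TestFamilyPValue:
    def test_small_n_null_rejected(self, species_tree_4):
        model = BirthDeathModel(0.1, 10)
        with pytest.raises(ValueError):
            family_p_value({"A": 1, "B": 1, "C": 1, "D": 1}, model, species_tree_4, n_null=50)

    def test_changing_family_impossible_under_frozen_model(self, species_tree_4):
        model = BirthDeathModel(0.0, 10)
        p = family_p_value(
            {"A": 1, "B": 2, "C": 1, "D": 1}, model, species_tree_4, n_null=200, seed=0
        )
        assert p == pytest.approx(1.0 / 201.0)

    def test_modal_family_scores_near_one(self, species_tree_4):
        model = BirthDeathModel(0.001, 10)
        # nearly-frozen process: a constant family is the modal outcome
        p = family_p_value(
            {"A": 2, "B": 2, "C": 2, "D": 2}, model, species_tree_4, n_null=300, seed=1
        )
        assert p > 0.5

    def test_extreme_count_cannot_raise_p(self, species_tree_11):
        table, _ = sim.simulate_family_counts(species_tree_11, 0.017, 40, seed=2)
        table = filter_families(table)
        res = GeneFamilyEvolution(table, species_tree_11).fit()
        fam = table.family_ids[0]
        base = dict(zip(species_tree_11.tip_labels, table.counts()[0]))
        inflated = dict(base)
        inflated["CRO"] = res.model.count_cap  # far above everything else
        p0 = family_p_value(base, res.model, species_tree_11, n_null=300, seed=3)
        p1 = family_p_value(inflated, res.model, species_tree_11, n_null=300, seed=3)
        assert p1 <= p0


class TestAncestralAndBranchCalls:
    def _results(self, tree, table, lam, cap=None):
        spec = GeneFamilyEvolution(table, tree, count_cap=cap)
        model = BirthDeathModel(lam, spec.count_cap, spec.root_prior)
        return GeneFamilyEvolutionResults(spec, model, spec.loglike_per_family(lam))

    def test_constant_family_flat_history(self, species_tree_11):
        counts = np.full((1, 11), 4)
        table = FamilyCountTable.from_counts(["F"], species_tree_11.tip_labels, counts)
        res = self._results(species_tree_11, table, 0.002)
        anc = res.ancestral_counts("F")
        assert all(c == 4 for c, _ in anc.values())
        calls = res.branch_calls("F", family_p=1.0)
        assert all(not c.significant for c in calls)
        assert all(c.direction == "none" for c in calls)

    def test_planted_jump_flagged_as_expansion(self, species_tree_11):
        # every species has 3 genes except a burst to 25 in C. rosea
        counts = {t: 3 for t in species_tree_11.tip_labels}
        counts["CRO"] = 25
        table = FamilyCountTable.from_counts(
            ["F"], species_tree_11.tip_labels, [[counts[t] for t in species_tree_11.tip_labels]]
        )
        res = self._results(species_tree_11, table, 0.002, cap=60)
        calls = res.branch_calls("F", family_p=0.01)
        flagged = [c for c in calls if c.significant]
        assert any(c.child_node == "CRO" and c.direction == "expansion" for c in flagged)

    def test_posterior_tie_reported_smallest(self):
        # craft a root prior that makes root states 1 and 2 exactly
        # equiprobable a posteriori: the smaller count must be reported
        tree = DatedSpeciesTree.from_newick("(A:1,B:1);")
        table = FamilyCountTable.from_counts(["F"], ["A", "B"], [[1, 2]])
        P = bd_transition_matrix(0.25, 1.0, 3)
        lik = np.array([P[r, 1] * P[r, 2] for r in (1, 2)])
        prior = np.zeros(4)
        prior[1] = lik[1] / lik.sum()
        prior[2] = lik[0] / lik.sum()
        spec = GeneFamilyEvolution(table, tree, count_cap=3, root_prior=prior)
        model = BirthDeathModel(0.25, 3, prior)
        res = GeneFamilyEvolutionResults(spec, model, spec.loglike_per_family(0.25))
        ((count, tied),) = res.ancestral_counts("F").values()
        assert tied
        assert count == 1

    def test_branch_table_shape(self, species_tree_11):
        table, _ = sim.simulate_family_counts(species_tree_11, 0.017, 5, seed=3)
        table = filter_families(table)
        res = GeneFamilyEvolution(table, species_tree_11).fit()
        res.family_tests(n_null=100, seed=0)
        bt = res.branch_table()
        # 20 branches per family (11 tips + 9 internal non-root nodes)
        assert len(bt) == 20 * table.n_families
        assert set(bt.columns) >= {"family_id", "parent_count", "child_count", "branch_p", "direction"}
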