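"""Reverse conservation analysis: masking, scores, windows, regions."""

import numpy as np
import pytest
from scipy.linalg import expm

from famevo import simulate as sim
from famevo.aamodel import AA_INDEX, aa_rate_matrix, discrete_gamma_rates
from famevo.alignments import Alignment, map_to_reference
from famevo.conservation import (
    ConservationProfile,
    ReverseConservation,
    call_divergent_regions,
    call_variable_regions,
    mask_gappy_columns,
    normalize_and_window,
    site_rates,
)
from famevo.trees import DatedSpeciesTree


class TestGapMask:
    def test_majority_gap_excluded_boundary_included(self):
        rows = ["A" * 3] * 4 + ["-AA", "-A-", "--A", "---", "--A", "---"]
        aln = Alignment([f"s{i}" for i in range(10)], rows)
        mask = mask_gappy_columns(aln, 0.5)
        # col1: 6/10 gaps -> out; col2: 3/10 -> in; col3: 5/10 -> in (not >0.5)
        assert mask.tolist() == [False, True, True]

    def test_gap_free_all_included(self):
        aln = Alignment(["a", "b"], ["MKV", "MKV"])
        assert mask_gappy_columns(aln).all()

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            mask_gappy_columns(Alignment([], []))


class TestSiteRates:
    def test_invariant_column_scores_lower(self, tree_6taxa_sub):
        rows = ["AAAAA", "AAAAC", "AAAAD", "AAAAE", "AAAAF", "AAAAG"]
        # column 1-4 invariant, column 5 maximally variable
        aln = Alignment(tree_6taxa_sub.tip_labels, rows)
        raw = site_rates(aln, tree_6taxa_sub)
        assert raw[0] < raw[4]
        assert np.allclose(raw[:4], raw[0])

    def test_identical_sequences_flat_profile(self):
        # identical sequences carry no rate information: the data-driven
        # guide tree has zero-length branches, every column gets the prior
        # mean rate, and the profile degenerates (all scores 0, no regions)
        aln = Alignment([f"s{i}" for i in range(6)], ["MKVW"] * 6)
        profile = ReverseConservation(aln).fit()
        raw = profile.raw_s[profile.included]
        assert np.allclose(raw, raw[0])
        assert profile.degenerate
        assert np.all(profile.normalized[profile.included] == 0)
        assert profile.variable_regions() == []

    def test_three_taxon_posterior_mean_oracle(self):
        """Posterior mean rate equals direct summation over the closed-form
        3-taxon star likelihood, category by category."""
        tree = DatedSpeciesTree.from_newick("(a:0.3,b:0.2,c:0.4);")
        aln = Alignment(["a", "b", "c"], ["AK", "AR", "GK"])
        K, alpha = 6, 1.0
        raw = site_rates(aln, tree, alpha=alpha, n_rate_categories=K, freqs="uniform")
        Q, pi = aa_rate_matrix(None)
        rates = discrete_gamma_rates(alpha, K)
        lens = {t.label: t.length for t in tree.leaves}
        for col in range(2):
            states = [AA_INDEX[aln.matrix[i, col]] for i in range(3)]
            liks = []
            for r in rates:
                P = {lab: expm(Q * r * t) for lab, t in lens.items()}
                lik = sum(
                    pi[x]
                    * P["a"][x, states[0]]
                    * P["b"][x, states[1]]
                    * P["c"][x, states[2]]
                    for x in range(20)
                )
                liks.append(lik)
            liks = np.array(liks)
            expected = float((rates * liks).sum() / liks.sum())
            assert raw[col] == pytest.approx(expected, abs=1e-10)

    def test_mismatched_tree_rejected(self, tree_6taxa_sub):
        aln = Alignment(["x", "y"], ["MK", "MK"])
        with pytest.raises(ValueError, match="match"):
            site_rates(aln, tree_6taxa_sub)


class TestNormalizeAndWindow:
    def test_z_formula_population_sd(self):
        p = normalize_and_window(np.array([1.0, 2.0, 3.0]), np.ones(3, bool), window=7)
        assert np.allclose(p.normalized, [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert abs(p.normalized.mean()) <= 1e-9
        assert abs(p.normalized.std() - 1.0) <= 1e-9

    def test_constant_series_windows_constant(self):
        p = normalize_and_window(np.full(20, 5.0), np.ones(20, bool))
        assert p.degenerate
        assert np.all(p.w_mean == 0.0)

    def test_edge_window_shrinks_symmetrically(self):
        raw = np.arange(10, dtype=float)
        p = normalize_and_window(raw, np.ones(10, bool), window=7)
        z = p.normalized
        # at column 1 the window covers columns 1..4
        assert p.w_mean[0] == pytest.approx(z[:4].mean())
        # interior column covers +-3 neighbours
        assert p.w_mean[5] == pytest.approx(z[2:9].mean())

    def test_shift_invariance_of_normalization(self, rng):
        raw = rng.normal(size=50)
        mask = np.ones(50, bool)
        p1 = normalize_and_window(raw, mask)
        p2 = normalize_and_window(raw + 7.5, mask)
        assert np.allclose(p1.normalized, p2.normalized)
        assert np.allclose(p1.w_mean, p2.w_mean)

    def test_windows_skip_excluded_columns(self):
        raw = np.array([1.0, 2.0, 100.0, 3.0])
        mask = np.array([True, True, False, True])
        p = normalize_and_window(raw, mask, window=3)
        assert np.isnan(p.w_mean[2])
        # window over included columns only: col 4 averages cols 2 and 4
        assert p.w_mean[3] == pytest.approx(p.normalized[[1, 3]].mean())


class TestRegionCalling:
    def _profile(self, w, mask=None):
        n = len(w)
        mask = np.ones(n, bool) if mask is None else mask
        return ConservationProfile(
            raw_s=np.array(w, float),
            normalized=np.array(w, float),
            w_mean=np.array(w, float),
            included=mask,
        )

    def test_no_regions_below_threshold(self):
        assert call_variable_regions(self._profile([0.1, 0.2, 0.3])) == []

    def test_single_run(self):
        regions = call_variable_regions(self._profile([0.0, 0.8, 0.9, 0.0, 0.0, 0.0, 0.0]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (2, 3)
        assert regions[0].peak_w == pytest.approx(0.9)
        assert regions[0].label == "I"

    def test_merge_rule_small_gap(self):
        # two runs separated by 2 sub-threshold columns merge (min_gap 3)
        w = [0.8, 0.8, 0.1, 0.1, 0.9, 0.9]
        regions = call_variable_regions(self._profile(w))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 6)
        # but a 3-column gap keeps them separate
        w = [0.8, 0.8, 0.1, 0.1, 0.1, 0.9]
        regions = call_variable_regions(self._profile(w))
        assert [r.label for r in regions] == ["I", "II"]

    def test_planted_block_recovery(self, tree_11_sub):
        hits = 0
        for seed in range(10):
            aln, man = sim.simulate_region_alignment(
                tree_11_sub, 400, [(191, 210, 4.0)], seed=seed
            )
            prof = ReverseConservation(aln, tree=tree_11_sub).fit()
            plant = set(range(191, 211))
            best = 0.0
            for r in prof.variable_regions():
                got = set(range(r.start, r.end + 1))
                best = max(best, len(got & plant) / len(got | plant))
            hits += best >= 0.6
        assert hits >= 8

    def test_relabeling_invariance(self, tree_11_sub):
        aln, _ = sim.simulate_region_alignment(tree_11_sub, 120, [(51, 70, 4.0)], seed=4)
        prof1 = ReverseConservation(aln, tree=tree_11_sub).fit()
        # rename sequences consistently in alignment and tree
        renamed = Alignment(
            [f"x_{i}" for i in aln.ids], ["".join(r) for r in aln.matrix]
        )
        tree2 = DatedSpeciesTree.from_newick(tree_11_sub.to_newick())
        for tip in tree2.leaves:
            tip.label = f"x_{tip.label}"
        prof2 = ReverseConservation(renamed, tree=tree2).fit()
        r1 = [(r.start, r.end) for r in prof1.variable_regions()]
        r2 = [(r.start, r.end) for r in prof2.variable_regions()]
        assert r1 == r2


class TestDivergenceCalls:
    def _profile_with_ref(self, w, ref_map):
        n = len(w)
        return ConservationProfile(
            raw_s=np.array(w, float),
            normalized=np.array(w, float),
            w_mean=np.array(w, float),
            included=np.ones(n, bool),
            reference=ref_map,
        )

    def test_class_rules(self):
        aln = Alignment(["ref", "o"], ["MKVWMKVW", "MKVWMKVW"])
        ref = map_to_reference(aln, "ref")
        a = self._profile_with_ref([0.9, 0.9, 0.0, 0.0, 0.9, 0.9, 0.0, 0.0], ref)
        b = self._profile_with_ref([0.1, 0.1, 0.0, 0.0, 0.8, 0.8, 0.0, 0.0], ref)
        calls = call_divergent_regions(a, b, min_gap=1)
        cats = {(c.start, c.end): c.category for c in calls}
        assert cats[(1, 2)] == "divergent-in-A"
        assert cats[(5, 6)] == "variable-in-both"

    def test_divergent_in_b_symmetric(self):
        aln = Alignment(["ref", "o"], ["MKVW", "MKVW"])
        ref = map_to_reference(aln, "ref")
        a = self._profile_with_ref([0.1, 0.1, 0.0, 0.0], ref)
        b = self._profile_with_ref([0.9, 0.9, 0.0, 0.0], ref)
        calls = call_divergent_regions(a, b)
        assert calls[0].category == "divergent-in-B"

    def test_disjoint_coverage_rejected(self):
        a = self._profile_with_ref([0.9, 0.9], None)
        b = ConservationProfile(
            raw_s=np.array([0.9, 0.9]),
            normalized=np.array([0.9, 0.9]),
            w_mean=np.array([0.9, 0.9]),
            included=np.zeros(2, bool),
        )
        b.included = np.array([False, False])
        with pytest.raises(ValueError, match="reference"):
            call_divergent_regions(a, b)

    def test_simulated_divergence_recovery(self, tree_11_sub):
        alnA, _ = sim.simulate_region_alignment(tree_11_sub, 300, [(140, 160, 5.0)], seed=3)
        alnB, _ = sim.simulate_region_alignment(tree_11_sub, 300, [], seed=4)
        pA = ReverseConservation(alnA, tree=tree_11_sub, reference_id="CRO").fit()
        pB = ReverseConservation(alnB, tree=tree_11_sub, reference_id="CRO").fit()
        calls = call_divergent_regions(pA, pB)
        overlapping = [
            c for c in calls if c.start <= 160 and c.end >= 140 and c.category == "divergent-in-A"
        ]
        assert overlapping
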