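"""qPCR expression analysis: efficiencies, ddCt, ANOVA/LSD letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famevo import simulate as sim
from famevo.qpcr import (
    RelativeExpression,
    anova_lsd,
    ddct,
    exclude_replicates,
    primer_efficiency,
    read_ct_table,
)


def make_records(gene_cts: dict, ref_ct: float = 20.0, control="ctrl"):
    """Build a Ct frame: {treatment: [target Ct per bio rep]} for one gene."""
    rows = []
    for tr, cts in gene_cts.items():
        for rep, ct in enumerate(cts, start=1):
            for tech in (1, 2):
                rows.append(
                    {
                        "gene": "g1",
                        "treatment": tr,
                        "bio_rep": rep,
                        "tech_rep": tech,
                        "ct_target": ct,
                        "ct_reference": ref_ct,
                        "detectable": not np.isnan(ct),
                    }
                )
    return pd.DataFrame(rows)


class TestPrimerEfficiency:
    def test_perfect_doubling(self):
        pts = [(x, 30 - 3.321928 * x) for x in (0.0, 1.0, 2.0, 3.0)]
        out = primer_efficiency(pts)
        assert out["amplification_factor"] == pytest.approx(2.0, abs=1e-4)
        assert out["efficiency_percent"] == pytest.approx(100.0, abs=0.05)

    def test_slope_formula(self):
        pts = [(x, 30 - 3.6 * x) for x in (0, 1, 2)]
        out = primer_efficiency(pts)
        assert out["amplification_factor"] == pytest.approx(10 ** (1 / 3.6), abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            primer_efficiency([(0, 30), (1, 27)])

    def test_positive_slope_flagged(self):
        out = primer_efficiency([(0, 30), (1, 31), (2, 32)])
        assert not out["valid"]


class TestDdct:
    def test_textbook_example(self):
        rec = make_records({"ctrl": [24.0], "treat": [25.0]})
        out = ddct(rec, "g1", "ctrl")
        val = out.loc[out.treatment == "treat", "rel_expr"].iloc[0]
        assert val == pytest.approx(0.5)

    def test_treatment_equal_to_control_is_one(self):
        rec = make_records({"ctrl": [24.0, 24.0], "treat": [24.0, 24.0]})
        out = ddct(rec, "g1", "ctrl")
        assert np.allclose(out["rel_expr"], 1.0)

    def test_nd_propagates_never_zero(self):
        rec = make_records({"ctrl": [24.0], "treat": [np.nan]})
        out = ddct(rec, "g1", "ctrl")
        val = out.loc[out.treatment == "treat", "rel_expr"]
        assert val.isna().all()

    def test_recovery_with_noise(self):
        folds = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["ctrl", "ind"])
        recovered = []
        for seed in range(20):
            tab, _ = sim.simulate_ct_table(["g1"], ["ctrl", "ind"], folds, sigma=0.15, seed=seed)
            out = ddct(tab, "g1", "ctrl")
            grp = out[out.treatment == "ind"]
            recovered.append(2.0 ** -grp["ddct"].mean())
        assert 1.6 <= np.median(recovered) <= 2.5


class TestAnovaLsd:
    def test_identical_groups_single_letter(self):
        vals = {t: np.array([1.0, 1.0, 1.0]) for t in ("a1", "a2", "a3")}
        out = anova_lsd(vals)
        assert set(out["letters"].values()) == {"a"}

    def test_zero_variance_distinct_means_distinct_letters(self):
        out = anova_lsd({"hi": np.array([2.0, 2.0, 2.0]), "lo": np.array([1.0, 1.0, 1.0])})
        assert out["letters"]["hi"] != out["letters"]["lo"]
        assert out["letters"]["hi"] == "a"  # highest mean gets 'a'

    def test_toy_table_matches_hand_computed_lsd(self):
        """3 treatments x 3 replicates against a by-hand pooled-MSE LSD."""
        vals = {
            "t1": np.array([1.0, 1.2, 0.8]),
            "t2": np.array([3.1, 2.9, 3.0]),
            "t3": np.array([1.1, 1.3, 0.9]),
        }
        out = anova_lsd(vals)
        groups = list(vals.values())
        sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
        mse = sse / 6  # 9 observations - 3 groups
        lsd = stats.t.ppf(0.975, 6) * np.sqrt(mse * (1 / 3 + 1 / 3))
        assert out["mse"] == pytest.approx(mse)
        # t2 differs from t1 and t3 by ~2 > LSD; t1 vs t3 differ by 0.1 < LSD
        assert abs(np.mean(vals["t2"]) - np.mean(vals["t1"])) > lsd
        assert abs(np.mean(vals["t1"]) - np.mean(vals["t3"])) < lsd
        assert out["letters"]["t2"] == "a"
        assert out["letters"]["t1"] == out["letters"]["t3"] == "b"

    def test_no_shared_letter_implies_real_difference(self, rng):
        for _ in range(10):
            vals = {
                f"t{k}": rng.normal(rng.uniform(0, 2), 0.3, size=5) for k in range(4)
            }
            out = anova_lsd(vals)
            letters = out["letters"]
            mse, tcrit = out["mse"], out["t_critical"]
            for a in vals:
                for b in vals:
                    if a < b and not (set(letters[a]) & set(letters[b])):
                        lsd = tcrit * np.sqrt(mse * (1 / 5 + 1 / 5))
                        assert abs(vals[a].mean() - vals[b].mean()) > lsd

    def test_single_group_skipped(self):
        out = anova_lsd({"only": np.array([1.0, 2.0, 3.0])})
        assert out["skipped"]


class TestExclusions:
    def test_named_exclusion(self):
        rec = make_records({"ctrl": [24.0] * 5, "treat": [25.0] * 5})
        out = exclude_replicates(rec, [(None, "treat", 3)])
        assert out[(out.treatment == "treat")]["bio_rep"].nunique() == 4

    def test_empty_list_identity(self):
        rec = make_records({"ctrl": [24.0]})
        assert exclude_replicates(rec, []).equals(rec)

    def test_unknown_replicate_errors(self):
        rec = make_records({"ctrl": [24.0]})
        with pytest.raises(ValueError, match="no records"):
            exclude_replicates(rec, [(None, "ctrl", 9)])

    def test_below_minimum_flagged(self):
        rec = make_records({"ctrl": [24.0] * 5, "treat": [23.0] * 5})
        res = RelativeExpression(
            rec, "ctrl", exclusions=[(None, "treat", r) for r in (1, 2, 3)]
        ).fit()
        row = res.table[(res.table.treatment == "treat")].iloc[0]
        assert row["status"] == "D"  # detectable but underpowered


class TestRelativeExpressionModel:
    def test_exact_recovery_sigma_zero(self):
        genes = ["prs1", "prs2"]
        trs = ["ctrl", "up", "down"]
        folds = pd.DataFrame([[1.0, 4.0, 0.25], [1.0, 1.0, 1.0]], index=genes, columns=trs)
        tab, _ = sim.simulate_ct_table(genes, trs, folds, sigma=0.0, seed=0)
        res = RelativeExpression(tab, "ctrl").fit()
        wide = res.table.pivot(index="treatment", columns="gene", values="rel_expr")
        assert wide.loc["ctrl", "prs1"] == pytest.approx(1.0)
        assert wide.loc["up", "prs1"] == pytest.approx(4.0)
        assert wide.loc["down", "prs1"] == pytest.approx(0.25)

    def test_control_mean_exactly_one_with_noise(self):
        folds = pd.DataFrame([[1.0, 3.0]], index=["g1"], columns=["ctrl", "t"])
        tab, _ = sim.simulate_ct_table(["g1"], ["ctrl", "t"], folds, sigma=0.3, seed=7)
        res = RelativeExpression(tab, "ctrl").fit()
        ctrl = res.table[(res.table.treatment == "ctrl")]["rel_expr"].iloc[0]
        assert ctrl == pytest.approx(1.0, abs=1e-12)

    def test_plate_offset_invariance(self):
        folds = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["ctrl", "t"])
        tab, _ = sim.simulate_ct_table(["g1"], ["ctrl", "t"], folds, sigma=0.1, seed=3)
        res1 = RelativeExpression(tab, "ctrl").fit()
        shifted = tab.copy()
        mask = shifted.bio_rep == 2
        shifted.loc[mask, ["ct_target", "ct_reference"]] += 4.0
        res2 = RelativeExpression(shifted, "ctrl").fit()
        assert np.allclose(
            res1.table["rel_expr"].to_numpy(), res2.table["rel_expr"].to_numpy()
        )

    def test_planted_pattern_significance(self):
        """4-fold up and 4-fold down at sigma=0.15, n=5 must both separate
        from the control in the letter display."""
        folds = pd.DataFrame(
            [[1.0, 4.0, 0.25]], index=["g1"], columns=["ctrl", "up", "down"]
        )
        hits = 0
        for seed in range(10):
            tab, _ = sim.simulate_ct_table(
                ["g1"], ["ctrl", "up", "down"], folds, sigma=0.15, n_bio_reps=5, seed=seed
            )
            res = RelativeExpression(tab, "ctrl").fit()
            letters = res.anova["g1"]["letters"]
            distinct = (
                not (set(letters["up"]) & set(letters["ctrl"]))
                and not (set(letters["down"]) & set(letters["ctrl"]))
            )
            hits += distinct
        assert hits >= 9

    def test_nd_cells_reported(self):
        folds = pd.DataFrame([[1.0, np.nan]], index=["g1"], columns=["ctrl", "t"])
        tab, _ = sim.simulate_ct_table(["g1"], ["ctrl", "t"], folds, sigma=0.0, seed=0)
        res = RelativeExpression(tab, "ctrl").fit()
        cell = res.expression_matrix().loc["t", "g1"]
        assert cell == "N/D"

    def test_read_ct_table_schema(self, tmp_path):
        folds = pd.DataFrame([[1.0]], index=["g1"], columns=["ctrl"])
        tab, _ = sim.simulate_ct_table(["g1"], ["ctrl"], folds, seed=0)
        p = tmp_path / "ct.tsv"
        tab.to_csv(p, sep="\t", index=False)
        assert len(read_ct_table(p)) == len(tab)
        bad = tmp_path / "bad.tsv"
        tab.drop(columns=["ct_reference"]).to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_ct_table(bad)
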