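import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import deltasync as ds
from deltasync.core_data import DesignError
from oracles import bh_stepup_brute, gg_epsilon_eigen, split_plot_anova_oracle


def random_table(rng, n_per_group=6, group_shift=0.0, posture_shift=0.0):
    rows = []
    for g, gname in enumerate(("expert", "novice")):
        for i in range(n_per_group):
            pid = f"{gname}{i:02d}"
            subj = rng.normal(0, 1.0)
            for posture in ("Sitting", "Standing"):
                for stim in ("Symbolic", "Geometric"):
                    val = (
                        subj
                        + rng.normal(0, 0.5)
                        + (group_shift if gname == "expert" else 0.0)
                        + (posture_shift if posture == "Standing" else 0.0)
                    )
                    rows.append((pid, gname, posture, stim, val))
    return pd.DataFrame(
        rows, columns=["participant", "group", "posture", "stimulus", "value"]
    )


class TestMixedRmAnova:
    def test_all_identical_values_give_zero_f(self):
        table = random_table(np.random.default_rng(0))
        table["value"] = 0.7
        res = ds.mixed_rm_anova(table)
        for r in res.values():
            assert r.F == 0.0
            assert r.p_gg == 1.0

    def test_pure_group_offset(self, rng):
        table = random_table(rng)
        # overwrite with exact cell structure: group offset only
        table["value"] = np.where(table.group == "expert", 1.0, 0.0)
        table["value"] += np.repeat(rng.normal(0, 0.1, 12), 4)  # subject noise
        res = ds.mixed_rm_anova(table)
        assert res["group"].F > 10
        for eff in ("posture", "stimulus", "posture:stimulus"):
            assert res[eff].F == pytest.approx(0.0, abs=1e-18)

    def test_matches_projection_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for rep in range(20):
            table = random_table(rng, group_shift=rng.normal(0, 0.5),
                                 posture_shift=rng.normal(0, 0.5))
            res = ds.mixed_rm_anova(table)
            ref = split_plot_anova_oracle(table)
            for eff, f_ref in ref.items():
                assert res[eff].F == pytest.approx(f_ref, abs=1e-8), eff

    def test_two_level_factors_have_epsilon_one(self, rng):
        res = ds.mixed_rm_anova(random_table(rng))
        for r in res.values():
            assert r.epsilon == 1.0

    def test_f_invariant_under_level_relabeling(self, rng):
        table = random_table(rng, group_shift=0.4)
        renamed = table.replace(
            {"posture": {"Sitting": "zz-sit", "Standing": "aa-stand"},
             "stimulus": {"Symbolic": "01", "Geometric": "99"}}
        )
        a = ds.mixed_rm_anova(table)
        b = ds.mixed_rm_anova(renamed)
        for eff in ("group", "posture", "stimulus", "group:posture"):
            assert a[eff].F == pytest.approx(b[eff].F, rel=1e-12)

    def test_group_stratum_equals_oneway_anova_on_subject_means(self, rng):
        table = random_table(rng, group_shift=0.3)
        res = ds.mixed_rm_anova(table)
        per = table.groupby(["participant", "group"]).value.mean().reset_index()
        f_ref, p_ref = stats.f_oneway(
            per.loc[per.group == "expert", "value"],
            per.loc[per.group == "novice", "value"],
        )
        assert res["group"].F == pytest.approx(f_ref, rel=1e-10)
        assert res["group"].p_gg == pytest.approx(p_ref, rel=1e-10)

    def test_within_effects_consistent_with_statsmodels_anovarm(self, rng):
        """Exact stratum identity against the pure-within AnovaRM fit.

        AnovaRM pools our participant-nested error with the group
        interaction stratum, so for each within effect W:
        F_AnovaRM(W) = F(W) * (N - 1) / ((N - a) + F(group:W)).
        """
        from statsmodels.stats.anova import AnovaRM

        table = random_table(rng, posture_shift=0.5)
        res = ds.mixed_rm_anova(table)
        ref = AnovaRM(table, "value", "participant",
                      within=["posture", "stimulus"]).fit().anova_table
        n = table.participant.nunique()
        a = table.group.nunique()
        for eff, ref_name in [("posture", "posture"),
                              ("stimulus", "stimulus"),
                              ("posture:stimulus", "posture:stimulus")]:
            expected = (res[eff].F * (n - 1)
                        / ((n - a) + res[f"group:{eff}"].F))
            assert ref.loc[ref_name, "F Value"] == pytest.approx(
                expected, rel=1e-9), eff

    def test_likert_ratings_reuse_the_same_machinery(self, rng):
        """Behavioural self-evaluation items: 4-point ratings treated as
        continuous run through the identical split-plot decomposition."""
        table = random_table(rng)
        table["value"] = rng.integers(1, 5, len(table)).astype(float)
        expert = (table.group == "expert")
        table.loc[expert, "value"] = np.minimum(
            table.loc[expert, "value"] + 1, 4.0)
        res = ds.mixed_rm_anova(table)
        ref = split_plot_anova_oracle(table)
        for eff, f_ref in ref.items():
            assert res[eff].F == pytest.approx(f_ref, abs=1e-8), eff
        assert res["group"].F > res["posture"].F

    def test_missing_cell_is_named(self, rng):
        table = random_table(rng)
        table = table[~((table.participant == "expert00")
                        & (table.posture == "Standing")
                        & (table.stimulus == "Geometric"))]
        with pytest.raises(DesignError, match="expert00"):
            ds.mixed_rm_anova(table)

    def test_single_group_rejected(self, rng):
        table = random_table(rng)
        with pytest.raises(DesignError):
            ds.mixed_rm_anova(table[table.group == "expert"])


class TestGgEpsilon:
    def test_two_level_factor_is_one(self):
        cov = np.array([[1.0, 0.3], [0.3, 2.0]])
        assert ds.gg_epsilon(cov) == 1.0

    def test_compound_symmetry_is_spherical(self):
        cov = 0.5 * np.eye(3) + 0.4 * np.ones((3, 3))
        assert ds.gg_epsilon(cov) == pytest.approx(1.0)

    def test_nonspherical_matches_eigen_oracle(self):
        cov = np.array([[2.0, 0.8, 0.1],
                        [0.8, 1.0, 0.3],
                        [0.1, 0.3, 0.5]])
        c = linalg.helmert(3).T
        assert ds.gg_epsilon(cov) == pytest.approx(
            gg_epsilon_eigen(cov, c), abs=1e-12)
        assert ds.gg_epsilon(cov) < 1.0

    def test_lower_bound_clip(self):
        cov = np.diag([1.0, 1e-12, 1e-12, 1e-12])
        assert ds.gg_epsilon(cov) >= 1.0 / 3


class TestBonferroni:
    def test_two_levels_unadjusted(self, rng):
        table = random_table(rng, group_shift=1.0)
        comps = ds.bonferroni_comparisons(table, "group")
        assert len(comps) == 1
        assert comps[0].p_bonferroni == pytest.approx(comps[0].p)
        assert comps[0].direction == "expert > novice"

    def test_three_levels_factor_three(self, rng):
        rows = []
        for i in range(8):
            for lvl in ("a", "b", "c"):
                rows.append((f"s{i}", "g", lvl, rng.normal()))
        table = pd.DataFrame(rows, columns=["participant", "group", "cond",
                                            "value"])
        comps = ds.bonferroni_comparisons(table, "cond")
        assert len(comps) == 3
        for c in comps:
            assert c.p_bonferroni == pytest.approx(min(1.0, 3 * c.p))

    def test_direction_matches_cell_means(self, rng):
        table = random_table(rng)
        table["value"] = np.where(table.posture == "Standing", 2.0, 1.0)
        table["value"] += rng.normal(0, 0.01, len(table))
        comps = ds.bonferroni_comparisons(table, "posture")
        assert comps[0].direction == "Standing > Sitting"


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert ds.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_step_up_hand_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(ds.bh_fdr(p), [0.04] * 4)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(ds.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_matches_brute_step_up_and_is_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(2, 80)))
            adj = ds.bh_fdr(p)
            np.testing.assert_allclose(adj, bh_stepup_brute(list(p)),
                                       atol=1e-12)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ds.bh_fdr([0.5, 1.2])


class TestReporting:
    @staticmethod
    def pair_design(rng, n_pairs=4, n_per_group=8, shift_pairs=()):
        rows = []
        pairs = [(f"A{i}", f"B{i}") for i in range(n_pairs)]
        for gname in ("expert", "novice"):
            for i in range(n_per_group):
                pid = f"{gname}{i:02d}"
                for pi, (pa, pb) in enumerate(pairs):
                    subj = rng.normal(0, 0.05)
                    for posture in ("Sitting", "Standing"):
                        for stim in ("Symbolic", "Geometric"):
                            val = 0.4 + subj + rng.normal(0, 0.02)
                            if pi in shift_pairs and gname == "expert":
                                val += 0.2
                            rows.append((pid, gname, posture, stim, pa, pb,
                                         val))
        return pd.DataFrame(rows, columns=[
            "participant", "group", "posture", "stimulus", "pair_a",
            "pair_b", "psv"])

    def test_anova_by_pair_matches_per_pair_calls(self, rng):
        design = self.pair_design(rng, shift_pairs=(1,))
        batch = ds.anova_by_pair(design)
        for (pa, pb), sub in design.groupby(["pair_a", "pair_b"]):
            single = ds.mixed_rm_anova(sub, value="psv")
            for eff, r in single.items():
                row = batch[(batch.pair_a == pa) & (batch.pair_b == pb)
                            & (batch.effect == eff)].iloc[0]
                assert row.F == pytest.approx(r.F, rel=1e-10, abs=1e-12)
                assert row.p_gg == pytest.approx(r.p_gg, rel=1e-10, abs=1e-12)

    def test_fdr_adjusts_within_effect_across_pairs(self, rng):
        design = self.pair_design(rng)
        batch = ds.anova_by_pair(design)
        for eff, sub in batch.groupby("effect"):
            np.testing.assert_allclose(
                sub.p_fdr.to_numpy(),
                bh_stepup_brute(sub.p_gg.tolist()),
                atol=1e-12,
            )

    def test_report_flags_only_shifted_pair(self, rng):
        design = self.pair_design(rng, shift_pairs=(2,))
        batch = ds.anova_by_pair(design)
        report = ds.significance_report(batch, design)
        group_rows = report[report.effect == "group"]
        assert "A2-B2" in set(group_rows.pair)
        assert group_rows.loc[group_rows.pair == "A2-B2",
                              "comparison"].iloc[0] == "expert > novice"

    def test_alpha_one_lists_everything(self, rng):
        design = self.pair_design(rng)
        batch = ds.anova_by_pair(design)
        report = ds.significance_report(batch, design, alpha=1.0)
        assert len(report) == 2 * len(set(zip(design.pair_a, design.pair_b)))

    def test_null_design_reports_nothing_or_little(self, rng):
        design = self.pair_design(rng)  # no shift anywhere
        batch = ds.anova_by_pair(design)
        report = ds.significance_report(batch, design)
        assert len(report) <= 1

    def test_format_report_renders(self, rng):
        design = self.pair_design(rng, shift_pairs=(0,))
        batch = ds.anova_by_pair(design)
        txt = ds.format_report(ds.significance_report(batch, design), "t")
        assert "t" in txt.splitlines()[0]
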