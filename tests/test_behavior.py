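"""Tracking capacity, ANOVA battery, Cronbach's alpha, BIC Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoload.behavior import (bf01_bic, bf01_condition_effect, cronbach_alpha,
                              outlier_sensitivity, proportion_correct,
                              rescale_capacity, rm_two_way_anova,
                              tracking_capacity, tracking_records)
from emoload.synth import generate_mot_behavior


class TestTrackingCapacity:
    @pytest.mark.parametrize("p,n,d,expected", [
        (0.0, 1, 4, -2.0), (1.0, 1, 4, 2.0),
        (0.0, 1, 8, -4.0), (1.0, 1, 8, 4.0),
        (0.75, 1, 4, 1.0), (0.5, 1, 4, 0.0),
    ])
    def test_capacity_values(self, p, n, d, expected):
        assert tracking_capacity(p, n, d) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m,d,expected", [
        (-2.0, 4, -1.0), (2.0, 4, 1.0), (-4.0, 8, -1.0), (4.0, 8, 1.0),
        (0.0, 4, 0.0), (0.0, 8, 0.0),
    ])
    def test_rescaling_endpoints(self, m, d, expected):
        assert rescale_capacity(m, d) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tracking_capacity(1.2, 1, 4)
        with pytest.raises(ValueError):
            rescale_capacity(3.0, 4)

    @given(p=st.floats(0.0, 1.0), d=st.sampled_from([4, 8]))
    @settings(deadline=None, max_examples=100)
    def test_forward_backward_round_trip(self, p, d):
        """Inverting the success model recovers m exactly; m' stays in [-1, 1]."""
        m = tracking_capacity(p, 1, d)
        p_back = (m / 1 + d / 2) / d  # forward success model at n = 1
        assert p_back == pytest.approx(p, abs=1e-12)
        assert -1.0 <= rescale_capacity(m, d) <= 1.0

    def test_proportion_correct(self):
        tab = pd.DataFrame({"correct": [1] * 30 + [0] * 10})
        assert proportion_correct(tab) == 0.75
        with pytest.raises(ValueError):
            proportion_correct(tab.iloc[:0])

    def test_records_aggregation(self):
        parts = [generate_mot_behavior(1.0, 4, seed=s, subject_id=f"S{s}")
                 for s in range(3)]
        rec = tracking_records(pd.concat(parts, ignore_index=True))
        assert len(rec) == 3
        assert np.allclose(rec["m"], 1 * (4 * rec["p"] - 2))
        assert np.allclose(rec["m_prime"], rec["m"] / 2)


def mixed_table(rng, n_per_group=8, effects=(0.0, 0.5, 0.0)):
    g_eff, c_eff, i_eff = effects
    rows = []
    for g, gname in enumerate(["low", "high"]):
        for s in range(n_per_group):
            base = rng.normal(g * g_eff, 1)
            for c, cname in enumerate(["c1", "c2", "c3"]):
                rows.append({
                    "subject_id": f"{gname}{s}", "group": gname, "cond": cname,
                    "value": base + c * c_eff + g * c * i_eff + rng.normal(0, 0.5)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_pingouin_mixed(self, rng):
        import pingouin as pg

        tab = mixed_table(rng, effects=(1.0, 0.5, 0.0))
        res = rm_two_way_anova(tab, "value", "subject_id", "cond",
                               between="group")
        ref = pg.mixed_anova(tab, dv="value", within="cond",
                             subject="subject_id", between="group")
        for ours, source in [("group", "group"), ("within", "cond"),
                             ("interaction", "Interaction")]:
            row = ref[ref["Source"] == source].iloc[0]
            assert res.effects[ours]["F"] == pytest.approx(row["F"], rel=1e-8)
            assert res.effects[ours]["p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_all_equal_values_zero_f(self):
        tab = mixed_table(np.random.default_rng(0))
        tab["value"] = 5.0
        res = rm_two_way_anova(tab, "value", "subject_id", "cond",
                               between="group")
        for eff in res.effects.values():
            assert eff["F"] == 0.0
            assert eff["ng2"] == 0.0

    def test_two_within_levels_sphericity_trivial(self, rng):
        tab = mixed_table(rng)
        tab = tab[tab["cond"] != "c3"]
        res = rm_two_way_anova(tab, "value", "subject_id", "cond",
                               between="group")
        assert res.gg_epsilon == 1.0
        assert res.mauchly_w == 1.0

    def test_gg_correction_reported_when_violated(self, rng):
        # strongly heterogeneous covariance across 4 levels
        n = 12
        base = rng.standard_normal((n, 1))
        wide = np.hstack([base + rng.normal(0, s, (n, 1))
                          for s in (0.05, 0.1, 2.0, 5.0)])
        rows = [{"subject_id": f"s{i}", "group": "g1" if i < 6 else "g2",
                 "cond": f"c{j}", "value": wide[i, j]}
                for i in range(n) for j in range(4)]
        res = rm_two_way_anova(pd.DataFrame(rows), "value", "subject_id",
                               "cond", between="group")
        assert res.mauchly_p < 0.05
        assert res.gg_epsilon < 1.0
        assert "p_gg" in res.effects["within"]

    def test_fully_within_two_way(self, rng):
        import pingouin as pg

        rows = []
        for s in range(9):
            for a in ("a1", "a2"):
                for b in ("b1", "b2", "b3"):
                    rows.append({"subj": f"s{s}", "A": a, "B": b,
                                 "y": rng.normal((a == "a2") * 0.8, 1)})
        tab = pd.DataFrame(rows)
        res = rm_two_way_anova(tab, "y", "subj", "A", factor_b="B")
        ref = pg.rm_anova(tab, dv="y", within=["A", "B"], subject="subj")
        for ours, source in [("A", "A"), ("B", "B"), ("AxB", "A * B")]:
            row = ref[ref["Source"] == source].iloc[0]
            assert res.effects[ours]["F"] == pytest.approx(row["F"], rel=1e-8)

    def test_eta_squared_in_range(self, rng):
        res = rm_two_way_anova(mixed_table(rng, effects=(2.0, 1.0, 0.5)),
                               "value", "subject_id", "cond", between="group")
        for eff in res.effects.values():
            assert 0.0 <= eff["ng2"] <= 1.0

    def test_missing_cells_rejected(self, rng):
        tab = mixed_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            rm_two_way_anova(tab, "value", "subject_id", "cond", between="group")

    def test_tukey_flags_strong_contrast(self, rng):
        res = rm_two_way_anova(mixed_table(rng, effects=(0.0, 2.0, 0.0)),
                               "value", "subject_id", "cond", between="group")
        within = res.tukey[res.tukey["type"] == "within"]
        c1c3 = within[within["contrast"] == "c1 - c3"].iloc[0]
        assert c1c3["p"] < 0.01


class TestOutlierSensitivity:
    def test_clean_table_unchanged(self, rng):
        # evenly spaced values per cell: fence = [Q1 - 0.75, Q3 + 0.75]
        # covers the whole [0, 1] range, so nothing can be flagged
        tab = mixed_table(rng)
        for _, idx in tab.groupby(["cond", "group"]).groups.items():
            tab.loc[idx, "value"] = np.linspace(0.0, 1.0, len(idx))
        out = outlier_sensitivity(tab, "value", "subject_id", "cond",
                                  between="group")
        assert out["flagged_rows"] == []
        assert out["robust"]

    def test_extreme_value_flagged(self, rng):
        tab = mixed_table(rng)
        tab.loc[0, "value"] = 100.0
        out = outlier_sensitivity(tab, "value", "subject_id", "cond",
                                  between="group")
        assert 0 in out["flagged_rows"]
        assert tab.loc[0, "subject_id"] in out["excluded_subjects"]

    def test_flag_count_matches_quantile_scan(self, rng):
        tab = mixed_table(rng)
        tab.loc[[3, 40], "value"] = [50.0, -50.0]
        out = outlier_sensitivity(tab, "value", "subject_id", "cond",
                                  between="group")
        expected = []
        for _, grp in tab.groupby(["cond", "group"]):
            q1, q3 = np.percentile(grp["value"], [25, 75])
            iqr = q3 - q1
            expected.extend(grp.index[(grp["value"] < q1 - 1.5 * iqr)
                                      | (grp["value"] > q3 + 1.5 * iqr)])
        assert sorted(out["flagged_rows"]) == sorted(expected)


class TestCronbach:
    def test_identical_items_alpha_one(self, rng):
        col = rng.standard_normal((30, 1))
        assert cronbach_alpha(np.tile(col, (1, 6))) == pytest.approx(1.0)

    def test_parallel_items_closed_form(self, rng):
        # k parallel items with intercorrelation rho: alpha = k rho / (1 + (k-1) rho)
        k, rho, n = 10, 0.3, 10_000
        common = rng.standard_normal((n, 1)) * np.sqrt(rho)
        items = common + rng.standard_normal((n, k)) * np.sqrt(1 - rho)
        expected = k * rho / (1 + (k - 1) * rho)
        assert cronbach_alpha(items) == pytest.approx(expected, abs=0.01)

    def test_independent_items_alpha_near_zero(self, rng):
        assert abs(cronbach_alpha(rng.standard_normal((5000, 8)))) < 0.05

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        items = rng.standard_normal((40, 5)) + rng.standard_normal((40, 1))
        ours = cronbach_alpha(items)
        ref = pg.cronbach_alpha(pd.DataFrame(items))[0]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestBayesFactor:
    def test_identical_models_ambiguous(self, rng):
        y = rng.standard_normal(30)
        x = np.ones((30, 1))
        res = bf01_bic(y, x, x)
        assert res.bf01 == pytest.approx(1.0)
        assert res.label == "ambiguous"

    def test_strong_effect_favors_alternative(self, rng):
        rows = []
        for s in range(30):
            base = rng.standard_normal()
            rows.append({"subj": s, "cond": "a", "y": base + rng.normal(0, 1)})
            rows.append({"subj": s, "cond": "b", "y": base + 1.5 + rng.normal(0, 1)})
        res = bf01_condition_effect(pd.DataFrame(rows), "y", "subj", "cond")
        assert res.bf01 < 1 / 3

    def test_null_simulation_median_above_one(self, rng):
        bfs = []
        for _ in range(200):
            rows = []
            for s in range(30):
                base = rng.standard_normal()
                for cond in ("a", "b"):
                    rows.append({"subj": s, "cond": cond,
                                 "y": base + rng.normal(0, 1)})
            bfs.append(bf01_condition_effect(pd.DataFrame(rows), "y", "subj",
                                             "cond").bf01)
        assert np.median(bfs) > 1.0

    def test_non_nested_rejected(self, rng):
        y = rng.standard_normal(20)
        x0 = rng.standard_normal((20, 2))
        x1 = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="nested"):
            bf01_bic(y, x0, x1)

    @pytest.mark.parametrize("bf,frag", [
        (5.0, "moderate evidence for the null"),
        (15.0, "strong evidence for the null"),
        (50.0, "very strong evidence for the null"),
        (0.2, "moderate evidence for the alternative"),
        (1.5, "anecdotal"),
    ])
    def test_band_labels(self, bf, frag):
        from emoload.behavior import BayesResult

        assert frag in BayesResult(bf).label
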