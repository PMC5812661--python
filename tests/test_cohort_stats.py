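"""Cohort statistics: summaries, percent changes, ANOVA, correlation, logit."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liverquant.cohort_stats import (
    group_summary,
    nagelkerke_r2,
    pearson_volume_correlation,
    percent_change,
    plf_logistic_regression,
    reproduce_abstract_changes,
    two_way_anova_bonferroni,
)
from liverquant.phantom import GROUP_TRAJECTORIES, CohortSpec, simulate_cohort


def _table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "group", "day", "parameter", "value", "units"])


class TestGroupSummary:
    def test_single_animal_sd_flagged_zero(self):
        t = _table([("a1", "SHAM", 0, "T1", 1000.0, "ms")])
        s = group_summary(t)
        assert s["n"].iloc[0] == 1 and s["sd"].iloc[0] == 0.0 and not s["sd_defined"].iloc[0]

    def test_sd_zero_cohort_reproduces_spec_means(self):
        table, _ = simulate_cohort(CohortSpec(sd_scale=0.0, seed=0))
        s = group_summary(table)
        cell = s[(s["group"] == "ePH") & (s["day"] == 0) & (s["parameter"] == "T1")]
        assert cell["mean"].iloc[0] == pytest.approx(972.6)
        assert cell["sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_censored_cells_absent(self):
        table, _ = simulate_cohort(CohortSpec(seed=0))
        s = group_summary(table)
        assert s[(s["group"] == "PLF") & (s["day"] == 5)].empty


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,value,direction,expected",
        [
            (997.0, 1180.0, "increase", 18),
            (972.6, 1359.7, "increase", 40),
            (68.5, 61.1, "decrease", 11),
            (5.0, 5.0, "increase", 0),
            (5.0, 5.0, "decrease", 0),
        ],
    )
    def test_examples(self, baseline, value, direction, expected):
        assert percent_change(baseline, value, direction) == expected

    def test_half_up_rounding(self):
        assert percent_change(200.0, 201.0, "increase") == 1  # 0.5% rounds up
        assert percent_change(200.0, 199.0, "decrease") == 1

    @settings(deadline=None, max_examples=100)
    @given(baseline=st.floats(1.0, 1e4), value=st.floats(0.0, 1e4))
    def test_antisymmetry_before_rounding(self, baseline, value):
        pct = 100.0 * (value - baseline) / baseline
        inc, dec = percent_change(baseline, value, "increase"), percent_change(baseline, value, "decrease")
        assert inc == math.floor(pct + 0.5) and dec == math.floor(-pct + 0.5)

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


class TestAnova:
    @staticmethod
    def _two_group_table(rng, offset_day=None, offset=0.0, n=8, sd=1.0, days=(0, 1, 2, 3, 5, 7)):
        rows = []
        for grp in ("A", "B"):
            for i in range(n):
                for d in days:
                    v = rng.normal(0.0, sd)
                    if grp == "B" and d == offset_day:
                        v += offset
                    rows.append((f"{grp}{i}", grp, d, "T1", v, "ms"))
        return _table(rows)

    def test_identical_groups_all_adjusted_p_one(self, rng):
        t = self._two_group_table(rng)
        dup = t.copy()
        dup["group"] = dup["group"].map({"A": "C", "B": "D"})
        dup["value"] = t["value"].values  # C/D duplicate A/B exactly
        merged = pd.concat([t, dup], ignore_index=True)
        res = two_way_anova_bonferroni(merged, "T1")
        pair = [r for r in res if r.test == "bonferroni_pairwise" and
                {"A", "C"} <= set(r.label.split(" @ ")[0].split(" vs "))]
        assert pair and all(r.p_adjusted == pytest.approx(1.0) for r in pair)

    def test_adjusted_p_bounds(self, rng):
        res = two_way_anova_bonferroni(self._two_group_table(rng, offset_day=3, offset=1.0), "T1")
        for r in res:
            if r.p_adjusted is not None and np.isfinite(r.p_raw):
                assert r.p_adjusted >= r.p_raw - 1e-15
                assert r.p_adjusted <= 1.0

    def test_power_three_sd_offset(self):
        """A 3-SD group offset at one day (n=8/group) survives Bonferroni in
        >=95% of 200 seeded replicates."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = self._two_group_table(rng, offset_day=3, offset=3.0)
            res = two_way_anova_bonferroni(t, "T1")
            p = [r.p_adjusted for r in res if r.label == "A vs B @ day 3"]
            hits += p[0] < 0.05
        assert hits >= 0.95 * 200

    def test_censored_unbalanced_cohort_runs(self):
        table, _ = simulate_cohort(CohortSpec(seed=3))
        res = two_way_anova_bonferroni(table, "T1")
        omnibus = [r for r in res if r.test == "anova"]
        assert len(omnibus) == 3
        assert all(np.isfinite(r.statistic) for r in omnibus)
        # PLF appears in day<=3 contrasts only
        plf_days = {r.label.split("day ")[1] for r in res if "PLF" in r.label}
        assert plf_days <= {"0", "1", "2", "3"}


class TestPearson:
    def test_perfect_negative(self):
        rows = [(f"a{i}", "G", d, "T1", 10.0 - d, "ms") for i, d in enumerate((0, 1, 2))]
        rows += [(f"a{i}", "G", d, "volume_pct", 50.0 + d, "%") for i, d in enumerate((0, 1, 2))]
        r = pearson_volume_correlation(_table(rows), "G", "T1")
        assert r.statistic == pytest.approx(-1.0)

    def test_three_point_oracle(self):
        """r for pairs (1,2),(2,4),(3,5) matches the covariance formula."""
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        oracle = sxy / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        rows = [(f"a{i}", "G", i, "T1", x[i], "ms") for i in range(3)]
        rows += [(f"a{i}", "G", i, "volume_pct", y[i], "%") for i in range(3)]
        r = pearson_volume_correlation(_table(rows), "G", "T1")
        assert r.statistic == pytest.approx(oracle, abs=1e-12)
        assert r.statistic == pytest.approx(0.9820, abs=1e-4)

    def test_affine_invariance_and_range(self):
        table, _ = simulate_cohort(CohortSpec(seed=5))
        r1 = pearson_volume_correlation(table, "ePH", "T1")
        scaled = table.copy()
        sel = scaled["parameter"] == "T1"
        scaled.loc[sel, "value"] = 3.0 * scaled.loc[sel, "value"] + 100.0
        r2 = pearson_volume_correlation(scaled, "ePH", "T1")
        assert -1.0 <= r1.statistic <= 1.0
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_generator_correlation_recovery(self):
        """The pooled T1-volume correlation of simulated ePH cohorts matches
        the population value implied by the group trajectories (mixture of
        per-day bivariate clouds with independent animal effects)."""
        t1 = GROUP_TRAJECTORIES["T1"]["ePH"]
        vol = GROUP_TRAJECTORIES["volume_pct"]["ePH"]
        days = [0, 1, 2, 3, 5, 7]
        mx = np.array([t1[d][0] for d in days]); sx = np.array([t1[d][1] for d in days])
        my = np.array([vol[d][0] for d in days]); sy = np.array([vol[d][1] for d in days])
        cov = np.mean((mx - mx.mean()) * (my - my.mean()))
        rho = cov / math.sqrt(
            (np.var(mx) + np.mean(sx**2)) * (np.var(my) + np.mean(sy**2))
        )
        rs = []
        for seed in range(20):
            table, _ = simulate_cohort(CohortSpec(seed=seed))
            rs.append(pearson_volume_correlation(table, "ePH", "T1").statistic)
        assert np.mean(rs) == pytest.approx(rho, abs=0.1)
        assert rho < -0.5  # strongly negative, as in the study

    def test_zero_variance_flagged(self):
        rows = [(f"a{i}", "G", i, "T1", 5.0, "ms") for i in range(4)]
        rows += [(f"a{i}", "G", i, "volume_pct", float(i), "%") for i in range(4)]
        r = pearson_volume_correlation(_table(rows), "G", "T1")
        assert math.isnan(r.statistic) and r.extras["flag"] == "zero variance"


class TestLogisticRegression:
    def test_intercept_only_r2_zero(self):
        assert nagelkerke_r2(-10.0, -10.0, 20) == 0.0

    def test_binary_predictor_likelihood_oracle(self):
        """Single binary predictor with counts (x=0: 8 alive, 2 dead),
        (x=1: 2 alive, 8 dead): for a saturated binary predictor the MLE cell
        probabilities are the observed frequencies, giving a closed-form
        likelihood and hence a closed-form Nagelkerke R2."""
        rows = []
        k = 0
        for x, n_alive, n_dead in ((0.0, 8, 2), (1.0, 2, 8)):
            for _ in range(n_alive):
                rows.append((f"e{k}", "ePH", 1, "T1", x, "ms")); k += 1
            for _ in range(n_dead):
                rows.append((f"p{k}", "PLF", 1, "T1", x, "ms")); k += 1
        res = plf_logistic_regression(_table(rows), day=1, predictors=("T1",))
        ll1 = 2 * (2 * math.log(0.2) + 8 * math.log(0.8))
        ll0 = 20 * math.log(0.5)
        oracle = (1 - math.exp(2 * (ll0 - ll1) / 20)) / (1 - math.exp(2 * ll0 / 20))
        assert res.extras["nagelkerke_r2"] == pytest.approx(oracle, abs=1e-8)

    def test_null_predictors_r2_near_zero(self, rng):
        rows = []
        for i in range(200):
            grp = "PLF" if i % 2 else "ePH"
            for p in ("T1", "T2", "ADC", "MTR"):
                rows.append((f"m{i}", grp, 1, p, rng.normal(), ""))
        res = plf_logistic_regression(_table(rows), day=1)
        assert res.extras["nagelkerke_r2"] == pytest.approx(0.0, abs=0.05)
        assert res.p_raw > 0.05

    def test_one_class_outcome_rejected(self):
        rows = [(f"e{i}", "ePH", 1, "T1", float(i), "ms") for i in range(5)]
        with pytest.raises(ValueError):
            plf_logistic_regression(_table(rows), day=1)

    def test_r2_bounds(self):
        table, _ = simulate_cohort(CohortSpec(seed=8))
        res = plf_logistic_regression(table, day=1)
        assert 0.0 <= res.extras["nagelkerke_r2"] <= 1.0


class TestAbstractChanges:
    def test_table_means_reproduce_printed_integers(self):
        table, _ = simulate_cohort(CohortSpec(sd_scale=0.0, seed=0))
        summary = group_summary(table)
        check = reproduce_abstract_changes(summary)
        assert len(check) == 9
        assert (check["status"] == "pass").all()
        got = {(r["parameter"], r["day"], r["group"]): r["computed"] for _, r in check.iterrows()}
        assert got[("T1", 1, "cPH")] == 18 and got[("T1", 1, "ePH")] == 40
        assert got[("T1", 2, "cPH")] == 24 and got[("T1", 2, "ePH")] == 49
        assert got[("T2", 5, "cPH")] == 21 and got[("T2", 5, "ePH")] == 41
        assert got[("ADC", 1, "cPH")] == 13
        assert got[("MTR", 1, "cPH")] == 11 and got[("MTR", 1, "ePH")] == 15

    def test_flat_summary_gives_zero_changes(self):
        table, _ = simulate_cohort(CohortSpec(sd_scale=0.0, seed=0))
        flat = table.copy()
        base = flat[flat["day"] == 0].set_index(["group", "parameter"])["value"]
        flat["value"] = [
            base.loc[(g, p)].iloc[0] if hasattr(base.loc[(g, p)], "iloc") else base.loc[(g, p)]
            for g, p in zip(flat["group"], flat["parameter"])
        ]
        check = reproduce_abstract_changes(group_summary(flat))
        assert (check["computed"] == 0).all()

    def test_missing_cell_reported_missing(self):
        table, _ = simulate_cohort(CohortSpec(sd_scale=0.0, seed=0))
        pruned = table[table["parameter"] != "T2"]
        check = reproduce_abstract_changes(group_summary(pruned))
        assert (check.loc[check["parameter"] == "T2", "status"] == "missing").all()
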