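import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from splitbrood.scaling import (
    ancova_scaling,
    log_transform,
    one_way_anova_tukey,
    scaling_battery,
)

ENVS = ("ripe", "unripe", "none")


def make_groups(rng, means, sizes, sd=1.0):
    values, groups = [], []
    for mu, n, lab in zip(means, sizes, ["ripe", "unripe", "none"]):
        values.append(mu + sd * rng.standard_normal(n))
        groups += [lab] * n
    return np.concatenate(values), np.array(groups)


class TestLogTransform:
    def test_elementary_values(self):
        np.testing.assert_allclose(log_transform([1.0, np.e]), [0.0, 1.0])

    def test_nonpositive_rejected_with_positions(self):
        with pytest.raises(ValueError, match="positions \\[1\\]"):
            log_transform([2.0, 0.0, 3.0])

    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_invertible(self, xs):
        out = log_transform(xs)
        np.testing.assert_allclose(np.exp(out), xs, rtol=1e-12)


class TestOneWayAnovaTukey:
    def test_identical_observations_all_one_letter(self):
        values = np.ones(30)
        groups = np.repeat(list(ENVS), 10)
        res = one_way_anova_tukey(values, groups)
        assert res.F == 0.0
        assert len(set(res.tukey_letters.values())) == 1

    def test_against_bruteforce_and_statsmodels(self, rng):
        """F and every pairwise Tukey decision match both a first-principles
        enumeration and statsmodels' Tukey HSD on an unbalanced dataset."""
        from oracles import tukey_pairwise_bruteforce

        values, groups = make_groups(rng, (10.0, 10.8, 12.5), (12, 19, 7))
        res = one_way_anova_tukey(values, groups)

        oracle = tukey_pairwise_bruteforce(values, groups)
        for row in res.tukey.itertuples(index=False):
            q, p, rej = oracle[(row.group1, row.group2)]
            assert row.q == pytest.approx(q, rel=1e-10)
            assert row.p == pytest.approx(p, rel=1e-6)
            assert row.reject == rej

        sm = pairwise_tukeyhsd(values, groups, alpha=0.05)
        sm_rej = dict(zip([tuple(r) for r in np.array(sm._results_table.data)[1:, :2]],
                          sm.reject))
        for row in res.tukey.itertuples(index=False):
            key = (row.group1, row.group2)
            key = key if key in sm_rej else (row.group2, row.group1)
            assert row.reject == sm_rej[key]

        # one-way F equals the regression-based F
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({"y": values, "g": groups})
        a = anova_lm(smf.ols("y ~ C(g)", data=df).fit(), typ=2)
        assert res.F == pytest.approx(float(a.loc["C(g)", "F"]), rel=1e-10)
        assert res.p == pytest.approx(float(a.loc["C(g)", "PR(>F)"]), rel=1e-8)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            one_way_anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            one_way_anova_tukey([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_letters_shift_invariant(self, rng):
        values, groups = make_groups(rng, (5.0, 5.2, 9.0), (15, 15, 15))
        r1 = one_way_anova_tukey(values, groups)
        r2 = one_way_anova_tukey(values + 1234.5, groups)
        assert r1.tukey_letters == r2.tukey_letters
        assert r1.F == pytest.approx(r2.F, rel=1e-9)

    def test_clear_separation_gets_distinct_letters(self, rng):
        values, groups = make_groups(rng, (0.0, 10.0, 20.0), (20, 20, 20), sd=1.0)
        res = one_way_anova_tukey(values, groups)
        letters = res.tukey_letters
        assert len({letters[e] for e in ("ripe", "unripe", "none")}) == 3


class TestAncova:
    def _data(self, rng, slopes, intercepts, n=40, sd=0.3):
        xs, ys, gs = [], [], []
        for sl, ic, lab in zip(slopes, intercepts, ENVS):
            x = rng.uniform(1.0, 3.0, n)
            xs.append(x)
            ys.append(ic + sl * x + sd * rng.standard_normal(n))
            gs += [lab] * n
        return np.concatenate(ys), np.concatenate(xs), np.array(gs)

    def test_identical_lines_drop_interaction_and_no_env_effect(self, rng):
        y, x, g = self._data(rng, (2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        res = ancova_scaling(y, x, g)
        assert not res.interaction_retained
        terms = res.terms.set_index("term")
        assert terms.loc["environment", "p"] > 0.01
        assert len(res.slopes) == 1

    def test_heterogeneous_slopes_retain_interaction(self, rng):
        y, x, g = self._data(rng, (1.0, 2.5, 4.0), (1.0, 1.0, 1.0))
        res = ancova_scaling(y, x, g)
        assert res.interaction_retained
        assert res.interaction_p < 0.20
        slopes = res.slopes.set_index("environment")["slope"]
        assert slopes["ripe"] < slopes["unripe"] < slopes["none"]

    def test_common_slope_offsets_order_adjusted_means(self, rng):
        y, x, g = self._data(rng, (2.0, 2.0, 2.0), (3.0, 2.0, 1.0))
        res = ancova_scaling(y, x, g)
        assert not res.interaction_retained
        adj = res.adjusted_means.set_index("environment")["mean"]
        assert adj["ripe"] > adj["unripe"] > adj["none"]
        terms = res.terms.set_index("term")
        assert terms.loc["environment", "p"] < 1e-6
        assert res.tukey_on_adjusted["reject"].all()

    def test_screening_threshold_boundaries(self, rng):
        y, x, g = self._data(rng, (2.0, 2.1, 1.9), (1.0, 1.0, 1.0))
        always = ancova_scaling(y, x, g, screening_threshold=1.0)
        never = ancova_scaling(y, x, g, screening_threshold=0.0)
        assert always.interaction_retained
        assert not never.interaction_retained

    def test_collinear_covariate_rejected(self, rng):
        g = np.repeat(list(ENVS), 10)
        x = (g == "ripe").astype(float) * 1.0 + (g == "unripe") * 2.0 + (g == "none") * 3.0
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="constant within a group"):
            ancova_scaling(y, x, g)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="two groups"):
            ancova_scaling(rng.standard_normal(10), rng.uniform(1, 2, 10), ["ripe"] * 10)


class TestScalingBattery:
    def _table(self, rng, n=420):
        """Phenotypes whose environment effects mirror the study pattern:
        ripe > unripe > none for body and femur; ripe >> unripe ~ none for
        testis; allometric links between the three traits."""
        env = np.array(["ripe", "unripe", "none"])[rng.integers(3, size=n)]
        body_mu = {"ripe": 23.5, "unripe": 13.0, "none": 12.3}
        body = np.array([body_mu[e] for e in env]) * np.exp(0.08 * rng.standard_normal(n))
        femur_off = {"ripe": 1.0, "unripe": 1.05, "none": 0.82}
        femur = np.array([femur_off[e] for e in env]) * body ** 0.5 * np.exp(0.05 * rng.standard_normal(n))
        testis_off = {"ripe": 1.5, "unripe": 0.95, "none": 1.0}
        testis = 0.01 * np.array([testis_off[e] for e in env]) * body ** 0.9 \
            * np.exp(0.10 * rng.standard_normal(n))
        return pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "environment": env,
             "block": "d1", "body_mass_mg": body, "femur_area_mm2": femur,
             "testis_mass_mg": testis}
        )

    def test_study_pattern_recovered(self, rng):
        data = self._table(rng)
        rep = scaling_battery(data)
        # body ANOVA: ripe biggest and separated; unripe/none near each other
        letters = rep.anovas["body_mass_mg"].tukey_letters
        assert letters["ripe"] not in (letters["unripe"], letters["none"])
        means = rep.anovas["testis_mass_mg"].group_means
        assert means["ripe"] > max(means["unripe"], means["none"])
        assert set(rep.table.columns) == {"model", "term", "df", "F", "p"}
        assert (rep.table["F"] >= 0).all()
        # six models reported: 3 anovas + 3 ancovas
        assert rep.table["model"].nunique() == 6

    def test_single_environment_errors(self, rng):
        data = self._table(rng)
        with pytest.raises(ValueError, match="two groups"):
            scaling_battery(data[data["environment"] == "ripe"])

    def test_label_permutation_equivariance(self, rng):
        data = self._table(rng)
        rep1 = scaling_battery(data)
        perm = {"ripe": "unripe", "unripe": "none", "none": "ripe"}
        data2 = data.assign(environment=data["environment"].map(perm))
        rep2 = scaling_battery(data2)
        m1 = rep1.anovas["body_mass_mg"].group_means
        m2 = rep2.anovas["body_mass_mg"].group_means
        for old, new in perm.items():
            assert m1[old] == pytest.approx(m2[new])
        assert rep1.anovas["body_mass_mg"].F == pytest.approx(
            rep2.anovas["body_mass_mg"].F, rel=1e-10
        )

    def test_missing_trait_rows_dropped_per_analysis(self, rng):
        data = self._table(rng)
        data.loc[data.index[:30], "femur_area_mm2"] = np.nan
        rep = scaling_battery(data)
        assert rep.anovas["femur_area_mm2"].group_sizes.sum() == len(data) - 30
        assert rep.anovas["body_mass_mg"].group_sizes.sum() == len(data)
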