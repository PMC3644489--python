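"""Propensity derivation, stratification, weighting, matching, KM."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy.special import expit

import screenbias as sb
from screenbias.estimators import DesignSpec, fit_logistic, marginal_arr
from screenbias.propensity import (
    derive_propensity,
    greedy_match,
    iptw_arr,
    iptw_weights,
    km_cumulative,
    matched_arr,
    mcnemar_test,
    quintile_stratified_rates,
    standardized_difference,
)
from conftest import reference_greedy_match


def _ps_rows(n, seed, confounded=True):
    rng = np.random.default_rng(seed)
    age = rng.choice(["50-59", "60-69", "70-74"], n, p=[0.4, 0.35, 0.25])
    sex = rng.choice(["M", "F"], n)
    rows = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "pcp_id": rng.integers(0, max(n // 50, 2), n),
            "age_group": age,
            "sex": sex,
            "income_quintile": rng.integers(1, 6, n),
            "rural": rng.random(n) < 0.15,
            "comorbidity": rng.choice(
                ["not_hospitalized", "hosp_no_comorbidity", "comorbid"], n,
                p=[0.5, 0.35, 0.15],
            ),
        }
    )
    lp = -2.0
    if confounded:
        lp = lp + 1.2 * (age == "70-74") + 0.8 * (sex == "F")
    rows["exposed"] = rng.random(n) < expit(lp)
    p_out = expit(-3.5 + 0.9 * (age == "70-74") - 0.6 * rows["exposed"])
    rows["crc_incident"] = rng.random(n) < p_out
    rows["crc_death"] = rows["crc_incident"] & (rng.random(n) < 0.3)
    rows["instrument"] = 5.0 + rng.random(n)
    return rows


class TestDerivation:
    def test_scores_match_manual_prediction(self):
        rows = _ps_rows(2000, seed=1)
        prop = derive_propensity(rows)
        from screenbias.estimators import build_design_matrix

        X = build_design_matrix(prop.fit.design, rows).to_numpy()
        manual = 1 / (1 + np.exp(-(X @ prop.fit.params.to_numpy())))
        np.testing.assert_allclose(prop.scores, np.clip(manual, 1e-6, 1 - 1e-6), atol=1e-12)

    def test_uninformative_covariates_give_half_c_statistic(self):
        rows = _ps_rows(4000, seed=2, confounded=False)
        prop = derive_propensity(rows)
        assert abs(prop.fit.c_statistic - 0.5) < 0.03

    def test_informative_covariates_discriminate(self, restricted_propensity):
        assert restricted_propensity.fit.c_statistic > 0.65


class TestQuintiles:
    def test_constant_scores_split_into_equal_fifths(self):
        rows = _ps_rows(103, seed=3)
        table, _ = quintile_stratified_rates(rows, np.full(103, 0.3), "crc_incident")
        assert table["n"].max() - table["n"].min() <= 1
        assert table["n"].sum() == 103

    def test_hand_built_fixture_rates(self):
        # 20 rows, scores force quintiles of 4; events placed by hand
        rows = _ps_rows(20, seed=4)
        rows["exposed"] = [True, False] * 10
        rows["crc_incident"] = [False] * 20
        # quintile 1 = subjects 0-3: one exposed event of 2 exposed -> 50%
        rows.loc[0, "crc_incident"] = True
        # quintile 5 = subjects 16-19: one unexposed event of 2 -> 50%
        rows.loc[17, "crc_incident"] = True
        scores = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 4)
        table, est = quintile_stratified_rates(rows, scores, "crc_incident")
        assert table.loc[0, "rate_exposed_pct"] == 50.0
        assert table.loc[0, "rate_unexposed_pct"] == 0.0
        assert table.loc[4, "rate_unexposed_pct"] == 50.0
        # pooled: stratum ARRs (+50, 0, 0, 0, -50) equally weighted
        assert est.arr == pytest.approx(0.0)

    def test_single_arm_everywhere_rejected(self):
        rows = _ps_rows(50, seed=5)
        rows["exposed"] = True
        rows.loc[0, "exposed"] = False  # both classes exist overall
        rows.loc[0, "crc_incident"] = True
        scores = np.linspace(0.1, 0.9, 50)
        # stratum 1 holds the lone control; others one-armed but usable stratum exists
        table, est = quintile_stratified_rates(rows, scores, "crc_incident")
        assert est.extra["n_strata_used"] == 1


class TestIPTW:
    def test_weight_values(self):
        w = iptw_weights(np.array([0.5, 0.8]), np.array([True, False]))
        assert w == pytest.approx([2.0, 5.0])

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            iptw_weights(np.array([0.0, 0.5]), np.array([True, False]))

    def test_weighting_balances_covariates(self):
        """With the true PS, weighted covariate means equalize across arms."""
        rng = np.random.default_rng(6)
        n = 40000
        x = rng.standard_normal(n)
        ps = expit(-1.0 + 1.0 * x)
        e = rng.random(n) < ps
        w = iptw_weights(ps, e)
        m1 = np.average(x[e], weights=w[e])
        m0 = np.average(x[~e], weights=w[~e])
        assert abs(m1 - m0) < 0.05
        # pseudo-population: each arm sums to about n
        assert abs(w[e].sum() - n) / n < 0.1
        assert abs(w[~e].sum() - n) / n < 0.1

    def test_constant_weights_reduce_to_unweighted(self):
        rows = _ps_rows(3000, seed=7)
        scores = np.full(len(rows), 0.5)
        weighted = iptw_arr(rows, scores, "crc_incident")
        design = DesignSpec(outcome="crc_incident",
                            covariates=list(sb.cohort.COVARIATES))
        unweighted = marginal_arr(fit_logistic(design, rows), rows)
        assert weighted.arr == pytest.approx(unweighted.arr, abs=1e-8)

    def test_recovers_truth_under_measured_confounding(self):
        """IPTW corrects the confounded contrast the raw comparison misses."""
        arrs, naive, truths = [], [], []
        for rep in range(10):
            rows = _ps_rows(8000, seed=200 + rep, confounded=True)
            old = (rows["age_group"] == "70-74").to_numpy()
            p1 = expit(-3.5 + 0.9 * old - 0.6)
            p0 = expit(-3.5 + 0.9 * old)
            truths.append(100 * (p1.mean() - p0.mean()))
            prop = derive_propensity(rows)
            arrs.append(iptw_arr(rows, prop.scores, "crc_incident").arr)
            naive.append(sb.unadjusted_risk_difference(rows, "crc_incident").arr)
        bias = np.array(arrs) - np.array(truths)
        se = bias.std(ddof=1) / np.sqrt(len(bias))
        assert abs(bias.mean()) < 2 * se + 0.05
        naive_bias = np.array(naive) - np.array(truths)
        assert naive_bias.mean() > 3 * se  # confounding visibly biases the raw contrast


class TestGreedyMatch:
    def test_exact_match_at_five_digits(self):
        scores = np.array([0.30000, 0.30000, 0.9])
        exposed = np.array([True, False, False])
        m = greedy_match(scores, exposed, seed=0)
        assert len(m.pairs) == 1
        assert m.pairs.loc[0, "control_id"] == 1
        assert m.pairs.loc[0, "distance"] == 0.0
        assert m.pairs.loc[0, "digits"] == 5

    def test_pigeonhole_unmatched_count(self):
        scores = np.array([0.5] * 7 + [0.5] * 3)
        exposed = np.array([True] * 7 + [False] * 3)
        m = greedy_match(scores, exposed, seed=0)
        assert len(m.pairs) == 3
        assert m.n_unmatched_treated == 4

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_agrees_with_stepwise_reference_on_30_units(self, seed):
        rng = np.random.default_rng(42)
        scores = np.round(rng.random(30), 6)
        exposed = np.zeros(30, dtype=bool)
        exposed[rng.choice(30, 12, replace=False)] = True
        ids = np.arange(30)
        m = greedy_match(scores, exposed, seed=seed, ids=ids)
        ref_pairs, ref_unmatched = reference_greedy_match(scores, exposed, seed, ids)
        got = set(zip(m.pairs["treated_id"], m.pairs["control_id"]))
        assert got == set(ref_pairs)
        assert m.n_unmatched_treated == ref_unmatched

    def test_row_order_permutation_is_irrelevant(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        exposed = rng.random(200) < 0.3
        ids = np.arange(200)
        m1 = greedy_match(scores, exposed, seed=3, ids=ids)
        perm = rng.permutation(200)
        m2 = greedy_match(scores[perm], exposed[perm], seed=3, ids=ids[perm])
        key = lambda m: sorted(zip(m.pairs["treated_id"], m.pairs["control_id"]))
        assert key(m1) == key(m2)

    def test_no_subject_reused(self, restricted_matched):
        pairs = restricted_matched.pairs
        used = pd.concat([pairs["treated_id"], pairs["control_id"]])
        assert used.is_unique
        assert (pairs["distance"] >= 0).all()


class TestStandardizedDifference:
    def test_equal_proportions_zero(self):
        assert standardized_difference(0.3, 0.3) == 0.0
        assert standardized_difference(0.0, 0.0) == 0.0

    def test_published_female_row_value(self):
        assert round(standardized_difference(0.557, 0.541), 2) == 3.22

    def test_formula_oracle_large_imbalance(self):
        p1, p2 = 0.064, 0.513
        expected = 100 * abs(p1 - p2) / np.sqrt(
            (p1 * (1 - p1) + p2 * (1 - p2)) / 2
        )
        assert standardized_difference(p1, p2) == pytest.approx(expected, abs=1e-12)
        assert expected > 100  # the motivating comorbidity-style imbalance

    def test_symmetry(self):
        assert standardized_difference(0.2, 0.7) == standardized_difference(0.7, 0.2)


class TestMcNemar:
    def test_balanced_discordance_is_null(self):
        t = np.array([1] * 10 + [0] * 10 + [0] * 5, dtype=bool)
        c = np.array([0] * 10 + [1] * 10 + [0] * 5, dtype=bool)
        res = mcnemar_test(t, c)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("b,c,expected", [(10, 0, 10.0), (5, 15, 5.0)])
    def test_statistic_formula(self, b, c, expected):
        t = np.array([1] * b + [0] * c + [1] * 3, dtype=bool)
        ctrl = np.array([0] * b + [1] * c + [1] * 3, dtype=bool)
        res = mcnemar_test(t, ctrl)
        assert res.statistic == pytest.approx(expected)
        assert res.exact == (b + c < 25)

    def test_no_discordant_pairs_convention(self):
        t = np.array([1, 0, 1], dtype=bool)
        res = mcnemar_test(t, t.copy())
        assert res.p_value == 1.0


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_fraction(self):
        events = np.array([1, 1, 2, 5, np.nan, np.nan, np.nan, 3])
        censor = np.full(8, np.nan)
        curve = km_cumulative(events, censor, horizon=5)
        ecdf = [(np.nan_to_num(events, nan=99) <= y).mean() for y in range(1, 6)]
        np.testing.assert_allclose(curve["cum_incidence"], ecdf, atol=1e-12)

    def test_all_censored_at_year_one_flat_zero(self):
        curve = km_cumulative(np.full(6, np.nan), np.ones(6), horizon=4)
        assert (curve["cum_incidence"] == 0).all()

    def test_hand_computed_product_limit(self):
        # 10 subjects: events years 1,2,2,3; censorings at 1 and 2; rest to horizon
        events = np.array([1, 2, 2, np.nan, np.nan, 3, np.nan, np.nan, np.nan, np.nan])
        censor = np.array([np.nan, np.nan, np.nan, 2, 1, np.nan, np.nan, np.nan, np.nan, np.nan])
        curve = km_cumulative(events, censor, horizon=3)
        np.testing.assert_allclose(curve["cum_incidence"], [0.1, 0.325, 0.46], atol=1e-12)
        assert curve["n_at_risk"].tolist() == [10, 8, 5]

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(11)
        n = 400
        events = np.where(rng.random(n) < 0.3, rng.integers(1, 8, n), np.nan)
        censor = np.where(rng.random(n) < 0.4, rng.integers(1, 8, n), np.nan)
        horizon = 7
        curve = km_cumulative(events, censor, horizon)
        obs_censor = np.where(np.isnan(censor), horizon, np.minimum(censor, horizon))
        had_event = ~np.isnan(events) & (events <= obs_censor)
        time = np.where(had_event, events, obs_censor)
        kmf = KaplanMeierFitter().fit(time, had_event)
        for year in range(1, horizon + 1):
            ours = curve.loc[curve["year"] == year, "cum_incidence"].iloc[0]
            ref = 1 - float(kmf.survival_function_at_times(year).iloc[0])
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_curve_is_monotone_and_bounded(self, restricted_matched, default_registry):
        subj = default_registry.subjects.set_index("subject_id")
        members = subj.loc[restricted_matched.pairs["treated_id"].to_numpy()]
        ev = members["crc_dx_year"].to_numpy(dtype="float64", na_value=np.nan) - 5
        ev[ev <= 0] = np.nan
        other = members["other_death_year"].to_numpy(dtype="float64", na_value=np.nan) - 5
        curve = km_cumulative(ev, other, horizon=7)
        inc = curve["cum_incidence"].to_numpy()
        assert (np.diff(inc) >= -1e-12).all()
        assert ((inc >= 0) & (inc <= 1)).all()


class TestMatchedAnalysis:
    def test_identical_outcomes_give_zero_arr(self):
        rows = _ps_rows(40, seed=12)
        rows["crc_incident"] = False
        pairs = pd.DataFrame({"treated_id": range(0, 10), "control_id": range(10, 20),
                              "distance": 0.0, "digits": 5})
        m = sb.MatchedSample(pairs=pairs, n_unmatched_treated=0)
        est, _ = matched_arr(m, rows, "crc_incident")
        assert est.arr == 0.0

    def test_direct_counting_oracle(self):
        """10 pairs, 3 treated-only and 1 control-only events -> +20 pp."""
        rows = _ps_rows(40, seed=13)
        rows["crc_incident"] = False
        rows.loc[[0, 1, 2], "crc_incident"] = True       # treated events
        rows.loc[13, "crc_incident"] = True              # control event (discordant pair)
        pairs = pd.DataFrame({"treated_id": range(0, 10), "control_id": range(10, 20),
                              "distance": 0.0, "digits": 5})
        m = sb.MatchedSample(pairs=pairs, n_unmatched_treated=0)
        est, subgroups = matched_arr(m, rows, "crc_incident")
        assert est.p_exposed == pytest.approx(30.0)
        assert est.p_unexposed == pytest.approx(10.0)
        assert est.arr == pytest.approx(20.0)
        assert est.extra["mcnemar_statistic"] == pytest.approx((3 - 1) ** 2 / (3 + 1))
        assert not subgroups.empty
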