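"""Classification and ANOVA/LSD statistics tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import ivimtrack as iv
from ivimtrack.stats import StatConfig, lsd_test
from oracles import (
    oneway_f_bruteforce,
    oneway_f_from_summary,
    repeated_f_bruteforce,
    sd_two_pass,
    two_sided_t_pvalue_betainc,
)

ALL_STAGES = [iv.TNStage(t, n) for t in range(5) for n in range(3)]


class TestClassifyResponse:
    def test_pcr(self):
        label = iv.classify_response(iv.TNStage(3, 1), iv.TNStage(0, 0))
        assert label.klass == "pCR" and label.responder

    def test_stable_disease(self):
        label = iv.classify_response(iv.TNStage(3, 1), iv.TNStage(3, 1))
        assert label.klass == "no_response" and not label.responder

    def test_partial_via_n_only(self):
        label = iv.classify_response(iv.TNStage(3, 2), iv.TNStage(3, 1))
        assert label.klass == "partial_response" and label.responder

    def test_exhaustive_partition(self):
        """All 225 (c, yp) pairs: total, mutually exclusive, 15 pCR."""
        counts = {"pCR": 0, "partial_response": 0, "no_response": 0}
        for c, yp in itertools.product(ALL_STAGES, ALL_STAGES):
            label = iv.classify_response(c, yp)
            counts[label.klass] += 1
            # class and responder flag are mutually consistent
            assert label.responder == (label.klass in {"pCR", "partial_response"})
            if yp.T == 0 and yp.N == 0:
                assert label.klass == "pCR"
        assert sum(counts.values()) == 225
        assert counts["pCR"] == 15  # one per clinical baseline stage

    def test_missing_pathology_policies(self):
        label = iv.classify_response(iv.TNStage(3, 1), None)
        assert label.klass == "no_response" and label.missing_pathology
        with pytest.raises(ValueError):
            iv.classify_response(iv.TNStage(3, 1), None, missing_policy="error")

    def test_stage_range_validation(self):
        with pytest.raises(ValueError):
            iv.TNStage(5, 0)
        with pytest.raises(ValueError):
            iv.TNStage(2, 3)


class TestOnewayAnova:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(-1, 1), 1.0,
                                 size=int(rng.integers(3, 9))).tolist()
                      for _ in range(k)]
            res = iv.anova_oneway({str(i): g for i, g in enumerate(groups)})
            f_oracle, df_b, df_w = oneway_f_bruteforce(groups)
            assert res.F == pytest.approx(f_oracle, rel=1e-10)
            assert (res.df_between, res.df_error) == (df_b, df_w)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 1, 8),
                  rng.normal(1.0, 1, 12)]
        res = iv.anova_oneway({str(i): g for i, g in enumerate(groups)})
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_constant_distinct_groups_give_infinite_f(self):
        res = iv.anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert np.isinf(res.F) and res.p_value == 0.0

    def test_identical_groups_give_zero_f(self):
        res = iv.anova_oneway({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_summary_statistic_reconstruction(self):
        """Group means/SDs with equal n reconstruct the same F as raw data
        built to have exactly those moments."""
        ns, means, sds = [15, 15, 15], [0.87, 1.13, 1.28], [0.23, 0.26, 0.32]
        f_summary = oneway_f_from_summary(ns, means, sds)
        rng = np.random.default_rng(0)
        groups = {}
        for i, (n, m, s) in enumerate(zip(ns, means, sds)):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            groups[str(i)] = m + s * x
        res = iv.anova_oneway(groups)
        assert res.F == pytest.approx(f_summary, rel=1e-10)

    def test_two_groups_equal_pooled_t_squared(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(0.4, 1, 7)
        res = iv.anova_oneway({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t ** 2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            iv.anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestRepeatedAnova:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(20):
            m = rng.normal(size=(int(rng.integers(3, 9)),
                                 int(rng.integers(2, 5))))
            res = iv.anova_repeated(m)
            f_oracle, df_t, df_e = repeated_f_bruteforce(m.tolist())
            assert res.F == pytest.approx(f_oracle, rel=1e-10)
            assert (res.df_between, res.df_error) == (df_t, df_e)

    def test_matches_statsmodels_anovarm(self, rng):
        m = rng.normal(size=(8, 3))
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "time": np.tile(["a", "b", "c"], 8),
            "y": m.ravel(),
        })
        sm_res = AnovaRM(long, "y", "subject", within=["time"]).fit()
        res = iv.anova_repeated(m)
        assert res.F == pytest.approx(float(sm_res.anova_table["F Value"].iloc[0]),
                                      rel=1e-8)
        assert res.p_value == pytest.approx(
            float(sm_res.anova_table["Pr > F"].iloc[0]), rel=1e-8)

    def test_identical_columns_give_zero_f(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        res = iv.anova_repeated(np.column_stack([col, col, col]))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_additive_model_gives_infinite_f(self):
        subj = np.array([0.0, 1.0, 2.0, 5.0])[:, None]
        time = np.array([0.0, 0.3, 0.9])[None, :]
        res = iv.anova_repeated(subj + time)
        assert np.isinf(res.F) and res.p_value == 0.0

    def test_ss_partition(self, rng):
        m = rng.normal(size=(6, 3))
        res = iv.anova_repeated(m)
        grand = m.mean()
        ss_total = np.sum((m - grand) ** 2)
        ss_parts = (res.ms_between * res.df_between
                    + res.ms_error * res.df_error
                    + 3 * np.sum((m.mean(axis=1) - grand) ** 2))
        assert ss_parts == pytest.approx(ss_total, rel=1e-10)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            iv.anova_repeated(m)


class TestLsd:
    def test_null_case(self):
        res = lsd_test(1.0, 1.0, 5, 5, ms_error=0.2, df_error=8)
        assert res.T_stat == 0.0 and res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_linearity_in_mean_difference(self):
        r1 = lsd_test(0.0, 0.3, 6, 6, ms_error=0.5, df_error=10)
        r2 = lsd_test(0.0, 0.6, 6, 6, ms_error=0.5, df_error=10)
        assert r2.T_stat == pytest.approx(2 * r1.T_stat, rel=1e-12)

    def test_pvalue_matches_betainc_route(self, rng):
        for _ in range(20):
            ma, mb = rng.normal(size=2)
            mse = float(rng.uniform(0.05, 2.0))
            df = int(rng.integers(3, 40))
            res = lsd_test(ma, mb, int(rng.integers(2, 20)),
                           int(rng.integers(2, 20)), mse, df)
            assert res.p_value == pytest.approx(
                two_sided_t_pvalue_betainc(res.T_stat, df), abs=1e-8)

    def test_zero_variance_distinct_means(self):
        res = lsd_test(1.0, 2.0, 4, 4, ms_error=0.0, df_error=6)
        assert np.isinf(res.T_stat) and res.p_value == 0.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            lsd_test(1.0, 2.0, 0, 4, ms_error=0.1, df_error=6)


@given(a=st.floats(0.5, 3.0), c=st.floats(-2.0, 2.0))
def test_affine_invariance_of_f_and_t(a, c):
    """F and LSD T are unchanged by y -> a*y + c on all ADC values."""
    rng = np.random.default_rng(99)
    m = rng.normal(size=(6, 3))
    base = iv.anova_repeated(m)
    trans = iv.anova_repeated(a * m + c)
    assert trans.F == pytest.approx(base.F, rel=1e-9)
    r0 = lsd_test(m[:, 0].mean(), m[:, 1].mean(), 6, 6,
                  base.ms_error, base.df_error)
    r1 = lsd_test(a * m[:, 0].mean() + c, a * m[:, 1].mean() + c, 6, 6,
                  trans.ms_error, trans.df_error)
    assert r1.T_stat == pytest.approx(r0.T_stat, rel=1e-9)


@given(st.floats(0.1, 3.0), st.floats(0.2, 3.0))
def test_pvalues_monotone_in_effect_size(shift, extra):
    """Larger group separation (hence larger F / |T|) gives smaller p."""
    base = np.array([-1.0, 0.0, 1.0])
    groups_small = {"a": base, "b": base + shift}
    groups_large = {"a": base, "b": base + shift + extra}
    small = iv.anova_oneway(groups_small)
    large = iv.anova_oneway(groups_large)
    assert large.F > small.F
    assert large.p_value <= small.p_value
    r_small = lsd_test(0.0, shift, 3, 3, ms_error=1.0, df_error=4)
    r_large = lsd_test(0.0, shift + extra, 3, 3, ms_error=1.0, df_error=4)
    assert r_large.p_value <= r_small.p_value


class TestRunGroupAnalysis:
    @staticmethod
    def _adc_table(cohort):
        rows = []
        for rec in cohort:
            for tp, curve in rec.curves.items():
                rows.append({"patient_id": rec.patient_id, "timepoint": tp,
                             "adc": iv.fit_adc_monoexp(curve).adc / 1e-3})
        return pd.DataFrame(rows)

    def test_structure_and_summary_oracle(self, default_cohort):
        adc = self._adc_table(default_cohort)
        labels = {r.patient_id: r.group == "responder" for r in default_cohort}
        analysis = iv.run_group_analysis(adc, labels)
        assert set(analysis.anova) == {"responders", "nonresponders"}
        assert all(len(v) == 3 for v in analysis.lsd.values())
        # summary means/SDs equal an independent two-pass recomputation
        for _, row in analysis.summary.iterrows():
            want_group = "responder" if row["group"] == "responders" else "nonresponder"
            vals = [
                float(adc[(adc.patient_id == r.patient_id)
                          & (adc.timepoint == row["timepoint"])]["adc"].iloc[0])
                for r in default_cohort if r.group == want_group
            ]
            assert row["mean"] == pytest.approx(sum(vals) / len(vals), rel=1e-12)
            assert row["sd"] == pytest.approx(sd_two_pass(vals), rel=1e-9)

    def test_constant_adc_gives_global_null(self, small_cohort):
        adc = self._adc_table(small_cohort)
        adc["adc"] = 1.0
        labels = {r.patient_id: r.group == "responder" for r in small_cohort}
        analysis = iv.run_group_analysis(adc, labels)
        for res in analysis.anova.values():
            assert res.F == pytest.approx(0.0, abs=1e-12)
        for results in analysis.lsd.values():
            assert not any(r.significant for r in results)

    def test_single_patient_group_skipped_with_warning(self):
        recs = iv.generate_cohort(iv.CohortConfig(
            seed=2, n_responders=3, n_nonresponders=1, noise_model="none"))
        adc = self._adc_table(recs)
        labels = {r.patient_id: r.group == "responder" for r in recs}
        with pytest.warns(UserWarning, match="skipped"):
            analysis = iv.run_group_analysis(adc, labels)
        assert analysis.skipped_groups == ["nonresponders"]
        assert "nonresponders" not in analysis.anova

    def test_missing_timepoint_rejected(self, small_cohort):
        adc = self._adc_table(small_cohort)
        adc = adc[~((adc.patient_id == adc.patient_id.iloc[0])
                    & (adc.timepoint == "post"))]
        labels = {r.patient_id: r.group == "responder" for r in small_cohort}
        with pytest.raises(ValueError):
            iv.run_group_analysis(adc, labels)
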