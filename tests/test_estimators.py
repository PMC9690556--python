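"""Regression/PS estimators against independent oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import tmlebench as tb
from tmlebench.base import ModelSpec
from tmlebench.estimators import (MatchResult, PropensityFit, fit_logistic,
                                  fit_propensity, iptw_or, lr_or,
                                  match_nearest, ps_covariate_or,
                                  ps_matching_or,
                                  standardized_mean_differences)

from _oracles import greedy_match, iptw_two_stratum, irls_logistic, or_2x2
from conftest import toy_frame

TRUE_MOR = 1.660  # brute-force counterfactual oracle, 1e6 draws

# hand fixture: 8 subjects, two covariates
FRAME8 = pd.DataFrame({
    "x1": [0.5, -1.2, 0.3, 2.1, -0.7, 1.4, 0.0, -2.0],
    "x2": [1, 0, 1, 1, 0, 0, 1, 0],
    "y":  [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
    "delta": 1,
})

# 12-subject printed fixture with a treatment column
FRAME12 = pd.DataFrame({
    "z":  [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
    "w3": [31.0, 38.2, 35.5, 29.8, 41.0, 36.6, 33.1, 37.9, 30.5, 39.4,
           34.2, 32.8],
    "y":  [1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0],
    "delta": 1,
})


class TestFitLogistic:
    def test_matches_irls_oracle_on_hand_data(self):
        fit = fit_logistic(FRAME8, ModelSpec("outcome", ("x1", "x2")), "y")
        oracle = irls_logistic(FRAME8[["x1", "x2"]].to_numpy(),
                               FRAME8["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-6)

    def test_intercept_only_limit(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"x1": rng.normal(size=50_000),
                              "y": (rng.random(50_000) < 0.3).astype(float)})
        fit = fit_logistic(frame, ModelSpec("outcome", ("x1",)), "y")
        assert np.allclose(fit.fitted, frame["y"].mean(), atol=0.01)

    def test_treatment_model_uses_specified_covariates(self, cohort_5k):
        ps = fit_propensity(cohort_5k)
        assert list(ps.coefficients.index) == ["const", "w2", "w6"]
        np.testing.assert_allclose(ps.logit_ps,
                                   np.log(ps.ps / (1 - ps.ps)), atol=1e-10)

    def test_missing_values_rejected(self, cohort_5k_mnar20):
        with pytest.raises(ValueError):
            fit_logistic(cohort_5k_mnar20, ModelSpec("outcome", ("z", "w3")),
                         "y")

    def test_perfect_separation_names_covariate(self):
        frame = pd.DataFrame({"x1": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0],
                              "y": [0.0, 0, 0, 1, 1, 1], "delta": 1})
        with pytest.raises((ValueError, RuntimeError), match="x1|converge"):
            fit_logistic(frame, ModelSpec("outcome", ("x1",)), "y")


class TestLrOr:
    def test_equals_irls_oracle_exactly(self):
        res = lr_or(FRAME12, ModelSpec("outcome", ("z", "w3")))
        oracle = irls_logistic(FRAME12[["z", "w3"]].to_numpy(),
                               FRAME12["y"].to_numpy())
        assert res.or_hat == pytest.approx(np.exp(oracle[1]), abs=1e-8)

    def test_missing_treatment_rejected(self):
        with pytest.raises(ValueError):
            lr_or(FRAME12, ModelSpec("outcome", ("w3",)))

    def test_ci_brackets_point(self, cohort_5k_mnar20):
        res = tb.LogisticOR().fit(cohort_5k_mnar20).result_
        assert res.ci_low <= res.or_hat <= res.ci_high
        assert res.ci_high == pytest.approx(
            res.or_hat * np.exp(1.959963984540054 * res.se_log_or), rel=1e-9)


class TestPsCovariate:
    def test_constant_ps_degenerates_to_unadjusted(self):
        frame = toy_frame(30, 20, 20, 30)
        ps = PropensityFit(ps=np.full(100, 0.5), logit_ps=np.zeros(100),
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        res = ps_covariate_or(frame, ps, outcome_spec=None)
        base = lr_or(frame, ModelSpec("outcome", ("z",)))
        assert res.or_hat == pytest.approx(base.or_hat, abs=1e-8)

    def test_two_stratum_adjustment_matches_oracle(self):
        # two strata with different event rates; PS = known stratum share
        rng = np.random.default_rng(3)
        w = np.repeat([0, 1], 2000)
        z = rng.random(4000) < np.where(w == 1, 0.7, 0.3)
        py = 0.1 + 0.2 * w + 0.15 * z
        y = (rng.random(4000) < py).astype(float)
        frame = pd.DataFrame({"w": w, "z": z.astype(int), "y": y, "delta": 1})
        ps_val = np.where(w == 1, 0.7, 0.3)
        ps = PropensityFit(ps=ps_val, logit_ps=np.log(ps_val / (1 - ps_val)),
                           model=ModelSpec("treatment", ("w",)),
                           coefficients=pd.Series(dtype=float))
        res = ps_covariate_or(frame, ps, outcome_spec=None)
        oracle = irls_logistic(
            np.column_stack([z.astype(float), ps_val]), y)
        assert res.or_hat == pytest.approx(np.exp(oracle[1]), abs=1e-8)


class TestMatching:
    def test_identical_ps_all_matched_at_zero_distance(self):
        n = 12
        lp = np.zeros(n) + 0.3
        lp[0] += 1e-9  # avoid zero SD while keeping distances ~0
        z = np.array([1] * 4 + [0] * 8)
        ps = PropensityFit(ps=expit(lp), logit_ps=lp,
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        m = match_nearest(ps, z, caliper_sd_mult=10.0)
        assert m.n_matched == 4
        assert all(abs(lp[t] - lp[c]) <= 2e-9 for t, c in m.pairs)

    def test_greedy_enumeration_example(self):
        lp = np.array([0.0, 1.0, 5.0, 0.1, 1.1])
        z = np.array([1, 1, 1, 0, 0])
        ps = PropensityFit(ps=expit(lp), logit_ps=lp,
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        mult = 0.5 / lp.std(ddof=1)  # caliper width exactly 0.5
        m = match_nearest(ps, z, caliper_sd_mult=mult)
        assert m.caliper_width == pytest.approx(0.5)
        assert m.n_matched == 2
        assert set(m.pairs) == {(1, 4), (0, 3)}  # subject with logit 5 is out

    @pytest.mark.parametrize("seed", range(25))
    def test_postconditions_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 120)
        lp = rng.normal(size=n)
        z = (rng.random(n) < 0.4).astype(int)
        if z.sum() in (0, n):
            return
        ps = PropensityFit(ps=expit(lp), logit_ps=lp,
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        m = match_nearest(ps, z, caliper_sd_mult=0.15)
        used = [i for p in m.pairs for i in p]
        assert len(used) == len(set(used))  # no subject reused
        for t, c in m.pairs:
            assert z[t] == 1 and z[c] == 0
            assert abs(lp[t] - lp[c]) <= m.caliper_width + 1e-12
        oracle = greedy_match(lp, z, m.caliper_width)
        assert sorted(m.pairs) == sorted(oracle)

    def test_zero_sd_rejected(self):
        lp = np.zeros(6)
        ps = PropensityFit(ps=expit(lp), logit_ps=lp,
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            match_nearest(ps, np.array([1, 1, 1, 0, 0, 0]))

    def test_single_arm_rejected(self):
        lp = np.arange(5.0)
        ps = PropensityFit(ps=expit(lp), logit_ps=lp,
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            match_nearest(ps, np.ones(5))


class TestMatchedOr:
    def test_closed_form_2x2(self):
        frame = toy_frame(30, 20, 20, 30)
        pairs = tuple((i, 50 + i) for i in range(50))
        res = ps_matching_or(frame, MatchResult(pairs, 1.0, 50))
        assert res.or_hat == pytest.approx(or_2x2(30, 20, 20, 30), rel=1e-8)
        assert res.or_hat == pytest.approx(2.25, rel=1e-8)

    def test_identical_outcomes_give_unit_or(self):
        frame = toy_frame(25, 25, 25, 25)
        pairs = tuple((i, 50 + i) for i in range(50))
        res = ps_matching_or(frame, MatchResult(pairs, 1.0, 50))
        assert res.or_hat == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_cell_rejected(self):
        frame = toy_frame(50, 0, 20, 30)
        pairs = tuple((i, 50 + i) for i in range(50))
        with pytest.raises(ValueError):
            ps_matching_or(frame, MatchResult(pairs, 1.0, 50))


class TestIptw:
    def test_uniform_ps_equals_crude_or(self):
        frame = toy_frame(30, 20, 15, 35)
        ps = PropensityFit(ps=np.full(100, 0.5), logit_ps=np.zeros(100),
                           model=ModelSpec("treatment", ()),
                           coefficients=pd.Series(dtype=float))
        res = iptw_or(frame, ps)
        assert res.or_hat == pytest.approx(or_2x2(30, 20, 15, 35), rel=1e-9)

    def test_two_stratum_exact_cell_counts(self):
        # exact cell frequencies => Hajek weighting equals the closed form
        rows = []
        for w, z, n_cell, n_event in [(0, 1, 200, 60), (0, 0, 300, 60),
                                      (1, 1, 400, 200), (1, 0, 100, 25)]:
            for i in range(n_cell):
                rows.append({"w": w, "z": z, "y": float(i < n_event),
                             "delta": 1})
        frame = pd.DataFrame(rows)
        ps_val = np.where(frame["w"] == 1, 0.8, 0.4)
        ps = PropensityFit(ps=ps_val, logit_ps=np.log(ps_val / (1 - ps_val)),
                           model=ModelSpec("treatment", ("w",)),
                           coefficients=pd.Series(dtype=float))
        res = iptw_or(frame, ps)
        oracle = iptw_two_stratum(0.5, 0.4, 0.8, 0.2, 0.3, 0.25, 0.5)
        assert res.or_hat == pytest.approx(oracle, rel=1e-6)

    def test_true_ps_recovers_marginal_or(self):
        # Horvitz-Thompson consistency under the benchmark DAG
        true_spec = ModelSpec("treatment", ("w3", "w5", "w6"))
        ors = []
        for rep in range(100):
            frame = tb.generate_cohort(tb.DgpConfig(n=5000, seed=9000 + rep))
            ps = fit_propensity(frame, true_spec)
            ors.append(iptw_or(frame, ps).or_hat)
        ors = np.asarray(ors)
        tol = 3 * ors.std(ddof=1) / np.sqrt(len(ors))
        assert ors.mean() == pytest.approx(TRUE_MOR, abs=tol + 0.02)


class TestClassInterfaces:
    @pytest.mark.parametrize("cls", [tb.LogisticOR, tb.PSCovariateOR,
                                     tb.PSMatchingOR, tb.IPTWOR])
    def test_row_order_invariance(self, cls, cohort_5k_mnar20):
        a = cls().fit(cohort_5k_mnar20).or_
        shuffled = cohort_5k_mnar20.sample(frac=1.0, random_state=5)
        b = cls().fit(shuffled).or_
        assert b == pytest.approx(a, rel=1e-9)

    def test_get_params_roundtrip(self):
        est = tb.IPTWOR(truncation=(0.01, 0.99))
        assert tb.IPTWOR(**est.get_params()).truncation == (0.01, 0.99)

    def test_balance_after_matching_on_true_ps(self, cohort_5k):
        est = tb.PSMatchingOR(
            treatment_spec=ModelSpec("treatment", ("w3", "w5", "w6")),
            outcome_spec=None)
        est.fit(cohort_5k)
        rows = [i for p in est.match_.pairs for i in p]
        matched = cohort_5k.iloc[rows]
        smd = standardized_mean_differences(matched, tb.dgp.COVARIATES)
        assert (smd < 0.10).all()
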