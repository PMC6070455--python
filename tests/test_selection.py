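import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from fmisokin import models as M
from fmisokin import selection as S
from fmisokin.fitting import FitResult, fit_model
from fmisokin.selection import _exact_runs_cdf


class TestRunsTest:
    def test_alternating_signs_maximal_runs(self):
        res = S.runs_test(np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]))
        assert res.n_runs == 6
        assert res.method == "exact"
        # maximal runs for n1=n2=3: upper tail is P(R=6)=2/20
        pmf = _exact_runs_cdf(3, 3)
        assert pmf[6] == pytest.approx(2 / 20)

    def test_two_runs_lower_tail_probability(self):
        res = S.runs_test(np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0]))
        assert res.n_runs == 2
        # brute-force enumeration: P(R <= 2) = 2/20 for n1 = n2 = 3
        pmf = _exact_runs_cdf(3, 3)
        assert sum(p for r, p in pmf.items() if r <= 2) == pytest.approx(2 / 20)

    def test_exact_pmf_by_brute_force(self):
        # enumerate all C(6,3) arrangements and count runs directly
        from itertools import permutations

        arrangements = set(permutations([1, 1, 1, -1, -1, -1]))
        counts = {}
        for arr in arrangements:
            runs = 1 + sum(a != b for a, b in zip(arr, arr[1:]))
            counts[runs] = counts.get(runs, 0) + 1
        pmf = _exact_runs_cdf(3, 3)
        for r, c in counts.items():
            assert pmf[r] == pytest.approx(c / len(arrangements))

    def test_one_sign_degenerate_case_defined(self):
        res = S.runs_test(np.array([1.0, 2.0, 3.0]))
        assert res.n_runs == 1
        assert np.isfinite(res.p_value)

    def test_zero_residual_inherits_previous_sign(self):
        res = S.runs_test(np.array([1.0, 0.0, -1.0, -1.0]))
        assert (res.n_pos, res.n_neg) == (2, 2)
        assert res.n_runs == 2

    def test_exact_and_normal_agree_for_balanced_n(self):
        # mid-p exact vs plain normal within 0.02 for n_pos = n_neg >= 10
        for n1 in (10, 12, 15):
            pmf = _exact_runs_cdf(n1, n1)
            n = 2 * n1
            mu = 2 * n1 * n1 / n + 1
            sd = math.sqrt(2 * n1 * n1 * (2 * n1 * n1 - n) / (n**2 * (n - 1)))
            for r in pmf:
                pr = pmf[r]
                lo = sum(p for k, p in pmf.items() if k <= r)
                hi = sum(p for k, p in pmf.items() if k >= r)
                exact = min(1.0, max(0.0, 2 * min(lo - pr / 2, hi - pr / 2)))
                normal = min(1.0, 2 * norm.sf(abs((r - mu) / sd)))
                assert abs(exact - normal) <= 0.02

    def test_too_few_signed_residuals_rejected(self):
        with pytest.raises(ValueError):
            S.runs_test(np.array([0.5]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-5.0, 5.0, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
            min_size=2,
            max_size=60,
        )
    )
    def test_p_value_well_defined_for_any_residuals(self, residuals):
        res = S.runs_test(np.array(residuals))
        assert 0.0 <= res.p_value <= 1.0
        assert 1 <= res.n_runs <= res.n_pos + res.n_neg
        assert res.passed == (res.p_value >= 0.05)


class TestInformationCriteria:
    def test_halving_wss_lowers_scores(self):
        for fn in (S.aic, S.aicc, S.bic):
            assert fn(20.0, 40, 6) < fn(40.0, 40, 6)

    def test_worked_example(self):
        # T=40, k=6, wss=40: AIC = 40 ln(1) + 12 = 12; AICc adds 84/33
        assert S.aic(40.0, 40, 6) == pytest.approx(12.0)
        assert S.aicc(40.0, 40, 6) == pytest.approx(12.0 + 84.0 / 33.0)

    def test_aicc_approaches_aic_for_large_t(self):
        assert S.aicc(1e6, 10**6, 6) - S.aic(1e6, 10**6, 6) == pytest.approx(0.0, abs=1e-4)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            S.aicc(10.0, 7, 6)

    def test_free_parameter_counts(self):
        expected = {"2C3K": 4, "2C4K": 5, "3C5K": 6, "3C6K": 7, "4C7K": 8, "4C8K": 9}
        for name, k in expected.items():
            assert M.model_spec(name).n_free == k

    def _fake_fit(self, model_name, residuals, weights):
        spec = M.model_spec(model_name)
        params = M.KineticParameters.from_free(spec, [0.1] + [0.1] * spec.n_rates)
        residuals = np.asarray(residuals, float)
        weights = np.asarray(weights, float)
        return FitResult(
            model=spec,
            params=params,
            wss=float(np.sum(weights * residuals**2)),
            residuals=residuals,
            weights=weights,
            n_starts=1,
            n_converged=1,
            best_start_index=0,
            seed=0,
            bounds=(None, None),
            modeled=np.zeros_like(residuals),
        )

    def test_rescaling_preserves_model_ranking(self):
        # scaling activities by c scales weights by 1/c and residuals by c;
        # criterion differences between models are unchanged
        rng = np.random.default_rng(0)
        r1, r2 = rng.standard_normal(40), 0.5 * rng.standard_normal(40)
        w = rng.uniform(0.5, 2.0, 40)
        c = 7.3
        f1, f2 = self._fake_fit("2C3K", r1, w), self._fake_fit("3C5K", r2, w)
        g1 = self._fake_fit("2C3K", c * r1, w / c)
        g2 = self._fake_fit("3C5K", c * r2, w / c)
        d = S.information_criteria(f1)["aicc"] - S.information_criteria(f2)["aicc"]
        d_scaled = S.information_criteria(g1)["aicc"] - S.information_criteria(g2)["aicc"]
        assert d_scaled == pytest.approx(d, rel=1e-12)


class TestLooMsep:
    def test_noise_free_msep_tiny(self, input_fn, coarse_schedule):
        spec = M.model_spec("2C3K")
        truth = M.KineticParameters.from_free(spec, [0.1, 0.35, 0.25, 0.01])
        clean = M.model_tac(spec, truth, input_fn, coarse_schedule)
        full = fit_model(spec, clean, input_fn, n_starts=10, seed=0)
        msep, folds, preds = S.loo_msep(spec, clean, input_fn, full_fit=full, n_restarts=2, seed=0)
        assert msep < 1e-6 * clean.activity.max() ** 2
        assert folds <= len(coarse_schedule)
        assert msep >= 0


class TestRankModels:
    def _scores(self, model, aicc_vals):
        out = []
        for i, a in enumerate(aicc_vals):
            out.append(
                S.SelectionScores(
                    model=model,
                    runs=S.RunsTestResult(5, 5, 5, 0.5, True, "exact"),
                    aic=a,
                    aicc=a,
                    bic=a + 1,
                    msep=a / 10,
                    msep_folds=10,
                    T=40,
                    k=4,
                )
            )
        return out

    def test_single_model_wins_everything(self):
        table = S.rank_models({"2C3K": self._scores("2C3K", [3.0, 4.0])})
        assert table.loc["2C3K", "wins_aicc"] == 2
        assert table.loc["2C3K", "runs_passes"] == 2

    def test_totals_are_sums(self):
        vals = [3.0, 4.0, 10.0]
        table = S.rank_models(
            {"2C3K": self._scores("2C3K", vals), "3C5K": self._scores("3C5K", [1.0, 9.0, 12.0])}
        )
        assert table.loc["2C3K", "total_aicc"] == pytest.approx(sum(vals))
        assert table["wins_aicc"].sum() == 3

    def test_mismatched_tac_sets_rejected(self):
        with pytest.raises(ValueError):
            S.rank_models(
                {"2C3K": self._scores("2C3K", [1.0]), "3C5K": self._scores("3C5K", [1.0, 2.0])}
            )
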