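"""Screening, AICc machinery and the adaptive-quadrature mixed logit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from sagersf.fitting import (SeparationError, aicc, akaike_weights, all_subsets,
                             assign_available_groups, confidence_flags,
                             fit_all_subsets, fit_mixed_logit, mixed_logit_loglik,
                             odds_ratios, pearson_screen, standardized_fit)


def simulate_mixed(seed, n_groups=40, rows_per_group=60, beta=(-1.0, 1.5, -0.8),
                   sigma=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sigma)
        x1 = rng.normal(0, 1, rows_per_group)
        x2 = rng.normal(0, 1, rows_per_group)
        eta = beta[0] + beta[1] * x1 + beta[2] * x2 + b
        y = (rng.random(rows_per_group) < expit(eta)).astype(int)
        for i in range(rows_per_group):
            rows.append((f"g{g}", y[i], x1[i], x2[i]))
    return pd.DataFrame(rows, columns=["group", "response", "x1", "x2"])


def trapezoid_loglik(table, covariates, beta, sigma, n_grid=2001, span=8.0):
    """Independent dense-quadrature oracle for the marginal log-likelihood."""
    total = 0.0
    for _, grp in table.groupby("group"):
        X = np.column_stack([np.ones(len(grp))] +
                            [grp[c].to_numpy(float) for c in covariates])
        y = grp["response"].to_numpy(float)
        bs = np.linspace(-span * sigma, span * sigma, n_grid)
        eta = (X @ np.asarray(beta))[:, None] + bs[None, :]
        ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        dens = np.exp(ll) * np.exp(-bs ** 2 / (2 * sigma ** 2)) / (sigma * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(dens, bs))
    return total


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-10.0, 2, 100) == pytest.approx(24.0 + 12.0 / 97.0)

    def test_asymptotic_limit(self):
        assert aicc(-10.0, 3, 10 ** 9) == pytest.approx(26.0, abs=1e-6)

    @pytest.mark.parametrize("ll,k,n", [(-5.0, 1, 10), (-123.4, 4, 57), (0.0, 2, 8)])
    def test_closed_form_grid(self, ll, k, n):
        assert aicc(ll, k, n) == pytest.approx(-2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 5, 6)


class TestAkaikeWeights:
    def test_singleton(self):
        w, d = akaike_weights([12.3])
        assert w[0] == 1.0 and d[0] == 0.0

    def test_two_equal(self):
        w, _ = akaike_weights([100.0, 100.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_delta_024(self):
        w, d = akaike_weights([10.0, 12.0, 14.0])
        assert np.allclose(d, [0, 2, 4])
        assert np.allclose(w, [0.66525, 0.24472, 0.09003], atol=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=300), min_size=1, max_size=20))
    def test_weights_sum_to_one(self, aiccs):
        w, d = akaike_weights(aiccs)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.min() == 0.0 and (d >= 0).all()


class TestAllSubsets:
    @pytest.mark.parametrize("p,expected", [(0, 1), (3, 8), (7, 128)])
    def test_powerset_count(self, p, expected):
        specs = all_subsets([f"v{i}" for i in range(p)])
        assert len(specs) == expected
        assert () in specs  # intercept-only model

    def test_guard(self):
        with pytest.raises(ValueError, match="model"):
            all_subsets([f"v{i}" for i in range(13)])


class TestConfidenceSet:
    def test_first_model_suffices(self):
        sel, renorm = confidence_flags([0.96, 0.04])
        assert sel.tolist() == [True, False]
        assert renorm.tolist() == [1.0, 0.0]

    def test_cumulative_arithmetic(self):
        sel, renorm = confidence_flags([0.5, 0.3, 0.15, 0.05])
        assert sel.tolist() == [True, True, True, False]
        assert np.allclose(renorm[:3], [0.52631578, 0.31578947, 0.15789473], atol=1e-6)
        assert renorm.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [4, 10, 20])
    def test_uniform_weights(self, m):
        sel, _ = confidence_flags(np.full(m, 1.0 / m))
        assert sel.sum() == int(np.ceil(0.95 * m))


class TestPearsonScreen:
    def test_identical_columns(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rep = pearson_screen(tab, ["a", "b"], priority=["a", "b"])
        assert rep.retained == ["a"]
        assert rep.dropped[0][0] == "b" and rep.dropped[0][2] == pytest.approx(1.0)

    def test_toy_table_priority(self):
        # r(a,b) = 0.9949, r(a,c) = 0.2, r(b,c) = 0.2902
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6],
                            "b": [1.2, 1.9, 3.3, 3.8, 5.1, 5.9],
                            "c": [4.0, 1, 5, 2, 6, 3]})
        rep = pearson_screen(tab, ["a", "b", "c"], priority=["a", "b", "c"])
        assert rep.retained == ["a", "c"]
        assert rep.pairwise_r.loc["a", "b"] == pytest.approx(0.9949, abs=1e-4)

    def test_unreachable_threshold(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rep = pearson_screen(tab, ["a", "b"], threshold=1.01)
        assert rep.retained == ["a", "b"]

    def test_order_stable(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 50)
        tab = pd.DataFrame({"a": base, "b": base + rng.normal(0, 0.1, 50),
                            "c": rng.normal(0, 1, 50)})
        r1 = pearson_screen(tab[["a", "b", "c"]], ["a", "b", "c"], priority=["a", "b", "c"])
        r2 = pearson_screen(tab[["c", "b", "a"]], ["c", "b", "a"], priority=["a", "b", "c"])
        assert r1.retained == r2.retained

    def test_constant_column_dropped_with_warning(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [7.0, 7, 7, 7]})
        with pytest.warns(UserWarning, match="constant"):
            rep = pearson_screen(tab, ["a", "b"])
        assert rep.retained == ["a"]


class TestFitMixedLogit:
    def test_sigma_zero_reduces_to_plain_logistic(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        n = 600
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = (rng.random(n) < expit(-0.5 + 1.2 * x1 - 0.7 * x2)).astype(int)
        tab = pd.DataFrame({"response": y, "x1": x1, "x2": x2,
                            "group": [f"g{i}" for i in rng.integers(0, 12, n)]})
        fit = fit_mixed_logit(tab, ["x1", "x2"])
        fe = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
        assert np.abs(fit.beta.to_numpy() - fe.params).max() < 1e-3
        assert fit.sigma_b < 0.01

    def test_parameter_recovery(self):
        true_beta = np.array([-1.0, 1.5, -0.8])
        errs = []
        for seed in range(3):
            fit = fit_mixed_logit(simulate_mixed(seed), ["x1", "x2"])
            errs.append(np.abs(fit.beta.to_numpy() - true_beta))
        med = np.median(np.vstack(errs), axis=0)
        assert np.all(med <= 0.15 * np.abs(true_beta) + 0.1)

    def test_marginal_loglik_matches_dense_quadrature(self):
        tab = simulate_mixed(7, n_groups=3, rows_per_group=10)
        fit = fit_mixed_logit(tab, ["x1", "x2"])
        oracle = trapezoid_loglik(tab, ["x1", "x2"], fit.beta.to_numpy(), fit.sigma_b)
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("sigma", [0.3, 1.0])
    def test_loglik_oracle_at_arbitrary_parameters(self, sigma):
        tab = simulate_mixed(11, n_groups=5, rows_per_group=12)
        beta = [-0.4, 0.9, -1.1]
        got = mixed_logit_loglik(tab, ["x1", "x2"], beta, sigma)
        assert got == pytest.approx(trapezoid_loglik(tab, ["x1", "x2"], beta, sigma),
                                    abs=1e-4)

    def test_wald_interval_ordering(self):
        fit = fit_mixed_logit(simulate_mixed(1, n_groups=10, rows_per_group=30),
                              ["x1", "x2"])
        assert (fit.lci <= fit.beta).all() and (fit.beta <= fit.uci).all()
        assert fit.aicc >= -2 * fit.loglik + 2 * fit.k
        assert fit.sigma_b >= 0

    def test_complete_separation_raises(self):
        n = 80
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(int)
        tab = pd.DataFrame({"response": y, "x": x,
                            "group": ["a"] * (n // 2) + ["b"] * (n // 2)})
        with pytest.raises(SeparationError, match="x"):
            fit_mixed_logit(tab, ["x"])

    def test_noise_covariate_raises_loglik_but_not_aicc(self):
        wins = 0
        for seed in range(10):
            tab = simulate_mixed(100 + seed, n_groups=10, rows_per_group=30)
            rng = np.random.default_rng(seed)
            tab["noise"] = rng.normal(0, 1, len(tab))
            small = fit_mixed_logit(tab, ["x1", "x2"])
            big = fit_mixed_logit(tab, ["x1", "x2", "noise"])
            assert big.loglik >= small.loglik - 1e-6
            wins += int(big.aicc > small.aicc)
        assert wins >= 6  # AICc penalizes the useless parameter most of the time


class TestStandardizedFit:
    def test_scaling_relation_single_covariate(self):
        rng = np.random.default_rng(5)
        n = 800
        x = rng.normal(0, 2.0, n)  # SD 2
        y = (rng.random(n) < expit(0.3 + 0.8 * x)).astype(int)
        tab = pd.DataFrame({"response": y, "x": x,
                            "group": [f"g{i}" for i in rng.integers(0, 8, n)]})
        raw = fit_mixed_logit(tab, ["x"])
        std = standardized_fit(tab, ["x"])
        sd = tab["x"].std(ddof=0)
        assert std.beta["x"] == pytest.approx(sd * raw.beta["x"], abs=1e-4)

    def test_idempotent_on_standardized_inputs(self):
        tab = simulate_mixed(8, n_groups=10, rows_per_group=30)
        for c in ("x1", "x2"):
            tab[c] = (tab[c] - tab[c].mean()) / tab[c].std(ddof=0)
        raw = fit_mixed_logit(tab, ["x1", "x2"])
        std = standardized_fit(tab, ["x1", "x2"])
        assert np.allclose(raw.beta.to_numpy(), std.beta.to_numpy(), atol=1e-5)

    def test_internal_standardized_coefs_match_explicit_refit(self):
        tab = simulate_mixed(9, n_groups=12, rows_per_group=25)
        tab["x1"] = tab["x1"] * 3.0 + 5.0  # give it a nontrivial scale
        fit = fit_mixed_logit(tab, ["x1", "x2"])
        refit = standardized_fit(tab, ["x1", "x2"])
        assert np.allclose(fit.beta_std[["x1", "x2"]].to_numpy(),
                           refit.beta[["x1", "x2"]].to_numpy(), atol=1e-4)
        # importance ranking agrees
        assert (fit.beta_std[["x1", "x2"]].abs().idxmax()
                == refit.beta[["x1", "x2"]].abs().idxmax())


class TestOddsRatios:
    def test_null_effect(self):
        tab = simulate_mixed(2, n_groups=8, rows_per_group=25)
        fit = fit_mixed_logit(tab, ["x1"])
        orat = odds_ratios(fit)
        assert orat.loc["x1", "odds_ratio"] == pytest.approx(np.exp(fit.beta["x1"]))

    def test_exponentiates_bounds(self):
        fit = fit_mixed_logit(simulate_mixed(3, n_groups=8, rows_per_group=25), ["x1"])
        orat = odds_ratios(fit)
        assert orat.loc["x1", "or_lci"] <= orat.loc["x1", "odds_ratio"] \
            <= orat.loc["x1", "or_uci"]


class TestModelSet:
    def test_ranking_and_weights(self):
        tab = simulate_mixed(4, n_groups=10, rows_per_group=30)
        ms = fit_all_subsets(tab, ["x1", "x2"])
        assert len(ms.models) == 4
        assert (np.diff(ms.table["aicc"]) >= 0).all()
        assert ms.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        wr = ms.table["weight_renormalized"]
        assert wr.sum() == pytest.approx(1.0, abs=1e-12)
        assert ms.top.formula == "x1 + x2"


class TestAssignAvailableGroups:
    def test_random_bird_mixes_responses_within_groups(self):
        tab = pd.DataFrame({
            "response": [1] * 20 + [0] * 100,
            "bird_id": [f"B{i % 4}" for i in range(20)] + ["_available_"] * 100,
        })
        out = assign_available_groups(tab, seed=1)
        av_groups = out.loc[out.response == 0, "group"].unique()
        assert set(av_groups) <= set(out.loc[out.response == 1, "group"].unique())

    def test_pooled_mode_keeps_reserved_group(self):
        tab = pd.DataFrame({"response": [1, 0], "bird_id": ["B1", "x"]})
        out = assign_available_groups(tab, mode="pooled")
        assert out.loc[out.response == 0, "group"].iloc[0] == "_available_"
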