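"""Movement-model fitting tests: oracles, closed forms, recovery, selection."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import psforage as pf
from psforage import stepfits, synth


def brute_force_ccrw_loglik(steps, params):
    """Sum the joint probability over all 2^S hidden mode paths."""
    d = params["delta"]
    lam = {0: params["lambda_I"], 1: params["lambda_E"]}
    trans = [
        [params["gamma_II"], 1 - params["gamma_II"]],
        [1 - params["gamma_EE"], params["gamma_EE"]],
    ]

    def emit(l, m):
        return (1 - np.exp(-lam[m])) * np.exp(-lam[m] * (l - 1))

    total = 0.0
    for modes in product([0, 1], repeat=len(steps)):
        p = (d if modes[0] == 0 else 1 - d) * emit(steps[0], modes[0])
        for k in range(1, len(steps)):
            p *= trans[modes[k - 1]][modes[k]] * emit(steps[k], modes[k])
        total += p
    return np.log(total)


class TestExtractSteps:
    def test_run_length_encoding(self):
        assert list(pf.extract_steps([1, 1, 1, -1, -1, 1], kind="orientations")) == [3, 2, 1]

    def test_constant_orientation(self):
        assert list(pf.extract_steps([1] * 10, kind="orientations")) == [10]

    def test_alternating(self):
        s = pf.extract_steps([1, -1] * 7, kind="orientations")
        assert np.all(s == 1) and s.size == 14

    def test_positions_and_orientations_agree(self, rng):
        moves = rng.choice([-1, 1], 500)
        pos = np.concatenate([[0], np.cumsum(moves)])
        assert np.array_equal(
            pf.extract_steps(pos, kind="positions"),
            pf.extract_steps(moves, kind="orientations"),
        )

    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=200))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_steps_sum_to_series_length(self, moves):
        assert pf.extract_steps(moves, kind="orientations").sum() == len(moves)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            pf.extract_steps([], kind="orientations")
        with pytest.raises(ValueError):
            pf.extract_steps([0], kind="positions")


class TestPmfNormalisation:
    TAIL = 100_000

    def test_bw_sums_to_one(self):
        l = np.arange(1, self.TAIL)
        for lam in (0.05, 0.3, 2.0):
            total = stepfits.bw_pmf(l, lam).sum() + stepfits.bw_survival(self.TAIL - 1, lam)
            assert abs(total - 1.0) < 1e-12

    def test_crw_sums_to_one(self):
        l = np.arange(1, self.TAIL)
        total = stepfits.crw_pmf(l, 0.8, 0.4, 0.02).sum() + stepfits.crw_survival(
            self.TAIL - 1, 0.8, 0.4, 0.02
        )
        assert abs(total - 1.0) < 1e-12

    def test_pl_sums_to_one_with_zeta_tail(self):
        for mu in (1.5, 2.0, 3.0):
            l = np.arange(1, self.TAIL)
            total = stepfits.pl_pmf(l, mu).sum() + special.zeta(mu, self.TAIL) / special.zeta(
                mu, 1.0
            )
            assert abs(total - 1.0) < 1e-12

    def test_pl_at_mu_two_matches_basel_value(self):
        assert stepfits.pl_pmf(1, 2.0) == pytest.approx(6 / np.pi**2, abs=1e-12)

    def test_pl_pmf_matches_zipf(self):
        l = np.arange(1, 50)
        assert np.allclose(stepfits.pl_pmf(l, 1.7), stats.zipf.pmf(l, 1.7), atol=1e-12)

    def test_ccrw_paths_sum_to_one_small_case(self):
        params = {"delta": 0.4, "lambda_I": 0.8, "lambda_E": 0.1, "gamma_II": 0.7, "gamma_EE": 0.9}
        total = 0.0
        for steps in product(range(1, 150), repeat=2):
            total += np.exp(brute_force_ccrw_loglik(list(steps), params))
        # truncating each step at 149 leaves only the exponential tails out
        assert total == pytest.approx(1.0, abs=1e-5)


class TestCCRWForward:
    @pytest.mark.parametrize("S", [1, 2, 5, 8])
    def test_forward_equals_brute_force(self, S, rng):
        params = {"delta": 0.3, "lambda_I": 0.7, "lambda_E": 0.05, "gamma_II": 0.8, "gamma_EE": 0.9}
        steps = rng.integers(1, 30, S).tolist()
        assert pf.loglik_ccrw(steps, params) == pytest.approx(
            brute_force_ccrw_loglik(steps, params), abs=1e-10
        )

    def test_identical_emissions_reduce_to_bw(self, rng):
        steps = rng.integers(1, 20, 50)
        params = {"delta": 0.3, "lambda_I": 0.4, "lambda_E": 0.4, "gamma_II": 0.6, "gamma_EE": 0.8}
        bw_ll = float(np.sum(np.log(stepfits.bw_pmf(steps, 0.4))))
        assert pf.loglik_ccrw(steps, params) == pytest.approx(bw_ll, abs=1e-9)

    def test_absorbed_in_one_mode_reduces_to_bw(self, rng):
        steps = rng.integers(1, 20, 50)
        params = {
            "delta": 1.0 - 1e-12,
            "lambda_I": 0.4,
            "lambda_E": 0.01,
            "gamma_II": 1.0 - 1e-12,
            "gamma_EE": 0.5,
        }
        bw_ll = float(np.sum(np.log(stepfits.bw_pmf(steps, 0.4))))
        assert pf.loglik_ccrw(steps, params) == pytest.approx(bw_ll, abs=1e-6)

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError):
            pf.loglik_ccrw([1, 2], {"delta": 1.5, "lambda_I": 1, "lambda_E": 1,
                                    "gamma_II": 0.5, "gamma_EE": 0.5})


class TestClosedFormMLEs:
    def test_bw_mean_two_gives_log_two(self):
        fit = pf.fit_bw([1, 3, 1, 3])
        assert fit.params["lambda"] == pytest.approx(np.log(2.0))

    def test_bw_degenerate_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            fit = pf.fit_bw([1, 1, 1])
        assert np.isinf(fit.params["lambda"])
        assert fit.loglik == 0.0

    def test_crw_with_p_one_reduces_to_bw(self, rng):
        steps = synth.sample_steps("bw", {"lambda": 0.3}, 3000, rng)
        bw = pf.fit_bw(steps)
        ll_as_mixture = float(
            np.sum(np.log(stepfits.crw_pmf(steps, 1.0, bw.params["lambda"], 0.01)))
        )
        assert ll_as_mixture == pytest.approx(bw.loglik, abs=1e-8)

    def test_nesting_inequalities_at_optimum(self, rng):
        steps = synth.sample_steps("ccrw",
            {"delta": 0.5, "lambda_I": 0.5, "lambda_E": 0.03, "gamma_II": 0.9, "gamma_EE": 0.95},
            4000, rng)
        fits = pf.fit_all_models(steps, rng=rng)
        assert fits["ccrw"].loglik >= fits["crw"].loglik - 1e-6
        assert fits["crw"].loglik >= fits["bw"].loglik - 1e-6

    def test_crw_nests_bw_on_geometric_sample(self, rng):
        steps = synth.sample_steps("bw", {"lambda": 0.4}, 5000, rng)
        assert pf.fit_ccrw(steps, rng=rng).loglik >= pf.fit_bw(steps).loglik - 1e-6


class TestParameterRecovery:
    """MLE bias within 3 SE at S = 1e4, with SE taken from replicate spread."""

    @pytest.mark.parametrize(
        "model,true",
        [
            ("bw", {"lambda": 0.3}),
            ("crw", {"p": 0.8, "beta_I": 0.4, "beta_E": 0.02}),
            ("pl", {"mu": 2.0}),
            ("ccrw", {"delta": 0.5, "lambda_I": 0.4, "lambda_E": 0.02,
                      "gamma_II": 0.85, "gamma_EE": 0.98}),
        ],
    )
    def test_recovery_within_three_se(self, model, true):
        seeds = {"bw": 101, "crw": 102, "pl": 103, "ccrw": 104}
        rng = np.random.default_rng(seeds[model])
        K = 6
        est = {k: [] for k in true}
        for _ in range(K):
            sample = synth.sample_steps(model, true, 10_000, rng)
            fit = stepfits.fit_model(model, sample, **({"rng": rng} if model in ("crw", "ccrw") else {}))
            for k in true:
                est[k].append(fit.params[k])
        for k, v in true.items():
            arr = np.array(est[k])
            if k == "delta":
                # one observation's worth of information per sequence: the
                # MLE is boundary-valued and its SE is O(1)
                assert abs(arr.mean() - v) <= 0.5 + 1e-9
                continue
            se = arr.std(ddof=1) / np.sqrt(K) + 1e-4  # guard exact-zero spread
            assert abs(arr.mean() - v) < 3 * se + 0.01 * max(abs(v), 0.1), (
                f"{model}.{k}: mean {arr.mean():.4f} vs true {v}"
            )

    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(77)
        spreads = []
        for S in (1000, 10_000):
            ests = [
                pf.fit_bw(synth.sample_steps("bw", {"lambda": 0.3}, S, rng)).params["lambda"]
                for _ in range(12)
            ]
            spreads.append(np.std(ests))
        assert spreads[1] < spreads[0]


class TestModelComparison:
    def test_aic_bic_identities(self, rng):
        steps = synth.sample_steps("bw", {"lambda": 0.3}, 500, rng)
        fit = pf.fit_bw(steps)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(1 * np.log(500) - 2 * fit.loglik)
        ccrw = pf.fit_ccrw(steps, rng=rng)
        assert ccrw.k == 5
        assert ccrw.bic == pytest.approx(5 * np.log(500) - 2 * ccrw.loglik)

    def test_equal_aic_gives_equal_weights(self):
        a = stepfits.FitResult("bw", {"lambda": 1.0}, -100.0, 50)
        b = stepfits.FitResult("pl", {"mu": 2.0}, -100.0, 50)
        cm = pf.compare_models([a, b])
        assert cm.akaike_weights["bw"] == pytest.approx(0.5)

    def test_delta_aic_two_gives_weight_ratio_e(self):
        a = stepfits.FitResult("bw", {"lambda": 1.0}, -100.0, 50)
        b = stepfits.FitResult("pl", {"mu": 2.0}, -101.0, 50)  # AIC differs by 2
        cm = pf.compare_models([a, b])
        assert cm.akaike_weights["bw"] / cm.akaike_weights["pl"] == pytest.approx(np.e)

    def test_bic_winner_requires_margin_of_ten(self):
        a = stepfits.FitResult("bw", {"lambda": 1.0}, -100.0, 50)
        b = stepfits.FitResult("pl", {"mu": 2.0}, -103.0, 50)  # delta BIC = 6
        assert pf.compare_models([a, b]).bic_best is None
        c = stepfits.FitResult("pl", {"mu": 2.0}, -110.0, 50)
        assert pf.compare_models([a, c]).bic_best == "bw"

    def test_mismatched_samples_rejected(self):
        a = stepfits.FitResult("bw", {"lambda": 1.0}, -100.0, 50)
        b = stepfits.FitResult("pl", {"mu": 2.0}, -100.0, 60)
        with pytest.raises(ValueError):
            pf.compare_models([a, b])

    def test_selection_recovers_generating_model(self, rng):
        # BIC with the >10 margin picks the generator for the identifiable
        # corners of model space
        cases = {
            "bw": {"lambda": 0.3},
            "pl": {"mu": 2.0},
            "ccrw": {"delta": 0.5, "lambda_I": 0.5, "lambda_E": 0.02,
                     "gamma_II": 0.9, "gamma_EE": 0.97},
        }
        for model, params in cases.items():
            hits = 0
            for _ in range(5):
                steps = synth.sample_steps(model, params, 10_000, rng)
                cm = pf.compare_models(pf.fit_all_models(steps, rng=rng))
                hits += cm.bic_best == model
            assert hits >= 4, f"{model}: selected {hits}/5"


class TestGoodnessOfFit:
    def test_iid_gof_accepts_true_model(self, rng):
        steps = synth.sample_steps("bw", {"lambda": 0.4}, 3000, rng)
        g, p = pf.gof_iid(steps, pf.fit_bw(steps), n_boot=60, rng=rng)
        assert p > 0.05

    def test_iid_gof_rejects_bw_on_bimodal_data(self, rng):
        steps = synth.sample_steps(
            "ccrw",
            {"delta": 0.5, "lambda_I": 0.9, "lambda_E": 0.01, "gamma_II": 0.9, "gamma_EE": 0.95},
            5000, rng)
        g, p = pf.gof_iid(steps, pf.fit_bw(steps), n_boot=60, rng=rng)
        assert p < 0.05

    def test_ccrw_residuals_near_uniform_under_truth(self, rng):
        params = {"delta": 0.5, "lambda_I": 0.5, "lambda_E": 0.03, "gamma_II": 0.9, "gamma_EE": 0.95}
        steps = synth.sample_steps("ccrw", params, 8000, rng)
        fit = pf.fit_ccrw(steps, rng=rng)
        d, p = pf.gof_ccrw(steps, fit)
        # discreteness leaves residual atoms, so D_KS has a floor well above
        # the continuous KS scale; a correct fit still sits far below the
        # misfit regime
        assert d < 0.1

    def test_ccrw_residuals_degenerate_on_constant_data(self):
        fit = stepfits.FitResult(
            "ccrw",
            {"delta": 0.5, "lambda_I": 0.5, "lambda_E": 0.05, "gamma_II": 0.8, "gamma_EE": 0.9},
            -10.0, 200)
        d, p = pf.gof_ccrw(np.ones(200, dtype=int), fit)
        assert d > 0.3


class TestSurvival:
    def test_survival_at_zero_is_one(self, rng):
        steps = synth.sample_steps("bw", {"lambda": 0.3}, 200, rng)
        curves = pf.survival_curves(steps)
        assert curves["empirical"][0] == 1.0

    def test_bw_survival_closed_form(self):
        l = np.arange(0, 30)
        assert np.allclose(stepfits.bw_survival(l, 0.4), np.exp(-0.4 * l))

    def test_symmetric_dwell_times_give_half_weight(self):
        assert stepfits.ccrw_marginal_weight(0.9, 0.9) == pytest.approx(0.5)

    def test_model_curves_present_and_decreasing(self, rng):
        steps = synth.sample_steps("crw", {"p": 0.7, "beta_I": 0.5, "beta_E": 0.05}, 2000, rng)
        fits = pf.fit_all_models(steps, rng=rng)
        curves = pf.survival_curves(steps, fits)
        for m in ("bw", "crw", "ccrw", "pl"):
            assert np.all(np.diff(curves[m]) <= 1e-12)
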