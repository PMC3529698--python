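"""Richardson/Romberg extrapolation of moment estimates."""

import numpy as np
import pytest

from tauleapx import (
    LeapProtocol,
    analytic_mean_linear,
    binomial_reconstruct,
    build_network,
    etl_mean_recursion,
    etl_second_moment_recursion,
    extrapolate_pair,
    extrapolated_run,
    multimodal_extrapolate,
    romberg_extrapolate,
    run_ensemble,
    suggest_split_points,
)
from tauleapx.extrapolation import MomentRecord


def _rec(mean, tau, T=1.0, second=None, order=1, method="etl"):
    mean = np.atleast_1d(np.asarray(mean, float))
    if second is None:
        second = np.outer(mean, mean)
    return MomentRecord(mean=mean, second_moment=np.atleast_2d(second),
                        tau=tau, T=T, order=order, method=method)


class TestPairwise:
    def test_identical_inputs_unchanged(self):
        """Weights sum to one, so extrapolating a constant is the identity."""
        a = _rec([5.0, 2.0], tau=0.4)
        b = _rec([5.0, 2.0], tau=0.2)
        out = extrapolate_pair(a, b, k=1, p=2)
        np.testing.assert_allclose(out.mean, [5.0, 2.0])
        np.testing.assert_allclose(out.second_moment, a.second_moment)
        assert out.order == 2

    def test_linear_bias_annihilated(self):
        """m(tau) = a + b*tau: the pair combination recovers a exactly."""
        a, b = 2.0, 1.0
        coarse = _rec([a + b * 0.4], tau=0.4)
        fine = _rec([a + b * 0.2], tau=0.2)
        out = extrapolate_pair(coarse, fine, k=1, p=2)
        assert out.mean[0] == pytest.approx(2.0, rel=1e-14)

    def test_decay_recursion_pair_error(self, decay_oracle):
        """Extrapolating exact Euler-leap means at (0.8, 0.4) leaves an
        absolute error of ~2.6 (exact recursion value 2.54; the reference
        figure 2.6 carries the sampling noise of finite ensembles)."""
        mu_T = analytic_mean_linear(decay_oracle, 10.4)[0]
        coarse = _rec(etl_mean_recursion(decay_oracle, 0.8, 13), 0.8, T=10.4)
        fine = _rec(etl_mean_recursion(decay_oracle, 0.4, 26), 0.4, T=10.4)
        out = extrapolate_pair(coarse, fine, k=1, p=2)
        assert abs(mu_T - out.mean[0]) == pytest.approx(2.6, abs=0.07)

    def test_mismatched_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio mismatch"):
            extrapolate_pair(_rec([1.0], 0.4), _rec([1.0], 0.3), k=1)

    def test_mismatched_horizon_rejected(self):
        with pytest.raises(ValueError, match="time horizons"):
            extrapolate_pair(_rec([1.0], 0.4, T=2.0), _rec([1.0], 0.2, T=1.0))


class TestRomberg:
    def test_quadratic_bias_annihilated_at_apex(self):
        """m(tau) = 1 + tau + tau^2 -> apex recovers 1 exactly."""
        ests = [_rec([1 + t + t * t], t) for t in (0.4, 0.2, 0.1)]
        table = romberg_extrapolate(ests, base_order=1, p=2)
        assert table.apex.mean[0] == pytest.approx(1.0, rel=1e-13)
        assert table.apex.order == 3
        assert [len(c) for c in table.columns] == [3, 2, 1]

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_polynomial_bias_annihilated_exactly(self, degree):
        """A degree-d polynomial bias is annihilated by d Romberg columns."""
        coef = np.arange(1.0, degree + 2)  # a0..ad
        taus = [0.8 / 2**i for i in range(degree + 1)]
        ests = [_rec([np.polyval(coef[::-1], t)], t) for t in taus]
        table = romberg_extrapolate(ests, base_order=1, p=2)
        assert table.apex.mean[0] == pytest.approx(coef[0], rel=1e-12)

    def test_two_estimates_equals_pair(self):
        a, b = _rec([3.3], 0.4), _rec([3.1], 0.2)
        table = romberg_extrapolate([a, b], base_order=1, p=2)
        pair = extrapolate_pair(a, b, k=1, p=2)
        assert table.apex.mean[0] == pair.mean[0]

    def test_decay_apex_beats_first_column(self, decay_oracle):
        """With exact recursion input (no MC noise) the apex error is
        strictly below both single-extrapolation errors."""
        mu_T = analytic_mean_linear(decay_oracle, 10.4)[0]
        ests = [
            _rec(etl_mean_recursion(decay_oracle, t, round(10.4 / t)), t, T=10.4)
            for t in (0.8, 0.4, 0.2)
        ]
        table = romberg_extrapolate(ests, base_order=1, p=2)
        first_col = [abs(mu_T - r.mean[0]) for r in table.columns[1]]
        apex = abs(mu_T - table.apex.mean[0])
        assert apex < min(first_col)

    def test_one_level_error_is_second_order(self, decay_oracle):
        """Error ratio of the extrapolated recursion means at (tau, tau/2)
        sits in [3.6, 4.4]: O(tau^2)."""
        mu_T = analytic_mean_linear(decay_oracle, 10.4)[0]

        def xerr(tau):
            c = _rec(etl_mean_recursion(decay_oracle, tau, round(10.4 / tau)),
                     tau, T=10.4)
            f = _rec(etl_mean_recursion(decay_oracle, tau / 2,
                                        round(20.8 / tau)), tau / 2, T=10.4)
            return abs(mu_T - extrapolate_pair(c, f, k=1, p=2).mean[0])

        ratio = xerr(0.2) / xerr(0.1)
        assert 3.6 <= ratio <= 4.4

    def test_non_geometric_ladder_rejected(self):
        with pytest.raises(ValueError, match="geometric"):
            romberg_extrapolate([_rec([1.0], 0.4), _rec([1.0], 0.25)])


class TestExtrapolatedRun:
    def test_zero_rates_pass_through(self):
        net = build_network({
            "species": [{"name": "X", "initial": 12}],
            "reactions": [{"reactants": {"X": 1}, "products": {}, "rate": 0.0}],
        })
        table = extrapolated_run(net, LeapProtocol(tau=0.5, T=2.0, S=10, seed=1))
        assert table.apex.mean[0] == pytest.approx(12.0)

    def test_decay_error_reduced_tenfold(self, decay, decay_oracle):
        """One extrapolation level shrinks the tau=0.8 mean error from 152
        to the few-molecule scale (factor > 10) at S=2e5."""
        net, _ = decay
        mu_T = analytic_mean_linear(decay_oracle, 10.4)[0]
        proto = LeapProtocol(tau=0.8, T=10.4, S=200_000, seed=5)
        plain = run_ensemble(net, proto)
        table = extrapolated_run(net, proto, levels=1)
        err_plain = abs(mu_T - plain.mean[0])
        err_x = abs(mu_T - table.apex.mean[0])
        assert err_plain / err_x > 10


class TestMultimodal:
    def test_single_all_inclusive_peak_equals_global(self, decay):
        """A split below all states leaves one all-inclusive peak whose
        extrapolation is bit-for-bit the global one."""
        net, _ = decay
        proto = LeapProtocol(tau=0.8, T=10.4, S=2000, seed=2, keep_states=True)
        coarse = run_ensemble(net, proto)
        fine = run_ensemble(net, proto.with_tau(0.4, seed=3))
        ref = extrapolate_pair(coarse, fine, k=1, p=2)
        for splits in ([-1.0], []):
            peaks = multimodal_extrapolate(coarse, fine, splits, k=1)
            assert len(peaks) == 1
            np.testing.assert_array_equal(peaks[0].mean, ref.mean)
            np.testing.assert_array_equal(peaks[0].second_moment,
                                          ref.second_moment)

    def test_subset_empty_at_one_stepsize_rejected(self):
        from tauleapx import EnsembleMomentEstimate

        coarse = EnsembleMomentEstimate.from_states(
            np.array([[1], [2], [3]]), tau=0.8, T=1.6, method="etl", seed=0,
            keep_states=True)
        fine = EnsembleMomentEstimate.from_states(
            np.array([[1], [2], [300]]), tau=0.4, T=1.6, method="etl", seed=0,
            keep_states=True)
        with pytest.raises(ValueError, match="empty replicate subset"):
            multimodal_extrapolate(coarse, fine, [100.0], k=1)

    def test_states_required(self, decay):
        net, _ = decay
        proto = LeapProtocol(tau=0.8, T=10.4, S=100, seed=2)
        est = run_ensemble(net, proto)
        with pytest.raises(ValueError, match="keep_states"):
            multimodal_extrapolate(est, est, [100.0], k=1)

    def test_schlogl_peak_means_match_cme(self, schlogl, schlogl_cme):
        """Per-peak extrapolated means agree with the CME conditional means
        (101.3 / 546.2) within 4 SE at S=2e4, tau=0.1/0.05."""
        net, defaults = schlogl
        S = 20_000
        proto = LeapProtocol(tau=0.1, T=5.0, S=S, seed=8, keep_states=True)
        coarse = run_ensemble(net, proto)
        fine = run_ensemble(net, proto.with_tau(0.05, seed=9))
        peaks = multimodal_extrapolate(coarse, fine, [300.0], k=1)
        cm = schlogl_cme.conditional_moments(300.0)
        for rec, ref in zip(peaks, (cm["low"], cm["high"])):
            n_eff = min(rec.meta["subset_sizes"])
            se = np.sqrt(max(ref["variance"], 1.0) / n_eff)
            # extrapolation weights (2, -1) roughly triple the variance
            assert abs(rec.mean[0] - ref["mean"]) < 4 * np.sqrt(5.0) * se

    def test_split_sensitivity_variance_exceeds_mean(self, schlogl):
        """Moving the split from 250 to 350 shifts the conditional variance
        relatively more than the conditional mean, for both peaks."""
        net, _ = schlogl
        proto = LeapProtocol(tau=0.1, T=5.0, S=20_000, seed=8, keep_states=True)
        est = run_ensemble(net, proto)
        from tauleapx.extrapolation import _partition

        lo250, hi250 = _partition(est, [250.0], 0).estimates
        lo350, hi350 = _partition(est, [350.0], 0).estimates
        for a, b in ((lo250, lo350), (hi250, hi350)):
            rel_mean = abs(a.mean[0] - b.mean[0]) / abs(a.mean[0])
            rel_var = abs(a.variance[0] - b.variance[0]) / abs(a.variance[0])
            assert rel_var > rel_mean


class TestSplitSuggestion:
    def test_unimodal_gives_no_split(self, rng):
        sample = rng.binomial(10_000, 0.35, size=20_000)
        assert suggest_split_points(sample) == []

    def test_balanced_mixture_split_between_modes(self, rng):
        sample = np.concatenate([
            rng.normal(100.0, 15.0, 5000),
            rng.normal(550.0, 40.0, 5000),
        ])
        splits = suggest_split_points(sample)
        assert len(splits) == 1
        assert 150 < splits[0] < 500

    def test_schlogl_leap_states_split_in_gap(self, schlogl):
        net, _ = schlogl
        proto = LeapProtocol(tau=0.1, T=5.0, S=20_000, seed=8, keep_states=True)
        est = run_ensemble(net, proto)
        splits = suggest_split_points(est.final_states[:, 0])
        assert len(splits) >= 1
        assert any(250 < s < 350 for s in splits)

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            suggest_split_points(np.arange(100))


class TestBinomialReconstruct:
    def test_moment_inversion(self):
        p = np.exp(-0.1 * 10.4)
        mean, var = 1e4 * p, 1e4 * p * (1 - p)
        n, phat = binomial_reconstruct(mean, var)
        assert n == 10_000
        assert phat == pytest.approx(p, rel=1e-12)
        assert phat == pytest.approx(0.35345, abs=5e-6)

    def test_poisson_limit_rejected(self):
        with pytest.raises(ValueError, match="variance >= mean"):
            binomial_reconstruct(10.0, 10.0)

    def test_reconstructed_pmf_close_to_cme(self, decay, decay_oracle):
        """Extrapolated moments at the (0.4, 0.2) pair reconstruct a binomial
        within total variation 0.01 of the exact terminal law; the coarsest
        (0.8, 0.4) pair carries a deterministic ~2.5-molecule residual mean
        bias that floors its TV near 0.02."""
        from scipy.stats import binom

        net, _ = decay
        grid = np.arange(0, 10_001)
        exact = binom.pmf(grid, 10_000, np.exp(-0.1 * 10.4))

        def tv_at(tau, seed):
            proto = LeapProtocol(tau=tau, T=10.4, S=1_000_000, seed=seed)
            apex = extrapolated_run(net, proto, levels=1).apex
            n, phat = binomial_reconstruct(apex.mean[0], apex.variance[0])
            return 0.5 * np.abs(binom.pmf(grid, n, phat) - exact).sum()

        assert tv_at(0.4, 17) < 0.01
        assert tv_at(0.8, 18) < 0.03
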