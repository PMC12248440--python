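"""EM mixture fitting: recovery, monotonicity, model selection, oracles."""

import warnings

import numpy as np
import pytest

from her2ith import FitOptions, HistogramGMM, SignalHistogram, fit_gmm, select_components
from her2ith.gmm import DegenerateFitWarning


def _trace_monotone(trace, slack=1e-10):
    return all(b >= a - slack for a, b in zip(trace, trace[1:]))


class TestFitK1:
    def test_point_mass_sigma_floored(self):
        fit = fit_gmm(SignalHistogram({4: 100}), 1)
        assert fit.means[0] == 4.0
        assert fit.sds[0] == FitOptions().sigma_floor
        assert fit.converged

    def test_closed_form_weighted_moments(self):
        hist = SignalHistogram({2: 10, 6: 30})
        fit = fit_gmm(hist, 1)
        assert fit.means[0] == pytest.approx(5.0)
        assert fit.sds[0] == pytest.approx(np.sqrt(3.0))


class TestFitK2:
    def test_parameter_recovery_on_planted_mixture(self, bimodal_hist):
        fit = fit_gmm(bimodal_hist, 2)
        assert fit.converged
        assert fit.means[0] == pytest.approx(1.5, abs=0.15)
        assert fit.means[1] == pytest.approx(6.0, abs=0.15)
        assert fit.weights[0] == pytest.approx(0.4, abs=0.05)
        assert _trace_monotone(fit.loglik_trace)

    def test_symmetric_two_point_histogram(self):
        # symmetry forces equal weights; point masses pin the means
        fit = fit_gmm(SignalHistogram({1: 50, 7: 50}), 2)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=1e-6)
        assert fit.means == pytest.approx([1.0, 7.0], abs=1e-6)

    def test_monotone_loglik_across_runs_and_seeds(self, bimodal_hist, unimodal_hist):
        for hist in (bimodal_hist, unimodal_hist):
            for seed in range(4):
                fit = fit_gmm(hist, 2, FitOptions(seed=seed))
                assert _trace_monotone(fit.loglik_trace)

    def test_mixture_mean_identity_at_convergence(self, bimodal_hist):
        fit = fit_gmm(bimodal_hist, 2)
        assert fit.mixture_mean == pytest.approx(bimodal_hist.mean, abs=1e-6)

    def test_initialization_seed_does_not_change_solution(self, bimodal_hist):
        ref = fit_gmm(bimodal_hist, 2, FitOptions(seed=0))
        for seed in (1, 5, 99):
            fit = fit_gmm(bimodal_hist, 2, FitOptions(seed=seed))
            assert fit.means == pytest.approx(ref.means, abs=1e-4)
            assert fit.weights == pytest.approx(ref.weights, abs=1e-4)

    def test_components_sorted_by_mean(self, bimodal_hist):
        fit = fit_gmm(bimodal_hist, 2)
        assert fit.means[0] <= fit.means[1]

    def test_degenerate_single_bin_warns_and_floors(self):
        with pytest.warns(DegenerateFitWarning):
            fit = fit_gmm(SignalHistogram({4: 100}), 2)
        assert fit.means == pytest.approx([4.0, 4.0])
        assert (fit.sds == FitOptions().sigma_floor).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            HistogramGMM(SignalHistogram({2: 5, 4: 5}), 3)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            HistogramGMM(SignalHistogram({4: 1}), 1)


class TestOracles:
    def test_em_mle_matches_dense_grid_on_small_support(self):
        """On a 3-bin histogram, no dense-grid parameter combination beats EM,
        and the grid argmax lies within grid resolution of the EM solution."""
        hist = SignalHistogram({1: 30, 4: 10, 7: 60})
        fit = fit_gmm(hist, 2, FitOptions(n_starts=8))
        model = HistogramGMM(hist, 2)

        pis = np.linspace(0.05, 0.95, 19)
        mus = np.arange(0.0, 8.25, 0.25)
        sds = np.array([0.25, 0.4, 0.6, 0.9, 1.3, 1.8, 2.5])
        x, w = hist.values_weights()

        def grid_ll(mu, sd):  # (n_mu, n_sd, n_bins) log component density
            z = (x[None, None, :] - mu[:, None, None]) / sd[None, :, None]
            return (-0.5 * z * z - np.log(sd)[None, :, None]
                    - 0.5 * np.log(2 * np.pi))

        lc = grid_ll(mus, sds)  # shared for both components
        best_ll, best_params = -np.inf, None
        for i1, m1 in enumerate(mus):
            for j1, s1 in enumerate(sds):
                c1 = lc[i1, j1]
                # broadcast over all (m2, s2, pi)
                c2 = lc.reshape(-1, len(x))
                for pi in pis:
                    mix = np.logaddexp(np.log(pi) + c1[None, :],
                                       np.log1p(-pi) + c2)
                    lls = mix @ w
                    k = int(np.argmax(lls))
                    if lls[k] > best_ll:
                        i2, j2 = divmod(k, len(sds))
                        best_ll = float(lls[k])
                        best_params = (pi, m1, mus[i2], s1, sds[j2])

        assert fit.loglik >= best_ll - 1e-9
        pi, m1, m2, s1, s2 = best_params
        order = np.argsort([m1, m2])
        grid_means = np.array([m1, m2])[order]
        grid_pis = np.array([pi, 1 - pi])[order]
        assert fit.means == pytest.approx(grid_means, abs=0.25)
        assert fit.weights == pytest.approx(grid_pis, abs=0.06)

    def test_against_sklearn_gaussian_mixture(self, bimodal_hist):
        """Independent EM implementation recovers the same two components."""
        from sklearn.mixture import GaussianMixture

        xs, ws = bimodal_hist.values_weights()
        x = np.repeat(xs, ws.astype(int)).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=0,
                             tol=1e-8, max_iter=500).fit(x)
        order = np.argsort(gm.means_.ravel())
        fit = fit_gmm(bimodal_hist, 2)
        assert fit.means == pytest.approx(gm.means_.ravel()[order], abs=0.05)
        assert fit.weights == pytest.approx(gm.weights_[order], abs=0.02)


class TestSelection:
    def test_unimodal_sample_prefers_one_component(self, unimodal_hist):
        sel = select_components(unimodal_hist)
        assert sel.chosen_k == 1
        assert sel.fit_k1.bic < sel.fit_k2.bic

    def test_bimodal_sample_prefers_two_components(self, bimodal_hist):
        sel = select_components(bimodal_hist)
        assert sel.chosen_k == 2
        assert sel.fit_k2.bic < sel.fit_k1.bic

    def test_point_mass_prefers_one_component(self):
        assert select_components(SignalHistogram({4: 100})).chosen_k == 1

    def test_small_weight_split_rejected_by_pi_min(self, bimodal_hist):
        # an absurdly high weight cutoff forces the monophasic call
        sel = select_components(bimodal_hist, pi_min=0.5)
        assert sel.chosen_k in (1, 2)
        sel_strict = select_components(bimodal_hist, pi_min=0.45)
        if sel_strict.fit_k2.weights.min() < 0.45:
            assert sel_strict.chosen_k == 1


class TestResultsObject:
    def test_summary_and_serialization(self, bimodal_hist):
        fit = fit_gmm(bimodal_hist, 2)
        text = fit.summary()
        assert "BIC" in text and "mixture mean" in text
        d = fit.to_dict(include_trace=True)
        assert d["k"] == 2 and len(d["loglik_trace"]) == len(fit.loglik_trace)

    def test_standard_errors_finite_on_clean_fit(self, bimodal_hist):
        se = fit_gmm(bimodal_hist, 2).standard_errors()
        assert np.isfinite(se["mu1"]) and se["mu1"] < 0.2
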