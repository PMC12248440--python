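"""Gaussian mixture fitting on HER2 copy-number histograms.

The copy-number distribution of one tumor is modelled as

    f(x) = pi_1 N(x | mu_1, sigma_1) + pi_2 N(x | mu_2, sigma_2)

with the one-component model as the monophasic special case.  Fitting is
maximum likelihood via expectation-maximization (EM) on the binned data:
each occupied integer bin enters the likelihood at its center with its
nucleus count as a frequency weight — with integer signal counts this is
identical to the per-cell likelihood.

Model selection between one and two components uses the Bayesian
information criterion, BIC = -2 log L + p log n with n the number of
nuclei (p = 2 for one component, 5 for two); a biphasic (two-component)
tumor additionally requires both mixture weights to be non-negligible.

The surface follows the Model/Results convention: build a
:class:`HistogramGMM` from a histogram, call :meth:`~HistogramGMM.fit`,
and read estimates, uncertainties and diagnostics off the returned
:class:`HistogramGMMResults` (or print ``results.summary()``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .histogram import SignalHistogram

__all__ = [
    "FitOptions",
    "HistogramGMM",
    "HistogramGMMResults",
    "ModelSelection",
    "DegenerateFitWarning",
    "fit_gmm",
    "select_components",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateFitWarning(UserWarning):
    """Two components requested on a histogram that cannot support them."""


@dataclass(frozen=True)
class FitOptions:
    """EM hyperparameters.

    sigma_floor : minimum component standard deviation, in copies.  FISH
        signal counts are integers, so a component narrower than a fraction
        of a copy is physically meaningless and would let the likelihood
        blow up on a point mass; 0.25 copies keeps point masses finite.
    tol : relative log-likelihood convergence tolerance.
    max_iter : EM iteration cap per start.
    n_starts : number of EM starts (one quantile-split start plus seeded
        random perturbations); the best final log-likelihood wins, ties
        broken by lower BIC then lower first-component mean.
    seed : seed of the restart perturbation stream.
    """

    sigma_floor: float = 0.25
    tol: float = 1e-8
    max_iter: int = 500
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.sigma_floor <= 0 or self.tol <= 0:
            raise ValueError("sigma_floor and tol must be positive")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")


class HistogramGMM:
    """One- or two-component normal mixture model for a signal histogram.

    Parameters
    ----------
    hist : SignalHistogram
        Binned HER2 copy-number data (needs at least 2 nuclei).
    n_components : {1, 2}
    """

    def __init__(self, hist: SignalHistogram, n_components: int):
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if hist.n_cells < 2:
            raise ValueError("mixture fitting needs at least 2 nuclei")
        self.hist = hist
        self.k = int(n_components)
        self.x, self.w = hist.values_weights()
        self.n = float(self.w.sum())

    # -- likelihood -------------------------------------------------------

    def _log_components(self, weights, means, sds) -> np.ndarray:
        """log(pi_i) + log N(x | mu_i, sigma_i), shape (k, n_bins)."""
        w = np.asarray(weights, dtype=float)[:, None]
        mu = np.asarray(means, dtype=float)[:, None]
        sd = np.asarray(sds, dtype=float)[:, None]
        z = (self.x[None, :] - mu) / sd
        return np.log(w) - 0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI

    def loglike(self, weights, means, sds) -> float:
        """Weighted log-likelihood of arbitrary mixture parameters."""
        comp = self._log_components(weights, means, sds)
        return float(np.dot(self.w, logsumexp(comp, axis=0)))

    def _bic(self, loglik: float) -> float:
        p = 3 * self.k - 1  # (k-1) weights + k means + k sds
        return -2.0 * loglik + p * math.log(self.n)

    # -- fitting ----------------------------------------------------------

    def fit(self, options: FitOptions | None = None) -> "HistogramGMMResults":
        """Maximum-likelihood fit; best of ``n_starts`` EM runs."""
        opts = options or FitOptions()
        if self.k == 1:
            return self._fit_k1(opts)
        if len(self.x) == 1:
            warnings.warn(
                "two components requested for a single occupied bin; "
                "returning the sigma-floored degenerate solution",
                DegenerateFitWarning,
                stacklevel=2,
            )
            mu = float(self.x[0])
            pars = (np.array([0.5, 0.5]), np.array([mu, mu]),
                    np.array([opts.sigma_floor, opts.sigma_floor]))
            ll = self.loglike(*pars)
            return self._results(*pars, ll, [ll], 0, True, opts, degenerate=True)

        best = None
        for start in self._initial_params(opts):
            run = self._em(start, opts)
            if best is None or self._better(run, best):
                best = run
        (weights, means, sds), ll, trace, n_iter, converged = best
        return self._results(weights, means, sds, ll, trace, n_iter, converged, opts)

    def _fit_k1(self, opts: FitOptions) -> "HistogramGMMResults":
        mu = float(np.average(self.x, weights=self.w))
        var = float(np.average((self.x - mu) ** 2, weights=self.w))
        sd = max(math.sqrt(var), opts.sigma_floor)
        pars = (np.array([1.0]), np.array([mu]), np.array([sd]))
        ll = self.loglike(*pars)
        return self._results(*pars, ll, [ll], 0, True, opts,
                             degenerate=len(self.x) == 1)

    def _initial_params(self, opts: FitOptions):
        """Quantile-split start plus seeded random perturbations."""
        order = np.argsort(self.x)
        cum = np.cumsum(self.w[order]) / self.n
        lo = cum <= 0.5
        if not lo.any() or lo.all():
            lo = np.zeros_like(lo, dtype=bool)
            lo[: max(1, len(self.x) // 2)] = True
        xs = self.x[order]
        ws = self.w[order]
        m1 = float(np.average(xs[lo], weights=ws[lo]))
        m2 = float(np.average(xs[~lo], weights=ws[~lo]))
        overall_sd = max(math.sqrt(self.hist.var), opts.sigma_floor)
        base_sd = max(overall_sd / 2.0, opts.sigma_floor)
        yield (np.array([0.5, 0.5]), np.array([m1, m2]),
               np.array([base_sd, base_sd]))
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.n_starts - 1):
            p1 = rng.uniform(0.2, 0.8)
            mus = np.sort(rng.normal([m1, m2], overall_sd / 2.0))
            yield (np.array([p1, 1.0 - p1]), mus,
                   np.array([base_sd, base_sd]))

    def _em(self, start, opts: FitOptions):
        weights, means, sds = (np.array(a, dtype=float) for a in start)
        sds = np.maximum(sds, opts.sigma_floor)
        trace: list[float] = []
        converged = False
        n_iter = 0
        prev = -math.inf
        for it in range(opts.max_iter + 1):
            # E-step quantities at the *current* parameters; the same pass
            # yields the log-likelihood, so the trace is exact per iterate.
            log_comp = self._log_components(weights, means, sds)
            peak = log_comp.max(axis=0)
            log_norm = peak + np.log(np.exp(log_comp - peak).sum(axis=0))
            ll = float(np.dot(self.w, log_norm))
            trace.append(ll)
            if it > 0 and abs(ll - prev) <= opts.tol * (abs(prev) + 1.0):
                converged = True
                break
            if it == opts.max_iter:
                break
            prev = ll
            resp = np.exp(log_comp - log_norm)
            # M-step with frequency weights; sigma clamped at the floor
            # (the clamp is the constrained M-step maximum, so the
            # likelihood stays monotone)
            wk = resp * self.w
            nk = np.maximum(wk.sum(axis=1), 1e-300)
            weights = nk / self.n
            means = (wk @ self.x) / nk
            var = (wk * (self.x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
            sds = np.maximum(np.sqrt(np.maximum(var, 0.0)), opts.sigma_floor)
            n_iter = it + 1
        return (weights, means, sds), trace[-1], trace, n_iter, converged

    def _better(self, run, best) -> bool:
        ll_a, ll_b = run[1], best[1]
        if not math.isclose(ll_a, ll_b, rel_tol=0, abs_tol=1e-9):
            return ll_a > ll_b
        # equal likelihood: lower BIC is identical here (same k), so break
        # ties by the lower first-component mean after sorting
        mu_a = float(np.min(run[0][1]))
        mu_b = float(np.min(best[0][1]))
        return mu_a < mu_b

    def _results(self, weights, means, sds, loglik, trace, n_iter, converged,
                 opts, degenerate: bool = False) -> "HistogramGMMResults":
        order = np.lexsort((weights, sds, means))
        return HistogramGMMResults(
            model=self,
            k=self.k,
            weights=np.asarray(weights)[order],
            means=np.asarray(means)[order],
            sds=np.asarray(sds)[order],
            loglik=float(loglik),
            bic=self._bic(float(loglik)),
            n_iter=int(n_iter),
            converged=bool(converged),
            loglik_trace=list(trace),
            options=opts,
            degenerate=degenerate,
        )


@dataclass
class HistogramGMMResults:
    """Fitted mixture: estimates, model-selection score, convergence record.

    Components are sorted by ascending mean, so ``means[0]`` is the
    low-copy component of a biphasic fit.  ``loglik_trace`` is the
    per-iteration log-likelihood of the winning EM run (monotone
    non-decreasing by construction of the EM updates).
    """

    model: HistogramGMM
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(repr=False)
    options: FitOptions = field(repr=False, default_factory=FitOptions)
    degenerate: bool = False

    @property
    def mixture_mean(self) -> float:
        """pi_1 mu_1 + pi_2 mu_2 — the fitted overall mean copy number."""
        return float(np.dot(self.weights, self.means))

    def standard_errors(self) -> dict[str, float]:
        """Delta-method standard errors from the observed information.

        Computed numerically on the unconstrained parameterisation
        (logit pi_1, mu_i, log sigma_i) and mapped back; NaN where the
        information matrix is singular (e.g. a sigma pinned at the floor).
        """
        from statsmodels.tools.numdiff import approx_hess1

        mdl = self.model
        if self.k == 1:
            theta = np.array([self.means[0], math.log(self.sds[0])])

            def negll(t):
                return -mdl.loglike([1.0], [t[0]], [math.exp(t[1])])

            names = ["mu1", "sigma1"]
            jac = np.array([1.0, self.sds[0]])
        else:
            p1 = min(max(self.weights[0], 1e-9), 1 - 1e-9)
            theta = np.array(
                [math.log(p1 / (1 - p1)), self.means[0], self.means[1],
                 math.log(self.sds[0]), math.log(self.sds[1])]
            )

            def negll(t):
                q = expit(t[0])
                return -mdl.loglike([q, 1 - q], [t[1], t[2]],
                                    [math.exp(t[3]), math.exp(t[4])])

            names = ["pi1", "mu1", "mu2", "sigma1", "sigma2"]
            jac = np.array([p1 * (1 - p1), 1.0, 1.0, self.sds[0], self.sds[1]])
        try:
            hess = approx_hess1(theta, negll)
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            if (var <= 0).any():
                raise np.linalg.LinAlgError
            se = np.sqrt(var) * np.abs(jac)
        except np.linalg.LinAlgError:
            se = np.full(len(theta), np.nan)
        return dict(zip(names, se))

    def summary(self) -> str:
        """Plain-text fit report in the Model/Results style."""
        se = self.standard_errors()
        lines = [
            "Histogram Gaussian mixture fit",
            "=" * 46,
            f"components      {self.k}",
            f"nuclei          {self.model.hist.n_cells}",
            f"log-likelihood  {self.loglik:.4f}",
            f"BIC             {self.bic:.4f}",
            f"iterations      {self.n_iter}   converged: {self.converged}",
            "-" * 46,
            f"{'comp':>4} {'weight':>8} {'mean':>8} {'sd':>8} {'se(mean)':>9}",
        ]
        for i in range(self.k):
            se_mu = se.get(f"mu{i + 1}", float("nan"))
            lines.append(
                f"{i + 1:>4} {self.weights[i]:>8.4f} {self.means[i]:>8.4f} "
                f"{self.sds[i]:>8.4f} {se_mu:>9.4f}"
            )
        lines.append("-" * 46)
        lines.append(f"mixture mean    {self.mixture_mean:.4f} copies")
        if self.degenerate:
            lines.append("warning: degenerate fit (single occupied bin)")
        return "\n".join(lines)

    def to_dict(self, include_trace: bool = False) -> dict:
        d = {
            "k": self.k,
            "weights": [float(v) for v in self.weights],
            "means": [float(v) for v in self.means],
            "sds": [float(v) for v in self.sds],
            "loglik": self.loglik,
            "bic": self.bic,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }
        if include_trace:
            d["loglik_trace"] = [float(v) for v in self.loglik_trace]
        return d

    def to_json(self, include_trace: bool = False) -> str:
        return json.dumps(self.to_dict(include_trace=include_trace), indent=2)


def fit_gmm(hist: SignalHistogram, k: int,
            options: FitOptions | None = None) -> HistogramGMMResults:
    """Functional shorthand for ``HistogramGMM(hist, k).fit(options)``."""
    return HistogramGMM(hist, k).fit(options)


@dataclass(frozen=True)
class ModelSelection:
    """Side-by-side one- and two-component fits and the BIC choice."""

    fit_k1: HistogramGMMResults
    fit_k2: HistogramGMMResults
    chosen_k: int

    @property
    def chosen(self) -> HistogramGMMResults:
        return self.fit_k2 if self.chosen_k == 2 else self.fit_k1


def select_components(hist: SignalHistogram, options: FitOptions | None = None,
                      pi_min: float = 0.10) -> ModelSelection:
    """Choose between mono- and biphasic fits.

    Two components are chosen iff BIC(k=2) < BIC(k=1) *and* both mixture
    weights are at least ``pi_min`` (a split that explains fewer than
    ``pi_min`` of the nuclei is not a subpopulation); ties favour the
    simpler model.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateFitWarning)
        f1 = fit_gmm(hist, 1, options)
        f2 = fit_gmm(hist, 2, options)
    chosen = 2 if (f2.bic < f1.bic and f2.weights.min() >= pi_min) else 1
    return ModelSelection(fit_k1=f1, fit_k2=f2, chosen_k=chosen)
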