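"""Contingency-table inference for the pCR association analysis.

Univariate associations between binary clinicopathological factors and
pathological complete response (pCR) are summarised by 2x2 odds ratios with
Woolf (log-odds) 95% confidence intervals,

    OR = ad / bc,    CI = exp( ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ),

together with Fisher's exact test (two-sided by the point-probability
method: the sum of hypergeometric probabilities of all tables, with the
observed margins, no more probable than the observed one) and Pearson's
chi-square test.  The multivariate analysis is a maximum-likelihood
logistic regression with Wald intervals (profile-likelihood intervals as a
fallback under separation).

Exposure convention: the first row of a table is the exposure of interest,
so ``odds_ratio_woolf`` returns odds(outcome | row 1) / odds(outcome | row 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "ORResult",
    "PCRRate",
    "pcr_rate",
    "odds_ratio_woolf",
    "fisher_exact",
    "chi_square",
    "multivariate_logistic",
    "build_table2",
    "Table2Report",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table: rows are exposure levels, columns outcome levels.

    Layout::

                    outcome+   outcome-
        exposure 1      a          b
        exposure 2      c          d
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("event", "no event")

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b,
                                (self.row_labels[1], self.row_labels[0]),
                                self.col_labels)

    def swap_cols(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c,
                                self.row_labels,
                                (self.col_labels[1], self.col_labels[0]))


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Woolf 95% CI and a two-sided Wald p-value.

    ``corrected`` marks the Haldane-Anscombe +0.5 continuity correction,
    applied only when the table contains a zero cell.
    """

    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False

    def rounded(self, sig: int = 3) -> tuple[float, float, float]:
        """(OR, lo, hi) at ``sig`` significant figures (report convention)."""
        def r(x: float) -> float:
            if x == 0 or not math.isfinite(x):
                return x
            return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
        return r(self.or_point), r(self.ci_low), r(self.ci_high)


class PCRRate(NamedTuple):
    """A pCR rate, raw and rounded to integer percent."""

    percent: float
    rounded: int


def pcr_rate(n_pcr: int, n_total: int) -> PCRRate:
    """pCR rate as a percentage, 100 * n_pcr / n_total."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_pcr <= n_total:
        raise ValueError("n_pcr must lie in [0, n_total]")
    pct = 100.0 * n_pcr / n_total
    return PCRRate(percent=pct, rounded=int(round(pct)))


def odds_ratio_woolf(t: ContingencyTable) -> ORResult:
    """Cross-product odds ratio with the Woolf log-scale 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ORResult(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        p_value=float(p),
        corrected=corrected,
    )


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, the first cell ``a`` determines the table; the
    two-sided p sums P(a') over every feasible a' whose point probability
    does not exceed the observed one (point-probability method).
    """
    row1, col1, n = t.a + t.b, t.a + t.c, t.n
    rv = sps.hypergeom(n, row1, col1)
    a_min = max(0, col1 - (n - row1))
    a_max = min(row1, col1)
    support = np.arange(a_min, a_max + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t.a)
    # relative slack guards against ties lost to floating-point noise
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def chi_square(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df), optional Yates."""
    obs = t.as_array().astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / t.n
    if (expected == 0).any():
        raise ValueError("chi-square undefined: zero expected cell count")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


# -- logistic regression ---------------------------------------------------


def _profile_ci(y: np.ndarray, X: pd.DataFrame, j: int,
                llmax: float, beta_hat: float) -> tuple[float, float]:
    """Profile-likelihood 95% CI for one coefficient via an offset refit."""
    import statsmodels.api as sm

    xj = X.iloc[:, j].to_numpy(dtype=float)
    rest = sm.add_constant(X.drop(columns=X.columns[j]), has_constant="add")
    crit = sps.chi2.ppf(0.95, 1) / 2.0

    def deficit(bj: float) -> float:
        model = sm.GLM(y, rest, family=sm.families.Binomial(), offset=bj * xj)
        fit = model.fit()
        return (llmax - fit.llf) - crit

    from scipy.optimize import brentq

    def bound(direction: int) -> float:
        step = 0.5
        lo = beta_hat
        for _ in range(60):
            hi = lo + direction * step
            if deficit(hi) > 0:
                return float(brentq(deficit, min(lo, hi), max(lo, hi), xtol=1e-6))
            lo = hi
            step *= 1.6
        return direction * math.inf

    return bound(-1), bound(+1)


def multivariate_logistic(data: pd.DataFrame, outcome: str,
                          covariates: list[str]) -> dict[str, ORResult]:
    """ML logistic regression of a binary outcome on 0/1-coded covariates.

    Returns one :class:`ORResult` per covariate (exp(beta) with Wald 95%
    CI and p).  Under (quasi-)separation the Wald interval degenerates;
    affected covariates are refit with profile-likelihood bounds and
    flagged via ``corrected=True``.
    """
    import statsmodels.api as sm

    y = data[outcome].to_numpy(dtype=float)
    X = data[covariates].astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    exog = sm.add_constant(X, has_constant="add")
    model_separated = False
    try:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
        llf = float(fit.llf)
    except Exception:
        # (quasi-)separation: the MLE diverges and the Hessian is singular.
        # A weak L1 penalty yields finite surrogate estimates; intervals
        # come from the profile likelihood and p-values from LR tests.
        model_separated = True
        reg = sm.Logit(y, exog).fit_regularized(method="l1", alpha=1e-4,
                                                disp=0, maxiter=500)
        params = pd.Series(np.asarray(reg.params).ravel(), index=exog.columns)
        bse = pd.Series(np.inf, index=exog.columns)
        pvalues = pd.Series(np.nan, index=exog.columns)
        llf = float(reg.llf)

    out: dict[str, ORResult] = {}
    for name in covariates:
        beta = float(params[name])
        se = float(bse[name])
        separated = (model_separated or not math.isfinite(se)
                     or se > 50 or abs(beta) > 15)
        if separated:
            j = list(X.columns).index(name)
            lo, hi = _profile_ci(y, X, j, llf, beta)
            reduced = sm.add_constant(X.drop(columns=[name]),
                                      has_constant="add")
            try:
                ll0 = float(sm.Logit(y, reduced).fit(disp=0, maxiter=200).llf)
                p = float(sps.chi2.sf(max(2.0 * (llf - ll0), 0.0), df=1))
            except Exception:
                p = math.nan
            out[name] = ORResult(math.exp(beta), math.exp(lo), math.exp(hi),
                                 p, corrected=True)
        else:
            out[name] = ORResult(
                or_point=math.exp(beta),
                ci_low=math.exp(beta - _Z95 * se),
                ci_high=math.exp(beta + _Z95 * se),
                p_value=float(pvalues[name]),
            )
    return out


# -- Table-2-style report --------------------------------------------------

#: (characteristic, column, exposure level, reference level) of each
#: univariate row; exposure-first so the OR sign matches the report layout.
_TABLE2_ROWS: list[tuple[str, str, str, str]] = [
    ("ER (positive vs negative)", "er", "positive", "negative"),
    ("PgR (positive vs negative)", "pgr", "positive", "negative"),
    ("Histological grade (3 vs 1-2)", "grade", "3", "1-2"),
    ("HER2 heterogeneity (high vs low)", "ith_label", "HH", "LH"),
]

#: multivariate indicator coding: column -> level coded 1
_TABLE2_INDICATORS: dict[str, tuple[str, str]] = {
    "er_pos": ("er", "positive"),
    "pgr_pos": ("pgr", "positive"),
    "hg3": ("grade", "3"),
    "hh": ("ith_label", "HH"),
}


def _level_mask(series: pd.Series, level: str) -> pd.Series:
    if level == "1-2":
        return series.astype(str).isin(["1", "2"])
    return series.astype(str) == level


@dataclass
class Table2Report:
    """Univariate and multivariate pCR association report.

    ``univariate`` has one row per characteristic with the 2x2 counts,
    rates, Woolf OR/CI, and Fisher/chi-square p-values; ``multivariate``
    holds the logistic-model ORs; ``flags`` collects degenerate or skipped
    rows.
    """

    total_n: int
    total_pcr: int
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def total_pcr_rate(self) -> PCRRate:
        return pcr_rate(self.total_pcr, self.total_n)

    def summary(self) -> str:
        lines = [
            "pCR association analysis",
            "=" * 72,
            f"total  n={self.total_n}  pCR={self.total_pcr} "
            f"({self.total_pcr_rate.rounded}%)",
            "-" * 72,
            "univariate (Woolf 95% CI):",
        ]
        for _, r in self.univariate.iterrows():
            lines.append(
                f"  {r['characteristic']:<34} OR {r['or']:>6.3g} "
                f"({r['ci_low']:.3g}-{r['ci_high']:.3g})  "
                f"fisher p={r['p_fisher']:.2g}"
            )
        if len(self.multivariate):
            lines.append("multivariate (logistic, Wald 95% CI):")
            for _, r in self.multivariate.iterrows():
                lines.append(
                    f"  {r['covariate']:<34} OR {r['or']:>6.3g} "
                    f"({r['ci_low']:.3g}-{r['ci_high']:.3g})  p={r['p']:.2g}"
                )
        for fl in self.flags:
            lines.append(f"note: {fl}")
        return "\n".join(lines)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "total": {"n": self.total_n, "pcr": self.total_pcr,
                          "pcr_rate": self.total_pcr_rate.percent},
                "univariate": self.univariate.to_dict(orient="records"),
                "multivariate": self.multivariate.to_dict(orient="records"),
                "flags": self.flags,
            },
            indent=2,
        )


def build_table2(labeled: pd.DataFrame, outcome: str = "pcr") -> Table2Report:
    """Assemble the univariate + multivariate pCR association report.

    ``labeled`` must carry the outcome column (0/1) plus er, pgr, grade
    and ith_label.  Characteristics with a missing column are skipped with
    a flag; rows with an empty exposure margin are reported with the
    Haldane-corrected OR and flagged degenerate.
    """
    flags: list[str] = []
    y = labeled[outcome].astype(int)
    uni_rows = []
    for name, col, exposure, reference in _TABLE2_ROWS:
        if col not in labeled.columns:
            flags.append(f"{name}: column {col!r} missing, row skipped")
            continue
        exp_mask = _level_mask(labeled[col], exposure)
        ref_mask = _level_mask(labeled[col], reference)
        a = int((exp_mask & (y == 1)).sum())
        b = int((exp_mask & (y == 0)).sum())
        c = int((ref_mask & (y == 1)).sum())
        d = int((ref_mask & (y == 0)).sum())
        if a + b == 0 or c + d == 0:
            flags.append(f"{name}: empty exposure margin, degenerate row")
        t = ContingencyTable(a, b, c, d, (exposure, reference),
                             ("pCR", "no pCR"))
        orr = odds_ratio_woolf(t)
        try:
            chi_stat, chi_p = chi_square(t)
        except ValueError:
            chi_stat, chi_p = math.nan, math.nan
        uni_rows.append({
            "characteristic": name,
            "n_exposed": a + b, "pcr_exposed": a,
            "rate_exposed": pcr_rate(a, a + b).percent if a + b else math.nan,
            "n_reference": c + d, "pcr_reference": c,
            "rate_reference": pcr_rate(c, c + d).percent if c + d else math.nan,
            "or": orr.or_point, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
            "p_wald": orr.p_value,
            "p_fisher": fisher_exact(t),
            "p_chi2": chi_p, "chi2_stat": chi_stat,
            "haldane_corrected": orr.corrected,
        })
    univariate = pd.DataFrame(uni_rows)

    indicators = {}
    for ind, (col, level) in _TABLE2_INDICATORS.items():
        if col in labeled.columns:
            indicators[ind] = _level_mask(labeled[col], level).astype(int)
    multi_rows = []
    if len(indicators) >= 2:
        data = pd.DataFrame(indicators)
        data[outcome] = y.to_numpy()
        usable = [c for c in indicators if data[c].nunique() > 1]
        dropped = sorted(set(indicators) - set(usable))
        for c in dropped:
            flags.append(f"multivariate: covariate {c!r} constant, dropped")
        if len(usable) >= 1:
            results = multivariate_logistic(data, outcome, usable)
            for cov in usable:
                r = results[cov]
                multi_rows.append({
                    "covariate": cov, "or": r.or_point,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "p": r.p_value, "profile_ci": r.corrected,
                })
    multivariate = pd.DataFrame(
        multi_rows, columns=["covariate", "or", "ci_low", "ci_high", "p",
                             "profile_ci"])
    return Table2Report(
        total_n=int(len(labeled)),
        total_pcr=int(y.sum()),
        univariate=univariate,
        multivariate=multivariate,
        flags=flags,
    )
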