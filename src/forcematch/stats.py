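"""Statistical tests and the standardized clinical regression.

Conventions, chosen once and used throughout:

* every p-value is two-tailed;
* group comparisons with very unequal sample sizes use the Mann-Whitney
  rank test reported as a tie-corrected normal-approximation Z (an exact
  enumeration method is available for small samples);
* the 2x2 chi-square uses no continuity correction (a Yates option
  exists but is off by default);
* the one-sample Kolmogorov-Smirnov normality test plugs in the sample
  mean and SD and uses scipy's small-sample (exact) null distribution of
  D; no Lilliefors correction for the estimated parameters is applied, a
  caveat documented in the methods note;
* the standardized regression z-scales the dependent variable together
  with every predictor (ddof=1) before an OLS fit with intercept.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
)

__all__ = [
    "TestResult",
    "RegressionResult",
    "rank_test",
    "t_test",
    "ks_normality",
    "chi_square_2x2",
    "pearson_r",
    "bonferroni",
    "standardized_regression",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic_name: str  # "Z", "t", "D", "chi2", "r", "F"
    statistic: float
    p: float
    df: float | tuple | None = None
    n: tuple | None = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p": self.p,
            "df": self.df,
            "n": self.n,
            "correction": self.correction,
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class RegressionResult:
    """Standardized multiple-regression fit."""

    name: str
    coefficients: pd.DataFrame  # index: predictor; beta, se, t, p, role
    f_statistic: float
    f_p: float
    df_model: int
    df_resid: int
    r_squared: float
    adj_r_squared: float
    n: int

    def beta(self, predictor: str) -> float:
        return float(self.coefficients.loc[predictor, "beta"])

    def t(self, predictor: str) -> float:
        return float(self.coefficients.loc[predictor, "t"])

    def p(self, predictor: str) -> float:
        return float(self.coefficients.loc[predictor, "p"])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficients": {
                str(k): {
                    "beta": float(r["beta"]),
                    "se": float(r["se"]),
                    "t": float(r["t"]),
                    "p": float(r["p"]),
                    "role": str(r["role"]),
                }
                for k, r in self.coefficients.iterrows()
            },
            "F": self.f_statistic,
            "F_p": self.f_p,
            "df": [self.df_model, self.df_resid],
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "n": self.n,
        }


def _two_tailed_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def rank_test(
    x,
    y=None,
    *,
    kind: str = "mann_whitney",
    mu: float = 0.0,
    method: str = "normal",
    name: str | None = None,
) -> TestResult:
    """Mann-Whitney U test or Wilcoxon signed-rank test.

    Reported as a Z statistic from the tie-corrected normal approximation
    (no continuity correction), with Z > 0 when the first sample ranks
    higher (Mann-Whitney) or when the differences are predominantly
    positive (Wilcoxon).  ``method="exact"`` replaces the p-value with an
    exact enumeration over rank assignments / sign patterns, feasible for
    small samples.

    For the Wilcoxon test, ``y`` may be a paired sample or ``None`` to
    test ``x`` against the null value ``mu``.
    """
    x = np.asarray(x, dtype=float)
    if kind == "mann_whitney":
        if y is None:
            raise InvalidArgumentError("mann_whitney requires two samples")
        y = np.asarray(y, dtype=float)
        if x.size < 2 or y.size < 2:
            raise InvalidArgumentError("need >= 2 observations per sample")
        n1, n2 = x.size, y.size
        big_n = n1 + n2
        u1 = _mann_whitney_u(x, y)
        mean_u = n1 * n2 / 2.0
        tie = _tie_term(np.concatenate([x, y]))
        var_u = n1 * n2 / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
        if var_u <= 0:
            raise DegenerateInputError("all pooled observations are tied")
        z = (u1 - mean_u) / math.sqrt(var_u)
        p = _two_tailed_normal_p(z)
        if method == "exact":
            p = _exact_mann_whitney_p(x, y)
        return TestResult(
            name=name or "mann_whitney",
            statistic_name="Z",
            statistic=float(z),
            p=p,
            n=(n1, n2),
            extra={"U": u1, "method": method},
        )

    if kind == "wilcoxon_signed_rank":
        d = x - (mu if y is None else np.asarray(y, dtype=float))
        d = d[d != 0.0]
        if d.size == 0:
            raise DegenerateInputError("all differences are zero")
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        n = d.size
        mean_w = n * (n + 1) / 4.0
        tie = _tie_term(np.abs(d))
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
        if var_w <= 0:
            raise DegenerateInputError("signed-rank variance is zero")
        z = (w_plus - mean_w) / math.sqrt(var_w)
        p = _two_tailed_normal_p(z)
        if method == "exact":
            p = _exact_wilcoxon_p(ranks, d, mean_w)
        return TestResult(
            name=name or "wilcoxon_signed_rank",
            statistic_name="Z",
            statistic=float(z),
            p=p,
            n=(n,),
            extra={"W_plus": w_plus, "method": method},
        )

    raise InvalidArgumentError(
        "kind must be 'mann_whitney' or 'wilcoxon_signed_rank'"
    )


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-tailed p by full enumeration of rank assignments.

    Enumerates all C(n1+n2, n1) splits of the pooled sample and counts
    U statistics at least as far from the null mean as observed.
    Intended for n1 + n2 <= ~16.
    """
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = sps.rankdata(pooled)
    obs = abs(_mann_whitney_u(x, y) - n1 * y.size / 2.0)
    offset = n1 * (n1 + 1) / 2.0 + n1 * y.size / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(pooled.size), n1):
        u_dev = abs(ranks[list(comb)].sum() - offset)
        total += 1
        if u_dev >= obs - 1e-12:
            count += 1
    return count / total


def _exact_wilcoxon_p(ranks: np.ndarray, d: np.ndarray, mean_w: float) -> float:
    """Exact two-tailed p over all 2^n sign patterns of the observed
    absolute ranks.  Intended for n <= ~16."""
    obs = abs(float(ranks[d > 0].sum()) - mean_w)
    n = ranks.size
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        w = float(ranks[np.fromiter(signs, bool, n)].sum())
        if abs(w - mean_w) >= obs - 1e-12:
            count += 1
    return count / 2**n


def t_test(
    x,
    y=None,
    *,
    mu: float = 0.0,
    mode: str = "one_sample",
    name: str | None = None,
) -> TestResult:
    """One-sample or paired Student t test with df = n - 1."""
    x = np.asarray(x, dtype=float)
    if mode == "paired":
        if y is None:
            raise InvalidArgumentError("paired mode requires a second sample")
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise InvalidArgumentError("paired samples must have equal length")
        d = x - y
    elif mode == "one_sample":
        d = x - mu
    else:
        raise InvalidArgumentError("mode must be 'one_sample' or 'paired'")
    n = d.size
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    s = d.std(ddof=1)
    if s == 0.0:
        raise DegenerateInputError("zero variance: t statistic undefined")
    t = float(d.mean() / (s / math.sqrt(n)))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 1)))
    return TestResult(
        name=name or f"t_{mode}",
        statistic_name="t",
        statistic=t,
        p=p,
        df=n - 1,
        n=(n,),
    )


def ks_normality(x, *, name: str | None = None) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(mean(x), sd(x)).

    The reference normal uses the sample mean and SD (ddof=1); the p-value
    comes from scipy's one-sample KS null (exact for small n).  Because the
    parameters are estimated from the same data the test is conservative
    (the Lilliefors-corrected p would be smaller); this matches the
    conventional reporting of the analysis this package reproduces.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InvalidArgumentError("need n >= 4")
    s = x.std(ddof=1)
    if s == 0.0:
        raise DegenerateInputError("constant sample")
    res = sps.kstest(x, "norm", args=(x.mean(), s))
    return TestResult(
        name=name or "ks_normality",
        statistic_name="D",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=(x.size,),
    )


def chi_square_2x2(
    a: float,
    b: float,
    c: float,
    d: float,
    *,
    yates: bool = False,
    name: str | None = None,
) -> TestResult:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default; set ``yates=True`` for the Yates
    correction.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise InvalidArgumentError("cell counts must be >= 0")
    n = cells.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise DegenerateInputError("a table margin is zero")
    expected = np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / n
    dev = np.abs(cells - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(
        name=name or "chi_square_2x2",
        statistic_name="chi2",
        statistic=chi2,
        p=p,
        df=1,
        n=(int(n),),
        correction="yates" if yates else "none",
    )


def pearson_r(x, y, *, name: str | None = None) -> TestResult:
    """Pearson product-moment correlation; two-tailed p via the t
    transform with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need two aligned samples with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateInputError("zero variance in one sample")
    res = sps.pearsonr(x, y)
    return TestResult(
        name=name or "pearson_r",
        statistic_name="r",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=x.size - 2,
        n=(x.size,),
    )


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: multiply each p by the family size, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise InvalidArgumentError("family size m must be >= number of p-values")
    return np.minimum(p * m_eff, 1.0)


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s == 0.0:
        raise DegenerateInputError("cannot z-scale a constant variable")
    return (v - v.mean()) / s


def standardized_regression(
    dependent,
    predictors: pd.DataFrame,
    *,
    roles: dict | None = None,
    name: str | None = None,
) -> RegressionResult:
    """Multiple regression with every variable Z-scaled before the fit.

    ``predictors`` is a DataFrame with one named column per predictor;
    ``roles`` optionally labels each as ``"of_interest"`` or ``"nuisance"``
    (metadata only — all predictors enter the model identically).  The fit
    is OLS with an intercept on the standardized variables; per-coefficient
    t statistics have df = n - k - 1.

    Raises :class:`CollinearityError` naming the offending columns when the
    standardized design is rank-deficient.
    """
    import statsmodels.api as sm

    y = np.asarray(dependent, dtype=float)
    X = predictors.astype(float)
    n, k = X.shape
    if n != y.size:
        raise InvalidArgumentError("dependent and predictors must align")
    if n <= k + 1:
        raise InvalidArgumentError("need n > number of predictors + 1")

    yz = _zscore(y)
    Xz = pd.DataFrame(
        {col: _zscore(X[col].to_numpy()) for col in X.columns}, index=X.index
    )
    rank = np.linalg.matrix_rank(Xz.to_numpy())
    if rank < k:
        offenders = []
        for col in X.columns:
            others = [c for c in X.columns if c != col]
            if not others:
                continue
            r2 = (
                sm.OLS(Xz[col].to_numpy(), sm.add_constant(Xz[others].to_numpy()))
                .fit()
                .rsquared
            )
            if r2 > 1.0 - 1e-10:
                offenders.append(str(col))
        raise CollinearityError(
            f"exactly collinear predictors: {offenders}", tuple(offenders)
        )

    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    roles = roles or {}
    coef = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
            "role": [roles.get(str(c), "of_interest") for c in X.columns],
        },
        index=[str(c) for c in X.columns],
    )
    return RegressionResult(
        name=name or "standardized_regression",
        coefficients=coef,
        f_statistic=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
    )
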