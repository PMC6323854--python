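"""Two-arm hypothesis tests: Pearson and Rao-Scott chi-square, Welch t, NB2 regression.

The unweighted arm comparisons use the ordinary Pearson chi-square.  When
one arm carries inverse-degree weights and chain clustering, the naive
chi-square is anticonservative; the first-order Rao-Scott correction divides
the Pearson statistic by an estimated mean generalised design effect d̂
(ratio of design-based to simple-random-sampling variance, averaged over
cells).  Network-size comparisons use Welch's t-test and a log-link
negative binomial (NB2) regression fitted by maximum likelihood in-package
so the iteration trace is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    ClusteringError,
    InputError,
    VarianceEstimationError,
)
from .estimators import WeightVector, _cluster_variance


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    correction: str = "none"
    design_effect: float | None = None
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "correction": self.correction,
            "design_effect": self.design_effect,
        }


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError(f"need an r x c table with r, c >= 2, got {table.shape}")
    if np.any(table < 0):
        raise InputError("table entries must be non-negative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise InputError("degenerate table: a row or column marginal is zero")
    return table


def _pearson_statistic(table: np.ndarray, continuity: bool = False) -> tuple[float, float]:
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    dev = np.abs(table - expected)
    if continuity:
        if table.shape != (2, 2):
            raise InputError("continuity adjustment applies to 2x2 tables only")
        dev = np.clip(dev - 0.5, 0.0, None)
    x2 = float(np.sum(dev**2 / expected))
    df = float((table.shape[0] - 1) * (table.shape[1] - 1))
    return x2, df


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    X² = Σ (O - E)² / E with E from the product of the marginals; df =
    (r-1)(c-1); p from the chi-square upper tail.  All row and column
    marginals must be positive.
    """
    table = _validate_table(table)
    x2, df = _pearson_statistic(table)
    return TestResult(
        statistic=x2,
        df=df,
        p_value=float(stats.chi2.sf(x2, df)),
        correction="none",
        name="pearson_chi2",
    )


def estimate_design_effect(
    values: dict[str, str], weights: WeightVector
) -> float:
    """Mean generalised design effect d̂ of the weighted categorical estimates.

    For each category, the design-based variance of the weighted prevalence
    (chain-clustered Taylor linearisation) is divided by the variance
    p(1-p)/(n-1) of the analogous with-replacement simple-random-sample
    estimator; d̂ is the mean over non-degenerate categories.  With equal
    weights and every unit its own cluster this is exactly 1 (up to
    floating point), the self-representing design.
    """
    if weights.chains is None:
        raise ClusteringError("weights carry no chain ids")
    chains = dict(weights.chains)
    if len(set(chains.values())) < 2:
        raise ClusteringError("need >= 2 clusters to estimate a design effect")
    n = len(weights)
    cats = sorted(set(values[pid] for pid in weights.weights))
    deffs = []
    for c in cats:
        p = sum(w for pid, w in weights.weights.items() if values[pid] == c)
        if p <= 0.0 or p >= 1.0:
            continue
        residuals = {
            pid: w * ((1.0 if values[pid] == c else 0.0) - p)
            for pid, w in weights.weights.items()
        }
        v_design = _cluster_variance(residuals, chains)
        v_srs = p * (1 - p) / (n - 1)
        deffs.append(v_design / v_srs)
    if not deffs:
        raise VarianceEstimationError("no non-degenerate category for d̂")
    dhat = float(np.mean(deffs))
    if dhat <= 0:
        raise VarianceEstimationError(f"estimated design effect {dhat} <= 0")
    return dhat


def rao_scott_chi2(
    table,
    design_effect: float | None = None,
    values: dict[str, str] | None = None,
    weights: WeightVector | None = None,
    continuity: bool = False,
) -> TestResult:
    """First-order Rao-Scott corrected chi-square for weighted/clustered data.

    ``table`` holds the weighted-estimate-scaled counts (each arm's
    prevalences multiplied by its sample size).  The Pearson statistic —
    with an optional Yates-style continuity adjustment on 2x2 tables — is
    divided by d̂, either supplied directly or estimated from the weighted
    arm's ``values`` and ``weights``; df is unchanged.  With d̂ = 1 and no
    continuity adjustment the result equals :func:`pearson_chi2` exactly.
    """
    table = _validate_table(table)
    if design_effect is None:
        if values is None or weights is None:
            raise InputError("supply design_effect or (values, weights)")
        design_effect = estimate_design_effect(values, weights)
    if design_effect <= 0:
        raise VarianceEstimationError(f"design effect must be > 0, got {design_effect}")
    x2, df = _pearson_statistic(table, continuity=continuity)
    stat = x2 / design_effect
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        correction="rao_scott_continuity" if continuity else "rao_scott",
        design_effect=design_effect,
        name="rao_scott_chi2",
    )


def welch_t_test(a, b, equal_var: bool = False) -> TestResult:
    """Two-sided t-test, Welch (Satterthwaite df) by default.

    A pooled-variance option is retained for sensitivity checks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each sample needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, df=float(a.size + b.size - 2),
                              p_value=1.0, name="t_test")
        raise InputError("both samples are constant with different means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        name="t_test" if equal_var else "welch_t_test",
    )


# ---------------------------------------------------------------------------
# negative binomial (NB2) regression


@dataclass
class NegBinResult:
    """Fit of y ~ intercept + group under a log-link NB2 model."""

    coefficient: float
    se: float
    p_value: float
    intercept: float
    alpha: float
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


def _nb2_loglik(y, mu, alpha, w) -> float:
    # NB2: Var(y) = mu + alpha * mu^2; alpha -> 0 recovers Poisson
    a = max(alpha, 1e-12)
    inv = 1.0 / a
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1.0)
        + inv * np.log(inv / (inv + mu))
        + y * np.log(mu / (inv + mu))
    )
    return float(np.sum(w * ll))


def negbin_regression(
    y,
    group,
    weights=None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> NegBinResult:
    """Maximum-likelihood NB2 regression of counts on a binary group indicator.

    Alternates Fisher-scoring steps for the coefficients (with step-halving,
    so the log-likelihood never decreases along the trace) with a bounded
    one-dimensional update of the dispersion alpha, until the log-likelihood
    change falls below ``tol``.  Returns the group coefficient (a log rate
    ratio), its SE from the expected information, and the Wald p-value.
    Optional non-negative observation ``weights`` enter as frequency-style
    weights on the likelihood.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if y.shape != group.shape or y.ndim != 1:
        raise InputError("y and group must be 1-D arrays of equal length")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise InputError("y must be non-negative integer counts")
    if np.all(y == 0):
        raise InputError("all counts are zero; the model is undefined")
    levels = np.unique(group)
    if levels.size != 2:
        raise InputError(f"group must be binary, got levels {levels}")
    group = (group == levels[1]).astype(float)
    if np.sum(group == 0) < 10 or np.sum(group == 1) < 10:
        raise InputError("need >= 10 observations per group")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.shape != y.shape:
        raise InputError("weights must be non-negative and match y")

    X = np.column_stack([np.ones_like(y), group])
    # moment start: log means per group, method-of-moments alpha
    beta = np.array(
        [
            np.log(max(np.average(y[group == 0], weights=w[group == 0]), 1e-3)),
            0.0,
        ]
    )
    beta[1] = (
        np.log(max(np.average(y[group == 1], weights=w[group == 1]), 1e-3)) - beta[0]
    )
    mu = np.exp(X @ beta)
    resid = np.average((y - mu) ** 2 - mu, weights=w)
    alpha = max(resid / max(np.average(mu**2, weights=w), 1e-12), 1e-6)

    trace = [_nb2_loglik(y, mu, alpha, w)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Fisher scoring for beta at fixed alpha, with step-halving
        mu = np.exp(X @ beta)
        score = X.T @ (w * (y - mu) / (1.0 + alpha * mu))
        info_w = w * mu / (1.0 + alpha * mu)
        info = X.T @ (info_w[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise VarianceEstimationError("singular information matrix") from exc
        ll_old = _nb2_loglik(y, mu, alpha, w)
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _nb2_loglik(y, np.exp(X @ cand), alpha, w)
            if ll_new >= ll_old - 1e-12:
                beta = cand
                break
            scale *= 0.5
        mu = np.exp(X @ beta)

        # bounded 1-D dispersion update on log(alpha)
        res = optimize.minimize_scalar(
            lambda la: -_nb2_loglik(y, mu, np.exp(la), w),
            bounds=(np.log(1e-10), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        cand_alpha = float(np.exp(res.x))
        if _nb2_loglik(y, mu, cand_alpha, w) >= _nb2_loglik(y, mu, alpha, w):
            alpha = cand_alpha

        trace.append(_nb2_loglik(y, mu, alpha, w))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        from .errors import ConvergenceError

        raise ConvergenceError(
            f"NB2 fit did not converge in {max_iter} iterations", trace=trace
        )

    info_w = w * mu / (1.0 + alpha * mu)
    info = X.T @ (info_w[:, None] * X)
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    zstat = beta[1] / se
    return NegBinResult(
        coefficient=float(beta[1]),
        se=se,
        p_value=float(2 * stats.norm.sf(abs(zstat))),
        intercept=float(beta[0]),
        alpha=float(alpha),
        loglik=trace[-1],
        loglik_trace=trace,
        n_iter=it,
        converged=True,
    )
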