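"""Point and interval estimation for the two survey arms.

Registry-arm (PR) categorical variables are summarised as unweighted
proportions with exact Clopper-Pearson binomial intervals.  RDS-arm
variables are additionally summarised with the inverse-reported-degree
(Volz-Heckathorn-type) weighted prevalence: participant i with reported
network size d_i receives weight w_i ∝ 1/d_i, offsetting the degree-biased
inclusion of a network-driven sample.  Variances for the weighted estimates
use Taylor linearisation of the ratio estimator with clustering at the
recruitment-chain (seed) level, and intervals are built on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import (
    ClusteringError,
    CompletenessError,
    InputError,
    WeightError,
)


@dataclass
class ProportionEstimate:
    """Point estimate + interval for one category, on the percent scale."""

    category: str
    x: int | None
    n: int
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    method: str = "unweighted_exact"
    se: float | None = None

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "x": self.x,
            "n": self.n,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method,
            "se": self.se,
        }


@dataclass
class WeightVector:
    """Normalised inverse-degree weights with chain ids for clustering."""

    weights: dict[str, float]
    chains: dict[str, str] | None = None

    def __len__(self) -> int:
        return len(self.weights)


def format_percent(value: float) -> str:
    """Render a percentage to one decimal, rounding half up (table style)."""
    return str(Decimal(repr(float(value))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def proportion(x: int, n: int) -> float:
    """100 * x / n.  Full precision; use :func:`format_percent` for tables."""
    if n <= 0:
        raise InputError(f"denominator must be positive, got n={n}")
    if not 0 <= x <= n:
        raise InputError(f"need 0 <= x <= n, got x={x}, n={n}")
    return 100.0 * x / n


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, percent scale.

    Beta-quantile form: lower = Beta(x, n-x+1) quantile at alpha/2, upper =
    Beta(x+1, n-x) quantile at 1-alpha/2; the lower bound is 0 when x=0 and
    the upper 100 when x=n.  Guarantees at-least-nominal coverage.
    """
    if n <= 0 or not 0 <= x <= n:
        raise InputError(f"need 0 <= x <= n, n > 0; got x={x}, n={n}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    hi = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return 100.0 * lo, 100.0 * hi


def unweighted_estimate(
    category: str, x: int, n: int, level: float = 0.95
) -> ProportionEstimate:
    lo, hi = clopper_pearson_ci(x, n, level)
    return ProportionEstimate(
        category=category,
        x=x,
        n=n,
        estimate=proportion(x, n),
        ci_low=lo,
        ci_high=hi,
        level=level,
        method="unweighted_exact",
    )


def rds_weights(
    degrees: dict[str, int],
    chains: dict[str, str] | None = None,
    cap: int | None = None,
) -> WeightVector:
    """Inverse-degree weights w_i ∝ 1/d_i, normalised to sum to 1.

    Participants with larger reported network size get smaller weights.
    ``cap`` (off by default) truncates degrees at a maximum before
    inversion, limiting the influence of implausibly small weights.
    """
    if not degrees:
        raise InputError("no degrees supplied")
    raw = {}
    for pid, d in degrees.items():
        if d is None or d < 1:
            raise WeightError(f"invalid degree {d!r} for participant {pid!r}")
        eff = min(d, cap) if cap is not None else d
        raw[pid] = 1.0 / eff
    total = sum(raw.values())
    weights = {pid: w / total for pid, w in raw.items()}
    if chains is not None:
        missing = set(weights) - set(chains)
        if missing:
            raise WeightError(f"no chain id for participants: {sorted(missing)}")
        chains = {pid: chains[pid] for pid in weights}
    return WeightVector(weights=weights, chains=chains)


def _check_values(values: dict[str, str], wv: WeightVector) -> None:
    missing = [pid for pid in wv.weights if pid not in values]
    if missing:
        raise CompletenessError(
            f"weighted participants without a value: {sorted(missing)}"
        )


def rds_weighted_proportion(
    values: dict[str, str], weights: WeightVector
) -> dict[str, ProportionEstimate]:
    """Weighted prevalence per category: 100 * Σ_{i: value=c} w_i.

    Extends the inverse-degree binary estimator to multi-category variables;
    the estimates sum to 100 over categories.  With all-equal degrees this
    reduces exactly to the unweighted proportion.
    """
    _check_values(values, weights)
    n = len(weights)
    est: dict[str, float] = {}
    xs: dict[str, int] = {}
    for pid, w in weights.weights.items():
        c = values[pid]
        est[c] = est.get(c, 0.0) + w
        xs[c] = xs.get(c, 0) + 1
    ws = list(weights.weights.values())
    if min(ws) == max(ws):
        # equal weights: the degrees cancel algebraically, so report the
        # exact unweighted proportion rather than its rounded accumulation
        percent = {c: proportion(xs[c], n) for c in est}
    else:
        # clamp: accumulated weights can overshoot [0, 1] by a few ulps
        percent = {c: min(max(100.0 * est[c], 0.0), 100.0) for c in est}
    return {
        c: ProportionEstimate(
            category=c, x=xs[c], n=n, estimate=percent[c], method="rds_weighted"
        )
        for c in sorted(est)
    }


def _cluster_variance(
    residuals: dict[str, float], chains: dict[str, str]
) -> float:
    """With-replacement cluster-total variance of a linearised estimator.

    ``residuals`` are the per-unit linearised contributions u_i (they sum to
    ~0 by construction); the variance is m/(m-1) * Σ_c U_c² over cluster
    totals U_c, the standard first-stage linearisation for a clustered
    design.
    """
    totals: dict[str, float] = {}
    for pid, u in residuals.items():
        c = chains[pid]
        totals[c] = totals.get(c, 0.0) + u
    m = len(totals)
    if m < 2:
        raise ClusteringError(f"need >= 2 chains for clustered variance, got {m}")
    vals = np.array(list(totals.values()))
    center = vals.mean()
    return float(m / (m - 1) * np.sum((vals - center) ** 2))


def _require_clusterable(wv: WeightVector) -> dict[str, str]:
    if wv.chains is None:
        raise ClusteringError("weights carry no chain ids")
    sizes: dict[str, int] = {}
    for pid in wv.weights:
        sizes[wv.chains[pid]] = sizes.get(wv.chains[pid], 0) + 1
    if len(sizes) < 2:
        raise ClusteringError(f"need >= 2 chains, got {len(sizes)}")
    singletons = sorted(c for c, k in sizes.items() if k < 2)
    if singletons:
        raise ClusteringError(
            f"chains with a single member must be filtered upstream: {singletons}"
        )
    return dict(wv.chains)


def rds_weighted_ci(
    values: dict[str, str],
    weights: WeightVector,
    level: float = 0.95,
) -> dict[str, ProportionEstimate]:
    """Weighted prevalences with chain-clustered linearised intervals.

    The variance of the ratio estimator p̂ = Σ w_i 1{value_i=c} / Σ w_i is
    estimated by Taylor linearisation (u_i = w_i (y_i - p̂)) with clustering
    at the chain level; the interval is symmetric on the logit scale and
    back-transformed, truncated to [0, 100].  Degenerate categories (p̂ of
    0 or 1, or zero variance) collapse to a point interval.
    """
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    chains = _require_clusterable(weights)
    estimates = rds_weighted_proportion(values, weights)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    for c, pe in estimates.items():
        p = pe.estimate / 100.0
        residuals = {
            pid: w * ((1.0 if values[pid] == c else 0.0) - p)
            for pid, w in weights.weights.items()
        }
        var = _cluster_variance(residuals, chains)
        se = float(np.sqrt(var))
        pe.level = level
        pe.se = 100.0 * se
        if se == 0.0 or p <= 0.0 or p >= 1.0:
            pe.ci_low, pe.ci_high = pe.estimate, pe.estimate
            continue
        logit = np.log(p / (1 - p))
        se_logit = se / (p * (1 - p))
        lo = 1.0 / (1.0 + np.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + np.exp(-(logit + z * se_logit)))
        pe.ci_low = float(np.clip(100 * lo, 0, 100))
        pe.ci_high = float(np.clip(100 * hi, 0, 100))
    return estimates


def weighted_mean_se(
    values: dict[str, float], weights: WeightVector
) -> tuple[float, float]:
    """Hájek-style weighted mean Σ w_i y_i / Σ w_i with linearised SE.

    Clustered at the chain level when chain ids are present (and usable);
    otherwise each unit is its own cluster.
    """
    if not weights.weights:
        raise InputError("empty weight vector")
    missing = [pid for pid in weights.weights if pid not in values]
    if missing:
        raise CompletenessError(f"no value for participants: {sorted(missing)}")
    w = np.array([weights.weights[pid] for pid in weights.weights])
    y = np.array([float(values[pid]) for pid in weights.weights], dtype=float)
    mean = float(np.sum(w * y) / np.sum(w))
    residuals = {
        pid: weights.weights[pid] * (float(values[pid]) - mean)
        for pid in weights.weights
    }
    if weights.chains is not None and len(set(weights.chains.values())) >= 2:
        var = _cluster_variance(residuals, weights.chains)
    else:
        var = _cluster_variance(residuals, {pid: pid for pid in residuals})
    return mean, float(np.sqrt(var))
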