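"""Diagnostic-accuracy statistics with cluster-stratified BC bootstrap CIs.

The evaluation reports sensitivity, specificity and false-detection rates at
neonate and hour level, and between-group differences.  Randomisation was
stratified by hospital and hour-level outcomes cluster within neonates, so
confidence intervals come from a bias-corrected (BC) percentile bootstrap
that resamples neonates with replacement within group x hospital clusters,
preserving each cluster's size.

The BC interval: with point estimate t computed on the original data and
bootstrap replicates t*_1..t*_B, the bias-correction constant is
z0 = Phi^-1(b/B) where b counts replicates below t (ties counted half); the
interval endpoints are the bootstrap-distribution quantiles at
Phi(2*z0 + z_{alpha/2}) and Phi(2*z0 + z_{1-alpha/2}).  No acceleration
constant is used (BC, not BCa).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "AccuracyResult",
    "BootstrapConfig",
    "InteractionResult",
    "EstimationError",
    "sensitivity",
    "specificity",
    "false_detection_rate",
    "hour_sensitivity",
    "form_false_detection_rate",
    "round_pct",
    "bc_bootstrap_ci",
    "difference_ci",
    "interaction_test",
    "required_group_size",
    "required_seizure_neonates",
]

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """Raised when a statistic or its bootstrap distribution is undefined."""


@dataclass(frozen=True)
class AccuracyResult:
    """A point estimate with a bias-corrected bootstrap confidence interval."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    n_numerator: int | None = None
    n_denominator: int | None = None
    n_boot: int = 0
    n_undefined: int = 0


@dataclass(frozen=True)
class BootstrapConfig:
    """Configuration of the cluster-stratified BC bootstrap."""

    n_iter: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    cluster_cols: tuple[str, ...] = ("group", "hospital")

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class InteractionResult:
    """Logistic-regression interaction fit for a post-hoc 2x2 contrast."""

    coefficients: dict
    interaction_p: float
    converged: bool
    notes: str = (
        "hours modelled as independent observations; within-infant "
        "clustering of hours is not adjusted for"
    )


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def _ratio_pct(num: float, den: float) -> float | None:
    """100*num/den, or None when the denominator is empty (undefined metric)."""
    if den == 0:
        return None
    return 100.0 * num / den


def sensitivity(tp: int, fn: int) -> float | None:
    """Percentage of gold seizure neonates the clinical team identified."""
    return _ratio_pct(tp, tp + fn)


def specificity(tn: int, fp: int) -> float | None:
    """Percentage of non-seizure neonates correctly classified negative."""
    return _ratio_pct(tn, tn + fp)


def false_detection_rate(fp: int, tp: int) -> float | None:
    """Percentage of clinically positive neonates who had no seizures."""
    return _ratio_pct(fp, fp + tp)


def hour_sensitivity(n_identified: int, n_gold: int) -> float | None:
    """Percentage of gold seizure hours identified by the clinical team."""
    return _ratio_pct(n_identified, n_gold)


def form_false_detection_rate(n_false: int, n_marked: int) -> float | None:
    """Percentage of form-marked hours with no seizure in that hour or the hour before."""
    return _ratio_pct(n_false, n_marked)


def round_pct(x: float | None, ndigits: int = 1) -> float | None:
    """Half-up decimal rounding for reported percentages (presentation only)."""
    if x is None:
        return None
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# BC cluster bootstrap
# ---------------------------------------------------------------------------

def _cluster_indices(
    data: pd.DataFrame, cluster_cols: Sequence[str]
) -> list[np.ndarray]:
    cols = [c for c in cluster_cols if c in data.columns]
    if not cols:
        return [np.arange(len(data))]
    groups = data.groupby(list(cols), sort=True, observed=True).indices
    return [np.asarray(groups[k]) for k in sorted(groups)]


def _resample(
    rng: np.random.Generator, clusters: list[np.ndarray]
) -> np.ndarray:
    """One stratified resample: each cluster redrawn with replacement, size kept."""
    parts = [idx[rng.integers(0, len(idx), size=len(idx))] for idx in clusters]
    return np.concatenate(parts)


def _enumerate_resamples(clusters: list[np.ndarray]) -> list[np.ndarray]:
    """All equally likely stratified resamples (tiny clusters only)."""
    total = 1
    for idx in clusters:
        total *= len(idx) ** len(idx)
        if total > 200_000:
            raise ValueError("exhaustive enumeration infeasible for this cohort size")
    per_cluster = [
        [np.asarray(c) for c in itertools.product(idx, repeat=len(idx))]
        for idx in clusters
    ]
    return [np.concatenate(combo) for combo in itertools.product(*per_cluster)]


def _bc_interval(
    theta: float, boot: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Bias-corrected percentile interval from a bootstrap distribution."""
    B = len(boot)
    b = np.sum(boot < theta) + 0.5 * np.sum(boot == theta)
    p = b / B
    lo_p, hi_p = 1.0 / (B + 1), B / (B + 1.0)
    if p <= lo_p or p >= hi_p:
        logger.warning(
            "bias-correction fraction %.4f clamped to [%.4f, %.4f]", p, lo_p, hi_p
        )
        p = min(max(p, lo_p), hi_p)
    z0 = norm.ppf(p)
    a1 = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    a2 = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(boot, [a1, a2])
    return float(lo), float(hi)


def _collect_boot(
    stat_of_idx: Callable[[np.ndarray], float | None],
    clusters: list[np.ndarray],
    config: BootstrapConfig,
    exhaustive: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    if exhaustive:
        samples = _enumerate_resamples(clusters)
    else:
        samples = (_resample(rng, clusters) for _ in range(config.n_iter))
    vals: list[float] = []
    n_undef = 0
    for idx in samples:
        v = stat_of_idx(idx)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_undef += 1
        else:
            vals.append(float(v))
    if not vals:
        raise EstimationError("statistic undefined on every bootstrap resample")
    if n_undef:
        logger.warning("dropped %d undefined bootstrap replicates", n_undef)
    return np.asarray(vals), n_undef


def bc_bootstrap_ci(
    stat_fn: Callable[[pd.DataFrame], float | None],
    data: pd.DataFrame,
    config: BootstrapConfig,
    *,
    label: str = "statistic",
    exhaustive: bool = False,
) -> AccuracyResult:
    """BC percentile CI for ``stat_fn`` under cluster-stratified resampling.

    ``stat_fn`` maps a one-row-per-neonate DataFrame to a scalar (or ``None``
    when undefined on a degenerate resample; such replicates are dropped and
    counted).  Neonates are resampled with replacement within each cluster
    defined by ``config.cluster_cols``, preserving cluster sizes.  With
    ``exhaustive=True`` every equally likely resample is enumerated instead
    of sampled (feasible only for toy cohorts); the point estimate always
    comes from the original data.
    """
    theta = stat_fn(data)
    if theta is None:
        raise EstimationError(f"{label}: statistic undefined on the original data")
    clusters = _cluster_indices(data, config.cluster_cols)
    rng = np.random.default_rng(config.seed)

    def stat_of_idx(idx: np.ndarray) -> float | None:
        return stat_fn(data.iloc[idx])

    boot, n_undef = _collect_boot(stat_of_idx, clusters, config, exhaustive, rng)
    lo, hi = _bc_interval(float(theta), boot, config.alpha)
    return AccuracyResult(
        label=label,
        estimate=float(theta),
        ci_low=lo,
        ci_high=hi,
        n_boot=len(boot),
        n_undefined=n_undef,
    )


def difference_ci(
    stat_fn: Callable[[pd.DataFrame], float | None],
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    config: BootstrapConfig,
    *,
    label: str = "difference",
    exhaustive: bool = False,
) -> AccuracyResult:
    """BC CI for ``stat(A) - stat(B)``, resampling both groups' clusters jointly.

    The clusters of the two groups must be disjoint (each neonate belongs to
    exactly one group x hospital cluster); per iteration both cohorts are
    resampled and the difference recomputed.
    """
    ta, tb = stat_fn(data_a), stat_fn(data_b)
    if ta is None or tb is None:
        raise EstimationError(f"{label}: statistic undefined on the original data")
    theta = float(ta) - float(tb)
    clus_a = _cluster_indices(data_a, config.cluster_cols)
    clus_b = _cluster_indices(data_b, config.cluster_cols)
    rng = np.random.default_rng(config.seed)

    # encode a joint resample as indices into the concatenation [A | B]
    off = len(data_a)
    clusters = clus_a + [idx + off for idx in clus_b]

    def stat_of_idx(idx: np.ndarray) -> float | None:
        va = stat_fn(data_a.iloc[idx[idx < off]])
        vb = stat_fn(data_b.iloc[idx[idx >= off] - off])
        if va is None or vb is None:
            return None
        return float(va) - float(vb)

    boot, n_undef = _collect_boot(stat_of_idx, clusters, config, exhaustive, rng)
    lo, hi = _bc_interval(theta, boot, config.alpha)
    return AccuracyResult(
        label=label,
        estimate=theta,
        ci_low=lo,
        ci_high=hi,
        n_boot=len(boot),
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# post-hoc interaction test
# ---------------------------------------------------------------------------

def interaction_test(hour_table: pd.DataFrame) -> InteractionResult:
    """Logistic regression of hour identification on group, period, and their product.

    ``hour_table`` has one row per gold seizure hour with columns ``group``
    (two levels; the lexicographically larger level is coded 1), ``period``
    (two levels, same coding) and ``identified`` (0/1).  Fits
    logit P(identified) = b0 + b1*group + b2*period + b3*group*period by
    Newton/IRLS and reports the Wald p-value for the interaction term b3.
    Hours are treated as independent (see ``notes`` on the result).
    """
    for col in ("group", "period", "identified"):
        if col not in hour_table.columns:
            raise ValueError(f"hour_table missing column {col!r}")
    g_levels = sorted(hour_table["group"].unique())
    p_levels = sorted(hour_table["period"].unique())
    if len(g_levels) != 2 or len(p_levels) != 2:
        raise ValueError("interaction_test needs exactly two group and two period levels")
    g = (hour_table["group"] == g_levels[1]).astype(float).to_numpy()
    p = (hour_table["period"] == p_levels[1]).astype(float).to_numpy()
    y = hour_table["identified"].astype(float).to_numpy()
    X = np.column_stack([np.ones_like(g), g, p, g * p])
    names = ["intercept", f"group[{g_levels[1]}]", f"period[{p_levels[1]}]", "interaction"]
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        coeffs = dict(zip(names, fit.params))
        pval = float(fit.pvalues[3])
    except Exception as exc:  # separation / singular design
        logger.warning("interaction fit failed: %s", exc)
        return InteractionResult(coefficients={}, interaction_p=float("nan"), converged=False)
    if not converged or not np.isfinite(pval):
        return InteractionResult(coefficients=coeffs, interaction_p=float("nan"), converged=False)
    return InteractionResult(coefficients=coeffs, interaction_p=pval, converged=True)


# ---------------------------------------------------------------------------
# sample-size arithmetic
# ---------------------------------------------------------------------------

def required_group_size(n_seizure_required: int, prevalence: float) -> int:
    """Neonates to monitor per group so that enough have confirmed seizures.

    ``ceil(n_seizure_required / prevalence)`` where prevalence is the
    expected proportion of monitored neonates with confirmed electrographic
    seizures.
    """
    if not (0 < prevalence <= 1):
        raise ValueError("prevalence must be in (0, 1]")
    return math.ceil(n_seizure_required / prevalence - 1e-9)


def required_seizure_neonates(
    delta_pp: float, sd_pp: float, power: float = 0.8, alpha: float = 0.05
) -> int:
    """Two-sample normal-approximation group size for a difference in means.

    ``n = 2 * (z_{1-alpha/2} + z_{1-beta})^2 * sd^2 / delta^2`` per group,
    rounded up (never below 1), for detecting an absolute difference
    ``delta_pp`` in mean sensitivity between groups with common SD ``sd_pp``
    (both in percentage points) at the given power and two-sided alpha.
    """
    if delta_pp <= 0:
        raise ValueError("delta_pp must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    n = 2 * z**2 * sd_pp**2 / delta_pp**2
    return max(1, math.ceil(n - 1e-9))
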