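"""Accuracy metrics, the BC cluster bootstrap, the interaction test, sample size."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from neoseize.stats import (
    BootstrapConfig,
    bc_bootstrap_ci,
    difference_ci,
    false_detection_rate,
    form_false_detection_rate,
    hour_sensitivity,
    interaction_test,
    required_group_size,
    required_seizure_neonates,
    round_pct,
    sensitivity,
    specificity,
)


class TestPointMetrics:
    @pytest.mark.parametrize(
        "fn,args,expected",
        [
            (sensitivity, (26, 6), 81.3),
            (sensitivity, (34, 4), 89.5),
            (specificity, (81, 15), 84.4),
            (specificity, (82, 10), 89.1),
            (false_detection_rate, (15, 26), 36.6),
            (false_detection_rate, (10, 34), 22.7),
            (hour_sensitivity, (177, 268), 66.0),
            (hour_sensitivity, (177, 391), 45.3),
            (form_false_detection_rate, (97, 247), 39.3),
            (form_false_detection_rate, (177, 461), 38.4),
        ],
    )
    def test_reported_one_decimal(self, fn, args, expected):
        assert round_pct(fn(*args)) == expected

    def test_perfect_sensitivity(self):
        assert sensitivity(12, 0) == 100.0
        assert hour_sensitivity(0, 10) == 0.0

    def test_zero_denominator_flagged_not_nan(self):
        assert sensitivity(0, 0) is None
        assert specificity(0, 0) is None
        assert false_detection_rate(0, 0) is None

    def test_counts_recover_group_size(self):
        tp, tn, fp, fn = 26, 81, 15, 6
        assert (tp + fn) + (tn + fp) == 128

    def test_half_up_rounding(self):
        assert round_pct(16.625) == 16.6  # 0.025 below the midpoint
        assert round_pct(36.65) == 36.7  # exact midpoint rounds away from zero
        assert round_pct(-8.2237) == -8.2


def bc_interval_oracle(theta, boot, alpha=0.05):
    """Independent hand computation of the BC interval from a distribution."""
    boot = np.sort(np.asarray(boot, dtype=float))
    B = len(boot)
    b = (boot < theta).sum() + 0.5 * (boot == theta).sum()
    p = min(max(b / B, 1 / (B + 1)), B / (B + 1))
    z0 = norm.ppf(p)
    a1 = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    a2 = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    return np.quantile(boot, a1), np.quantile(boot, a2)


class TestBcBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        df = pd.DataFrame({"x": [1, 2, 3], "group": "g", "hospital": "h"})
        res = bc_bootstrap_ci(lambda d: 7.0, df, BootstrapConfig(n_iter=200, seed=0))
        assert res.estimate == 7.0
        assert (res.ci_low, res.ci_high) == (7.0, 7.0)

    def test_exhaustive_enumeration_matches_hand_computed_bc(self):
        # one cluster of 3 neonates: all 27 equally likely resamples
        df = pd.DataFrame({"x": [1.0, 4.0, 10.0], "group": "g", "hospital": "h"})
        stat = lambda d: float(d["x"].mean())
        res = bc_bootstrap_ci(stat, df, BootstrapConfig(n_iter=1, seed=0), exhaustive=True)
        boot = [
            np.mean([df["x"].iloc[list(c)]])
            for c in itertools.product(range(3), repeat=3)
        ]
        assert len(boot) == 27
        lo, hi = bc_interval_oracle(res.estimate, boot)
        assert res.estimate == pytest.approx(5.0)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_near_symmetric_case_matches_percentile_oracle(self):
        # binary outcome with p-hat = 0.5: bias ~ 0 so z0 ~ 0 and the BC
        # interval agrees with the plain percentile interval to +-0.02
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": np.repeat([0.0, 1.0], 50), "group": "g", "hospital": "h"})
        stat = lambda d: float(d["x"].mean())
        res = bc_bootstrap_ci(stat, df, BootstrapConfig(n_iter=10_000, seed=7))
        boot = []
        for _ in range(10_000):
            boot.append(df["x"].to_numpy()[rng.integers(0, 100, 100)].mean())
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert res.ci_low == pytest.approx(plo, abs=0.02)
        assert res.ci_high == pytest.approx(phi, abs=0.02)

    def test_resamples_preserve_cluster_sizes(self):
        df = pd.DataFrame(
            {
                "x": np.arange(12, dtype=float),
                "group": ["a"] * 6 + ["b"] * 6,
                "hospital": ["h1", "h1", "h1", "h2", "h2", "h2"] * 2,
            }
        )
        sizes = df.groupby(["group", "hospital"]).size()

        def checking_stat(d):
            assert d.groupby(["group", "hospital"]).size().equals(sizes)
            return float(d["x"].mean())

        bc_bootstrap_ci(checking_stat, df, BootstrapConfig(n_iter=50, seed=3))

    def test_seed_determinism(self):
        df = pd.DataFrame(
            {"x": np.random.default_rng(0).normal(size=40), "group": "g", "hospital": "h"}
        )
        stat = lambda d: float(d["x"].mean())
        r1 = bc_bootstrap_ci(stat, df, BootstrapConfig(n_iter=500, seed=11))
        r2 = bc_bootstrap_ci(stat, df, BootstrapConfig(n_iter=500, seed=11))
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_interval_width_shrinks_with_sample_size(self):
        widths = []
        for n in (25, 100, 400):
            ws = []
            for seed in range(5):
                x = np.random.default_rng(100 + seed).normal(size=n)
                df = pd.DataFrame({"x": x, "group": "g", "hospital": "h"})
                res = bc_bootstrap_ci(
                    lambda d: float(d["x"].mean()), df,
                    BootstrapConfig(n_iter=1000, seed=seed),
                )
                ws.append(res.ci_high - res.ci_low)
            widths.append(np.mean(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_undefined_resamples_dropped_and_counted(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "group": "g", "hospital": "h"})

        def stat(d):  # undefined unless the resample contains a 1
            return float(d["x"].max()) if d["x"].max() > 0 else None

        res = bc_bootstrap_ci(stat, df, BootstrapConfig(n_iter=400, seed=2))
        assert res.n_undefined > 0
        assert res.n_boot + res.n_undefined == 400


class TestDifferenceCi:
    def test_identical_groups_straddle_zero(self):
        x = np.random.default_rng(3).normal(size=40)
        df = pd.DataFrame({"x": x, "group": "g", "hospital": "h"})
        stat = lambda d: float(d["x"].mean())
        res = difference_ci(stat, df, df.copy(), BootstrapConfig(n_iter=1000, seed=4))
        assert res.estimate == 0.0
        assert res.ci_low < 0 < res.ci_high

    def test_point_difference_of_published_hour_counts(self):
        a = pd.DataFrame({"num": [177], "den": [268], "group": "g", "hospital": "h"})
        b = pd.DataFrame({"num": [177], "den": [391], "group": "g", "hospital": "h"})
        stat = lambda d: 100.0 * d["num"].sum() / d["den"].sum()
        res = difference_ci(stat, a, b, BootstrapConfig(n_iter=10, seed=0))
        assert round_pct(res.estimate) == 20.8


def saturated_cell_fit(n11, n10, n01, n00, n11b, n10b, n01b, n00b):
    """Closed-form saturated-model coefficients from 2x2x2 cell counts.

    Cells: (group g, period p) with counts of identified / not identified.
    Returns beta3 = log(OR_p1 / OR_p0) where OR_p is the group odds ratio
    within period p.
    """
    odds = {}
    for (g, p), (y1, y0) in {
        (0, 0): (n11, n10), (1, 0): (n01, n00),
        (0, 1): (n11b, n10b), (1, 1): (n01b, n00b),
    }.items():
        odds[(g, p)] = y1 / y0
    or_p0 = odds[(1, 0)] / odds[(0, 0)]
    or_p1 = odds[(1, 1)] / odds[(0, 1)]
    return math.log(or_p1 / or_p0)


def cells_to_frame(counts):
    rows = []
    for (g, p), (y1, y0) in counts.items():
        rows += [{"group": g, "period": p, "identified": 1}] * y1
        rows += [{"group": g, "period": p, "identified": 0}] * y0
    return pd.DataFrame(rows)


class TestInteraction:
    def test_equal_odds_ratios_zero_interaction(self):
        counts = {  # OR = 3 in both periods
            ("a", "wd"): (30, 10), ("b", "wd"): (90, 10),
            ("a", "we"): (20, 20), ("b", "we"): (60, 20),
        }
        res = interaction_test(cells_to_frame(counts))
        assert res.converged
        assert abs(res.coefficients["interaction"]) < 1e-6

    def test_recovers_log_odds_ratio_ratio(self):
        counts = {
            ("a", "wd"): (50, 50), ("b", "wd"): (60, 40),
            ("a", "we"): (30, 70), ("b", "we"): (80, 20),
        }
        res = interaction_test(cells_to_frame(counts))
        beta3 = saturated_cell_fit(50, 50, 60, 40, 30, 70, 80, 20)
        assert res.converged
        assert res.coefficients["interaction"] == pytest.approx(beta3, abs=1e-6)
        assert 0 <= res.interaction_p <= 1

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_separation_reported_not_raised(self):
        counts = {  # one cell fully identified -> infinite MLE
            ("a", "wd"): (20, 0), ("b", "wd"): (10, 10),
            ("a", "we"): (10, 10), ("b", "we"): (10, 10),
        }
        res = interaction_test(cells_to_frame(counts))
        assert not res.converged


class TestSampleSize:
    def test_group_size_inflation(self):
        assert required_group_size(33, 0.40) == 83
        assert required_group_size(33, 0.25) == 132
        assert required_group_size(10, 1.0) == 10

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            required_group_size(33, 0.0)

    def test_normal_approximation_value(self):
        # 25 pp difference, SD 35 pp, 80% power, two-sided 5% level
        assert required_seizure_neonates(25, 35, 0.8, 0.05) == 31

    def test_huge_effect_floors_at_one(self):
        assert required_seizure_neonates(1e9, 35) == 1

    def test_doubling_sd_quadruples_n(self):
        n1 = required_seizure_neonates(10, 20)
        n2 = required_seizure_neonates(10, 40)
        assert n2 == pytest.approx(4 * n1, abs=4)  # before ceiling effects
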