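import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whitecast.validation import (
    AcceptanceLimits,
    CorrelationMethod,
    accuracy_in_vitro,
    accuracy_in_vivo,
    check_gates,
    device_suitability,
    fisher_z,
    fit_linearity,
    gated_correlation,
    precision_rsd,
    z_difference,
)


def _suitability_frame(L_black, L_white, a=5.0, b=5.0):
    rows = []
    for bg, Ls in (("black_acrylic", L_black), ("white_acrylic", L_white)):
        for L in Ls:
            rows.append({"background": bg, "L": L, "a": a, "b": b})
    return pd.DataFrame(rows)


class TestDeviceSuitability:
    def test_identical_triples_pass_with_zero_rsd(self):
        report = device_suitability(
            _suitability_frame([25.0] * 3, [92.0] * 3)
        )
        assert report.passed
        assert (report.rsd.to_numpy() == 0.0).all()

    def test_spread_readings_fail(self):
        # sd 2 over mean 12 -> RSD 16.67% > 2%
        report = device_suitability(
            _suitability_frame([10.0, 12.0, 14.0], [92.0] * 3)
        )
        assert not report.passed
        assert report.rsd.loc["black_acrylic", "L"] == pytest.approx(
            100 * 2 / 12
        )

    def test_near_zero_channel_is_indeterminate_not_divided(self):
        frame = _suitability_frame([25.0] * 3, [92.0] * 3, a=0.01)
        report = device_suitability(frame)
        assert ("black_acrylic", "a") in report.indeterminate
        assert math.isnan(report.rsd.loc["black_acrylic", "a"])
        assert report.passed  # indeterminate channels do not fail the check

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError, match=">= 3"):
            device_suitability(_suitability_frame([25.0] * 2, [92.0] * 3))


def _normal_equations(x, y):
    """Brute-force OLS oracle via the 2x2 normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    sigma2 = resid @ resid / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot
    return beta[1], beta[0], np.sqrt(cov[1, 1]), np.sqrt(cov[0, 0]), r2


class TestFitLinearity:
    def test_exact_line(self):
        x = np.array([0.0, 5.0, 10.0, 20.0, 30.0])
        res = fit_linearity(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.linearity_range == (0.0, 30.0)

    def test_matches_normal_equations_oracle_on_hand_dataset(self):
        x = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0])
        y = np.array([46.1, 48.9, 51.2, 54.0, 56.2, 61.5])
        res = fit_linearity(x, y)
        slope, intercept, s_sd, i_sd, r2 = _normal_equations(x, y)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.slope_sd == pytest.approx(s_sd)
        assert res.intercept_sd == pytest.approx(i_sd)
        assert res.adjusted_r2 == pytest.approx(
            1 - (1 - r2) * (len(x) - 1) / (len(x) - 2)
        )

    @given(
        n=st.integers(4, 10),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_oracle_on_small_random_datasets(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice([0.0, 5.0, 10.0, 20.0, 30.0], size=n)
        if len(np.unique(x)) < 3:
            return
        y = 50 + 0.4 * x + rng.normal(0, 2, size=n)
        res = fit_linearity(x, y)
        slope, intercept, s_sd, i_sd, _ = _normal_equations(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert res.intercept == pytest.approx(intercept, rel=1e-9)
        assert res.slope_sd == pytest.approx(s_sd, rel=1e-7)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_linearity([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_adjusted_r2_never_exceeds_r2(self, vivo_with_category):
        post = vivo_with_category[
            (vivo_with_category["timepoint"] == "after")
            & (vivo_with_category["formulation_id"] != "bm")
        ]
        for _, grp in post.groupby("category"):
            res = fit_linearity(grp["zno_pct"], grp["L"])
            assert res.adjusted_r2 <= res.r2


class TestGatedCorrelation:
    def test_monotone_nonnormal_data_routes_to_spearman(self):
        x = np.arange(20.0)
        y = np.exp(x / 2.0)  # heavily right-skewed response
        res = gated_correlation(x, y)
        assert res.method is CorrelationMethod.SPEARMAN
        assert res.normality_p < 0.05
        assert res.coefficient == pytest.approx(1.0)

    def test_anti_ordered_ranks(self):
        x = np.arange(20.0)
        res = gated_correlation(x, np.exp(-x / 2.0))
        assert res.coefficient == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self):
        x = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0])
        y = np.array([46.0, 49.1, 50.8, 53.9, 55.6, 59.0, 60.9, 63.8])
        res = gated_correlation(x, y)
        assert res.method is CorrelationMethod.PEARSON
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.coefficient == pytest.approx(r_oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gated_correlation([1, 2, 3, 4], [5, 5, 5, 5])


class TestAccuracyInVivo:
    REF = {"light": 64.0, "brown": 46.0}

    def test_measured_equals_reference(self):
        entries = accuracy_in_vivo({"light": [64.0, 64.0, 64.0]}, self.REF)
        assert entries[0].accuracy_pct == pytest.approx(100.0)

    def test_uniform_underestimate_gives_zero_width_interval(self):
        entries = accuracy_in_vivo(
            {"brown": [0.9 * 46.0] * 4}, self.REF
        )
        e = entries[0]
        assert e.accuracy_pct == pytest.approx(90.0)
        assert e.ci_low == pytest.approx(90.0)
        assert e.ci_high == pytest.approx(90.0)

    def test_three_subject_interval_matches_t_oracle(self):
        values = [60.0, 64.0, 68.0]
        entries = accuracy_in_vivo({"light": values}, self.REF)
        acc = 100 * np.array(values) / 64.0
        from scipy import stats

        half = stats.t.ppf(0.975, 2) * acc.std(ddof=1) / math.sqrt(3)
        assert entries[0].ci_low == pytest.approx(acc.mean() - half)
        assert entries[0].ci_high == pytest.approx(acc.mean() + half)

    def test_missing_reference_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="no reference"):
            accuracy_in_vivo({"tan": [55.0]}, self.REF)

    def test_absolute_convention(self):
        entries = accuracy_in_vivo(
            {"light": [61.0]}, self.REF, convention="absolute"
        )
        assert entries[0].accuracy_pct == pytest.approx(97.0)


class TestAccuracyInVitro:
    @pytest.mark.parametrize(
        "lab, expected",
        [
            ((0.0, 0.0, 0.0), 100.0),
            ((10.0, 0.0, 0.0), 90.0),
            ((0.0, 6.0, 8.0), 90.0),  # 6-8-10 triangle
        ],
    )
    def test_distance_convention_against_black(self, lab, expected):
        frame = pd.DataFrame(
            [{"paint": "black", "background": "black_acrylic",
              "L": lab[0], "a": lab[1], "b": lab[2]}]
        )
        entries = accuracy_in_vitro(frame)
        assert entries[0].accuracy_pct == pytest.approx(expected)

    def test_white_anchor(self):
        frame = pd.DataFrame(
            [{"paint": "white", "background": "black_acrylic",
              "L": 93.0, "a": 0.0, "b": 0.0}]
        )
        assert accuracy_in_vitro(frame)[0].accuracy_pct == pytest.approx(93.0)


def _precision_frame(groups):
    """groups: {(factor, formulation, day, timepoint): [L values]}"""
    rows = []
    for (factor, formulation, day, timepoint), values in groups.items():
        for L in values:
            rows.append(
                {"category": factor, "formulation_id": formulation,
                 "day": day, "timepoint": timepoint, "L": L}
            )
    return pd.DataFrame(rows)


class TestPrecisionRsd:
    def test_identical_replicates_have_zero_range(self):
        frame = _precision_frame(
            {("dark", "zno_0", 1, "before"): [46.0, 46.0, 46.0]}
        )
        [entry] = precision_rsd(frame, "category")
        assert entry.rsd_min == entry.rsd_max == 0.0

    def test_hand_computed_range(self):
        # group A: mean 50, sd 1 -> 2%; group B: mean 40, sd 2 -> 5%
        frame = _precision_frame(
            {
                ("dark", "zno_0", 1, "before"): [49.0, 50.0, 51.0],
                ("dark", "zno_5", 1, "before"): [38.0, 40.0, 42.0],
            }
        )
        [entry] = precision_rsd(frame, "category")
        assert entry.rsd_min == pytest.approx(2.0)
        assert entry.rsd_max == pytest.approx(5.0)
        assert entry.n_groups == 2

    def test_single_replicate_group_warns_and_skips(self):
        frame = _precision_frame(
            {
                ("dark", "zno_0", 1, "before"): [49.0, 50.0, 51.0],
                ("dark", "zno_5", 1, "before"): [40.0],
            }
        )
        with pytest.warns(UserWarning, match="single replicate"):
            [entry] = precision_rsd(frame, "category")
        assert entry.n_groups == 1

    def test_inter_day_pools_days(self):
        frame = _precision_frame(
            {
                ("black", "zno_0", 1, "before"): [36.0, 36.5, 37.0],
                ("black", "zno_0", 2, "before"): [40.0, 40.5, 41.0],
            }
        )
        [inter] = precision_rsd(frame, "category", mode="inter_day")
        intra = precision_rsd(frame, "category", mode="intra_day")
        # pooling the shifted days inflates the inter-day RSD
        assert inter.rsd_max > max(e.rsd_max for e in intra)

    def test_synthetic_study_rsd_below_ten_percent(self, vivo_with_category):
        for entry in precision_rsd(vivo_with_category, "category"):
            assert entry.rsd_max < 10.0


class TestFisherZ:
    def test_odd_function_origin(self):
        assert fisher_z(0.0) == 0.0

    @pytest.mark.parametrize("r, z", [(0.904, 1.494), (0.774, 1.030)])
    def test_published_conversions(self, r, z):
        assert round(fisher_z(r), 3) == z

    def test_matches_arctanh_closed_form_on_grid(self):
        grid = np.linspace(-0.999, 0.999, 201)
        for r in grid:
            assert fisher_z(r) == pytest.approx(np.arctanh(r), abs=1e-15)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.2])
    def test_domain(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestZDifference:
    def test_equal_coefficients_give_zero(self):
        z, sig = z_difference(0.8, 53, 0.8, 28)
        assert z == 0.0
        assert not sig

    def test_hand_case(self):
        # z1 = atanh(.9) = 1.47222, z2 = atanh(.5) = 0.549306
        # se = sqrt(1/17 + 1/22) = 0.322097 -> Z = 2.8653
        z, sig = z_difference(0.9, 20, 0.5, 25)
        expected = (math.atanh(0.9) - math.atanh(0.5)) / math.sqrt(
            1 / 17 + 1 / 22
        )
        assert z == pytest.approx(expected)
        assert sig

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            z_difference(0.5, 3, 0.5, 20)


class TestGates:
    def test_reusable_gate_function(self, vivo_with_category):
        post = vivo_with_category[
            (vivo_with_category["timepoint"] == "after")
            & (vivo_with_category["formulation_id"] != "bm")
        ]
        linearity = [
            fit_linearity(g["zno_pct"], g["L"])
            for _, g in post.groupby("category")
        ]
        precision = precision_rsd(vivo_with_category, "category")
        gates = check_gates(precision=precision, linearity=linearity)
        assert gates["precision"]
        assert gates["linearity"]
        assert gates["all"]

    def test_gate_limits_are_configuration(self):
        strict = AcceptanceLimits(min_adjusted_r2=0.999)
        res = fit_linearity(
            [0.0, 5.0, 10.0, 20.0], [46.0, 50.4, 49.1, 55.9]
        )
        assert not check_gates(linearity=[res], limits=strict)["linearity"]
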