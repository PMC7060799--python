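"""Validation statistics and the reference-value procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cinequant.refstats import (
    ErrorDetectionSummary,
    age_regression,
    bland_altman,
    dice,
    error_detection_summary,
    iqr_outlier_mask,
    mae_compare,
    prediction_interval,
    reference_values,
)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:3], b[5:] = True, True
        assert dice(a, b) == 0.0

    def test_partial_overlap_two_thirds(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([1, 0, 0, 0], bool)
        assert dice(a, b) == pytest.approx(2.0 / 3.0)

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            dice(np.zeros(3, bool), np.zeros(4, bool))

    @given(st.integers(0, 500))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(40) > 0.5
        b = rng.random(40) > 0.3
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestBlandAltman:
    def test_identical_series_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0
        assert ba.p_vs_zero == 1.0

    def test_exact_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x + 2.0, x)
        assert ba.bias == 2.0
        assert ba.loa_low == ba.loa_high == 2.0
        assert ba.p_vs_zero == 0.0

    def test_gaussian_differences_recover_bias_and_loa(self):
        rng = np.random.default_rng(12)
        manual = rng.normal(150, 20, 100)
        auto = manual + rng.normal(1.8, 5.0, 100)
        ba = bland_altman(auto, manual)
        se = 5.0 / np.sqrt(100)
        assert abs(ba.bias - 1.8) < 3 * se
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * 5.0, rel=0.3)
        assert ba.loa_low == pytest.approx(ba.bias - 1.96 * ba.sd)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestErrorDetection:
    # printed sensitivity/specificity/BACC triples for the six strata of a
    # two-arm (volumes/strains) x (healthy/patients/overall) summary
    TABLE = [
        (94.83, 86.57, 90.70),
        (95.39, 76.78, 86.09),
        (94.99, 82.93, 88.96),
        (92.69, 77.34, 85.02),
        (94.41, 76.65, 85.53),
        (93.21, 77.14, 85.18),
    ]

    @pytest.mark.parametrize("sens,spec,bacc", TABLE)
    def test_bacc_is_mean_of_sensitivity_and_specificity(self, sens, spec, bacc):
        assert abs(ErrorDetectionSummary.bacc_from_rates(sens, spec) - bacc) <= 0.005 + 1e-9

    def test_counts_to_rates(self):
        s = error_detection_summary([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (s.tp, s.fp, s.tn, s.fn) == (2, 1, 1, 1)
        assert s.sensitivity == pytest.approx(100 * 2 / 3)
        assert s.specificity == pytest.approx(50.0)
        assert s.bacc == pytest.approx((s.sensitivity + s.specificity) / 2)

    def test_perfect_detection(self):
        s = error_detection_summary([1, 0, 1, 0], [1, 0, 1, 0])
        assert s.sensitivity == s.specificity == s.bacc == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            error_detection_summary([], [])


class TestReferenceValues:
    def test_three_iqr_rule_removes_gross_outlier_only(self):
        vals = np.array([10.0, 11.0, 12.0, 13.0, 1000.0])
        mask = iqr_outlier_mask(vals)
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_stratum_gives_degenerate_interval(self):
        mean, lo, hi = prediction_interval(np.full(30, 7.0))
        assert mean == lo == hi == 7.0

    def test_prediction_interval_matches_closed_form(self):
        rng = np.random.default_rng(3)
        v = rng.normal(100, 10, 600)
        mean, lo, hi = prediction_interval(v)
        # large-n Gaussian PI approaches mean +/- 1.96 sd
        assert lo == pytest.approx(100 - 19.6, abs=1.0)
        assert hi == pytest.approx(100 + 19.6, abs=1.0)

    def test_stratified_table_layout_and_outlier_column(self):
        rng = np.random.default_rng(1)
        rows = []
        for sex in ("F", "M"):
            for age0 in (45, 55, 65):
                for _ in range(40):
                    rows.append({
                        "sex": sex, "age": age0 + rng.integers(0, 10),
                        "lv_edv_ml": rng.normal(150, 20),
                    })
        rows[0]["lv_edv_ml"] = 5000.0  # planted gross outlier
        df = pd.DataFrame(rows)
        ref = reference_values(df)
        assert set(ref["age_band"]) == {"45-54", "55-64", "65-74"}
        assert len(ref) == 6
        planted = ref[(ref.sex == "F") & (ref.age_band == "45-54")].iloc[0]
        assert planted["outliers_removed"] == 1
        assert planted["n"] == 39
        ok = ref[ref["available"]]
        assert (ok["pi_low"] < ok["mean"]).all() and (ok["mean"] < ok["pi_high"]).all()

    def test_empty_stratum_marked_unavailable(self):
        df = pd.DataFrame({
            "sex": ["M"] * 10, "age": np.linspace(45, 54, 10),
            "p": np.random.default_rng(0).normal(size=10),
        })
        ref = reference_values(df)
        missing = ref[(ref.age_band == "65-74")]
        assert not missing["available"].any()


class TestAgeRegression:
    def test_perfect_linear_data(self):
        age = np.linspace(45, 74, 200)
        df = pd.DataFrame({"sex": "M", "age": age, "p": 300 - 0.5 * age})
        out = age_regression(df, parameters=["p"])
        assert out.iloc[0]["slope_per_year"] == pytest.approx(-0.5, abs=1e-9)
        assert out.iloc[0]["p_bonferroni"] < 1e-12

    def test_noisy_slope_recovered_within_ci(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(45, 74, 500)
        y = 200 - 0.5 * age + rng.normal(0, 5, 500)
        df = pd.DataFrame({"sex": "F", "age": age, "p": y})
        out = age_regression(df, parameters=["p"])
        se = 5.0 / (np.std(age) * np.sqrt(500))
        assert abs(out.iloc[0]["slope_per_year"] + 0.5) < 4 * se

    def test_bonferroni_controls_family_error_on_pure_noise(self):
        rng = np.random.default_rng(9)
        n_sig = 0
        reps = 60
        m = 20
        for _ in range(reps):
            age = rng.uniform(45, 74, 120)
            data = {"sex": "M", "age": age}
            for j in range(m):
                data[f"p{j}"] = rng.normal(0, 1, 120)
            out = age_regression(pd.DataFrame(data))
            n_sig += int(out["significant"].any())
        # family-wise error should be near alpha = 0.05
        assert n_sig / reps <= 0.15

    def test_constant_age_rejected(self):
        df = pd.DataFrame({"sex": "M", "age": [50.0] * 10, "p": np.arange(10.0)})
        with pytest.raises(ValueError, match="age must vary"):
            age_regression(df)


class TestMAECompare:
    def test_identical_groups_p_one(self):
        e = np.array([1.0, 2.0, 3.0])
        out = mae_compare(e, e, paired=True)
        assert out["p"] == 1.0
        assert out["mae_a"] == out["mae_b"] == 2.0

    def test_zero_vs_noisy_group(self):
        rng = np.random.default_rng(0)
        out = mae_compare(np.zeros(30), rng.normal(0, 3, 30))
        assert out["mae_a"] == 0.0
        assert out["mae_b"] > 0.0

    def test_separated_groups_usually_significant(self):
        # Monte-Carlo power check: absolute-error groups with means
        # 4.04 (sd 4) vs 6.65 (sd 6), n = 50 pairs per replicate
        rng = np.random.default_rng(6)

        def gamma(mean, sd, n):
            shape = (mean / sd) ** 2
            return rng.gamma(shape, sd**2 / mean, n)

        hits = 0
        reps = 40
        for _ in range(reps):
            a = gamma(4.04, 4.0, 50)
            b = gamma(6.65, 6.0, 50)
            if mae_compare(a, b, paired=True)["p"] < 0.05:
                hits += 1
        assert hits / reps >= 0.6
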