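"""Validation statistics and the normative reference-value procedure.

Validation against a manual reader uses Dice overlap, Bland-Altman bias
and 95% limits of agreement with a paired t-test of the bias against zero,
Pearson correlation, and a comparison of mean absolute errors between
subject groups.  Error-detection performance is summarized by sensitivity,
specificity and balanced accuracy.

Reference values are computed per sex and age decade (45-54, 55-64,
65-74): values beyond 3 interquartile ranges below Q1 or above Q3 are
excluded a priori (type-7 linear-interpolation quartiles), and the
reported range is the Gaussian 95% prediction interval
mean +/- t_{0.975, n-1} * s * sqrt(1 + 1/n).  Age effects are assessed by
per-sex ordinary least squares with Bonferroni correction across the
parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AGE_BANDS = ((45, 54), (55, 64), (65, 74))


# ---------------------------------------------------------------------------
# overlap and agreement
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A^B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (na + nb)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    p_vs_zero: float
    n: int
    sd: float

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "p_vs_zero": self.p_vs_zero,
            "n": self.n,
        }


def bland_altman(x_auto, x_manual) -> BlandAltman:
    """Paired-difference agreement (differences taken auto - manual)."""
    a = np.asarray(x_auto, dtype=float)
    m = np.asarray(x_manual, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # exact shift (or identity): the t statistic is degenerate
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltman(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        p_vs_zero=p, n=len(d), sd=sd,
    )


def mae_compare(errors_a, errors_b, paired: bool = False) -> dict:
    """Mean absolute error summaries per group plus a two-sample p value.

    Paired t-test when ``paired`` (equal lengths required); otherwise
    Welch's unequal-variance t-test.
    """
    a = np.abs(np.asarray(errors_a, dtype=float))
    b = np.abs(np.asarray(errors_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal group sizes")
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
    else:
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "mae_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "mae_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "p": p, "test": "paired t" if paired else "Welch t",
    }


# ---------------------------------------------------------------------------
# error-detection summary
# ---------------------------------------------------------------------------


@dataclass
class ErrorDetectionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def bacc(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @staticmethod
    def bacc_from_rates(sensitivity_pct: float, specificity_pct: float) -> float:
        """Balanced accuracy (%) from printed sensitivity/specificity."""
        return (sensitivity_pct + specificity_pct) / 2.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "bacc_pct": self.bacc,
        }


def error_detection_summary(pipeline_flags, truth_labels) -> ErrorDetectionSummary:
    """Confusion counts of flagging vs manually labelled erroneous output.

    Both inputs are binary vectors: 1 = flagged (pipeline) / erroneous
    (truth), 0 = accepted / error-free.
    """
    f = np.asarray(pipeline_flags).astype(bool)
    t = np.asarray(truth_labels).astype(bool)
    if f.shape != t.shape or f.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D binary vectors")
    if len(f) == 0:
        raise ValueError("empty input")
    return ErrorDetectionSummary(
        tp=int(np.sum(f & t)),
        fp=int(np.sum(f & ~t)),
        tn=int(np.sum(~f & ~t)),
        fn=int(np.sum(~f & t)),
    )


# ---------------------------------------------------------------------------
# reference values
# ---------------------------------------------------------------------------


def iqr_outlier_mask(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """True where a value lies beyond k IQRs below Q1 or above Q3 (type-7)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def prediction_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(mean, low, high) Gaussian prediction interval for one new observation."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    mean = float(v.mean())
    if n < 2:
        return mean, mean, mean
    s = float(v.std(ddof=1))
    tq = stats.t.ppf(0.5 + level / 2.0, n - 1)
    half = tq * s * np.sqrt(1.0 + 1.0 / n)
    return mean, mean - half, mean + half


def _band_label(band) -> str:
    return f"{band[0]}-{band[1]}"


def reference_values(
    cohort: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    age_bands=AGE_BANDS,
    min_n: int = 20,
    method: str = "gaussian",
) -> pd.DataFrame:
    """Stratified means and 95% prediction intervals with 3-IQR outlier removal.

    ``cohort`` needs ``sex`` and ``age`` columns; every other numeric column
    is treated as a parameter unless ``parameters`` is given.  ``method``
    may be ``"gaussian"`` (t-based interval) or ``"percentile"``
    (empirical 2.5/97.5 percentiles).
    """
    if "sex" not in cohort or "age" not in cohort:
        raise ValueError("cohort needs 'sex' and 'age' columns")
    if parameters is None:
        parameters = [
            c for c in cohort.columns
            if c not in ("sex", "age") and np.issubdtype(cohort[c].dtype, np.number)
        ]
    rows = []
    for sex in sorted(cohort["sex"].unique()):
        for band in age_bands:
            stratum = cohort[
                (cohort["sex"] == sex)
                & (cohort["age"] >= band[0])
                & (cohort["age"] <= band[1])
            ]
            for p in parameters:
                vals = stratum[p].dropna().to_numpy(dtype=float)
                base = {
                    "sex": sex, "age_band": _band_label(band), "parameter": p,
                }
                if len(vals) == 0:
                    rows.append({**base, "n": 0, "mean": np.nan, "pi_low": np.nan,
                                 "pi_high": np.nan, "outliers_removed": 0,
                                 "available": False})
                    continue
                out = iqr_outlier_mask(vals)
                kept = vals[~out]
                if method == "percentile" and len(kept) >= 2:
                    mean = float(kept.mean())
                    lo, hi = np.percentile(kept, [2.5, 97.5])
                else:
                    mean, lo, hi = prediction_interval(kept)
                rows.append({
                    **base, "n": int(len(kept)), "mean": mean,
                    "pi_low": float(lo), "pi_high": float(hi),
                    "outliers_removed": int(out.sum()),
                    "available": True,
                    "small_stratum": len(kept) < min_n,
                })
    return pd.DataFrame(rows)


def reference_table_wide(ref: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy reference table to parameter rows x (band, bound) cols."""
    ref = ref[ref["available"]].copy()
    wide = ref.pivot_table(
        index=["sex", "parameter"], columns="age_band",
        values=["pi_low", "mean", "pi_high"],
    )
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    return wide


def age_regression(
    cohort: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-sex OLS of each parameter on age, Bonferroni-corrected p values.

    The correction family is the set of parameters within one sex.
    """
    import statsmodels.api as sm

    if parameters is None:
        parameters = [
            c for c in cohort.columns
            if c not in ("sex", "age") and np.issubdtype(cohort[c].dtype, np.number)
        ]
    rows = []
    m = len(parameters)
    for sex in sorted(cohort["sex"].unique()):
        sub = cohort[cohort["sex"] == sex]
        age = sub["age"].to_numpy(dtype=float)
        if len(np.unique(age)) < 2:
            raise ValueError("age must vary within each sex group")
        X = sm.add_constant(age)
        for p in parameters:
            y = sub[p].to_numpy(dtype=float)
            ok = np.isfinite(y)
            fit = sm.OLS(y[ok], X[ok]).fit()
            pval = float(fit.pvalues[1])
            adj = min(1.0, pval * m)
            rows.append({
                "sex": sex, "parameter": p,
                "slope_per_year": float(fit.params[1]),
                "p": pval, "p_bonferroni": adj,
                "significant": adj < alpha,
            })
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)
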