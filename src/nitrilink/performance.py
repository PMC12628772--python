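"""Nitrification chemistry metrics and univariate screening statistics.

Nitrate production is the difference between the summed reduced nitrogen
species (organic-N + NH4-N + NO2-N) in the influent and effluent;
efficiency divides production by the influent sum and the rate divides it
by the hydraulic retention time.  Between-period comparisons route to a
t-test or a Wilcoxon rank-sum test depending on Shapiro-Wilk normality in
both groups, with an F test choosing the pooled or unequal-variance t form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("nitrilink")

_IN_COLS = ("influent_organic_n", "influent_nh4_n", "influent_no2_n")
_OUT_COLS = ("effluent_organic_n", "effluent_nh4_n", "effluent_no2_n")


def nitrification_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Per-day nitrate production, nitrification efficiency, and rate.

    ``records`` must carry the influent/effluent organic-N, NH4-N and NO2-N
    columns plus ``hrt_days``.  Negative production (effluent exceeding
    influent) is passed through and flagged rather than clamped, preserving
    mass-balance anomalies for QC.

    Raises
    ------
    ValueError
        If any influent nitrogen sum is zero (efficiency undefined) or any
        HRT is non-positive.
    """
    missing = [
        c for c in _IN_COLS + _OUT_COLS + ("hrt_days",)
        if c not in records.columns
    ]
    if missing:
        raise ValueError(f"nitrogen records missing columns: {missing}")
    body = records.loc[:, list(_IN_COLS + _OUT_COLS)].to_numpy(dtype=float)
    if (body < 0).any():
        raise ValueError("nitrogen concentrations must be non-negative")
    hrt = records["hrt_days"].to_numpy(dtype=float)
    if (hrt <= 0).any():
        raise ValueError("hydraulic retention time must be positive")
    in_sum = records.loc[:, list(_IN_COLS)].sum(axis=1).to_numpy(dtype=float)
    out_sum = records.loc[:, list(_OUT_COLS)].sum(axis=1).to_numpy(dtype=float)
    if (in_sum == 0).any():
        raise ValueError(
            "influent nitrogen sum is zero; efficiency is undefined"
        )
    production = in_sum - out_sum
    negative = production < 0
    if negative.any():
        log.warning(
            "%d day(s) with negative nitrate production (flagged)",
            int(negative.sum()),
        )
    return pd.DataFrame(
        {
            "production": production,
            "efficiency": production / in_sum,
            "rate": production / hrt,
            "negative_production": negative,
        },
        index=records.index,
    )


def cells_from_copies(copies_per_ml, copies_per_genome: float):
    """Convert gene copies/mL to cells/mL given copies per genome."""
    if copies_per_genome <= 0:
        raise ValueError("copies_per_genome must be positive")
    return np.asarray(copies_per_ml, dtype=float) / copies_per_genome


#: Published average amoA copies per genome for each ammonia-oxidizer guild.
AMOA_COPIES_PER_GENOME = {"aoa": 1.0, "aob": 2.5, "comammox": 1.0}


def total_ammonia_oxidizers(copies_by_guild: dict) -> np.ndarray:
    """Sum guild cell abundances after copy-number normalization.

    ``copies_by_guild`` maps guild name ("aoa", "aob", "comammox") to a
    copies/mL series.
    """
    total = None
    for guild, copies in copies_by_guild.items():
        cells = cells_from_copies(copies, AMOA_COPIES_PER_GENOME[guild])
        total = cells if total is None else total + cells
    return total


@dataclass(frozen=True)
class TestReport:
    """Outcome of one between-period comparison."""

    test: str            # "t-test" or "wilcoxon"
    statistic: float
    pvalue: float
    decision_path: tuple  # human-readable record of each gate


def decide_test(
    shapiro_p1: float,
    shapiro_p2: float,
    f_test_p: float,
    normality_alpha: float = 0.05,
) -> tuple:
    """Pure decision function: which test, and which t-test form.

    Returns (test_name, equal_var) where ``equal_var`` is meaningful only
    for the t-test.
    """
    if shapiro_p1 > normality_alpha and shapiro_p2 > normality_alpha:
        return "t-test", f_test_p > normality_alpha
    return "wilcoxon", False


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v2 == 0 or v1 == 0:
        return 0.0
    f = v1 / v2
    p = stats.f.sf(f, len(a) - 1, len(b) - 1)
    return float(2.0 * min(p, 1.0 - p))


def between_period_test(
    values, period_labels, normality_alpha: float = 0.05
) -> TestReport:
    """Compare a variable between two periods.

    Shapiro-Wilk is run within each period; when both are compatible with
    normality an independent t-test is used (pooled when an F test accepts
    equal variances, Welch otherwise), else the Wilcoxon rank-sum test.
    Constant groups make the normality test undefined and fall back to the
    rank-sum test with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(period_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two period labels are required")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 values per period")
    path = []
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        log.warning("constant group; normality undefined, using rank-sum test")
        path.append("constant group -> wilcoxon")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestReport("wilcoxon", float(stat), float(p), tuple(path))
    sw1 = stats.shapiro(a).pvalue
    sw2 = stats.shapiro(b).pvalue
    fp = _f_test_p(a, b)
    test, equal_var = decide_test(sw1, sw2, fp, normality_alpha)
    path.append(f"shapiro p1={sw1:.4g}, p2={sw2:.4g} (alpha={normality_alpha})")
    if test == "t-test":
        path.append(
            f"F-test p={fp:.4g} -> {'pooled' if equal_var else 'welch'} t"
        )
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    else:
        path.append("normality rejected -> wilcoxon")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestReport(test, float(stat), float(p), tuple(path))


def period_summary(
    meta: pd.DataFrame, variables, period_col: str = "period"
) -> pd.DataFrame:
    """Mean +/- SD per period with the routed test and p-value per variable."""
    rows = []
    labels = meta[period_col]
    for var in variables:
        v = meta[var].astype(float)
        rep = between_period_test(v.to_numpy(), labels.to_numpy())
        grouped = v.groupby(labels)
        means, sds = grouped.mean(), grouped.std(ddof=1)
        rows.append(
            {
                "variable": var,
                "mean_p1": means.iloc[0],
                "sd_p1": sds.iloc[0],
                "mean_p2": means.iloc[1],
                "sd_p2": sds.iloc[1],
                "test": rep.test,
                "p": rep.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def spearman_screen(x_table: pd.DataFrame, y_series) -> pd.DataFrame:
    """Spearman rank correlation (tie-corrected) of each column against y.

    Constant columns yield NaN correlation and p (reported as missing).
    """
    y = np.asarray(y_series, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 paired observations")
    rows = []
    for col in x_table.columns:
        x = x_table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((col, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((col, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["variable", "rho", "p"]).set_index(
        "variable"
    )
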