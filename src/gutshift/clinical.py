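"""Normality-gated two-group tests for clinical tables.

Each clinical feature is compared between arms with a Student's t-test
(pooled variance) when Shapiro-Wilk finds both groups compatible with
normality (p > 0.05 in each), and a two-sided Wilcoxon rank-sum test
otherwise.  The family of per-feature p-values is then Benjamini-Hochberg
adjusted and significance called at FDR 0.05.
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import rank_sum_test
from .temporal import bh_adjust

SHAPIRO_ALPHA = 0.05

#: Published two-group p-values from the clinical-characteristics table of a
#: 27+27 pregnancy cohort (gestational diabetes vs. matched controls), used
#: as reference input for the BH adjustment step.
REFERENCE_CLINICAL_P: Dict[str, float] = {
    "age": 0.2945,
    "pre_bmi": 0.7577,
    "total_weight_gain": 0.0151,
    "fgb": 0.598,
    "hb": 0.028,
    "alt": 0.2528,
    "ast": 0.7547,
    "urea": 0.93,
    "creatine": 0.7997,
    "hba1c": 0.0012,
    "progesterone": 0.0583,
    "tc": 0.8289,
    "tg": 0.2302,
    "hdl_c": 0.8739,
    "ldl_c": 0.0864,
    "tsh": 0.7135,
}


def gated_two_group_test(
    values_g1: Sequence[float],
    values_g2: Sequence[float],
    equal_var: bool = True,
) -> Tuple[str, float]:
    """Shapiro-gated comparison of two clinical samples.

    Returns (test_used, p) with test_used in {"t_test", "wilcoxon"}.  A
    constant group (Shapiro undefined) falls through to the rank-sum path
    with a warning.  ``equal_var=True`` gives the classical pooled-variance
    Student's test; set False for Welch.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values per group")
    normal = True
    for arr, name in ((x, "group 1"), (y, "group 2")):
        if np.ptp(arr) == 0:
            warnings.warn(f"{name} is constant; Shapiro-Wilk undefined, using rank-sum test")
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            if stats.shapiro(arr).pvalue <= SHAPIRO_ALPHA:
                normal = False
                break
    if normal:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
        return "t_test", p
    _, p = rank_sum_test(x, y)
    return "wilcoxon", p


def adjust_clinical_table(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Append BH-adjusted q-values and an FDR-0.05 significance flag."""
    if len(results) < 1:
        raise ValueError("need at least one feature")
    out = results.copy()
    out["q_bh"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_bh"] < fdr
    return out


def run_clinical_table(
    data: pd.DataFrame,
    features: Sequence[str] = (),
    group_col: str = "group",
    equal_var: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full clinical analysis of a wide per-subject table.

    ``data`` has one row per subject with a ``group`` column ("GDM" /
    "control") and one numeric column per clinical feature.  Returns one row
    per feature: group means +- SD, test used, p, BH q and significance.
    """
    feats = list(features) or [
        c for c in data.columns if c not in (group_col, "subject_id") and pd.api.types.is_numeric_dtype(data[c])
    ]
    g1 = data[data[group_col] == "GDM"]
    g2 = data[data[group_col] == "control"]
    rows = []
    for feat in feats:
        x = g1[feat].dropna().to_numpy(dtype=float)
        y = g2[feat].dropna().to_numpy(dtype=float)
        test_used, p = gated_two_group_test(x, y, equal_var=equal_var)
        rows.append(
            {
                "feature": feat,
                "mean_gdm": x.mean(),
                "sd_gdm": x.std(ddof=1),
                "mean_control": y.mean(),
                "sd_control": y.std(ddof=1),
                "test_used": test_used,
                "p_value": p,
            }
        )
    return adjust_clinical_table(pd.DataFrame(rows), fdr=fdr)
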