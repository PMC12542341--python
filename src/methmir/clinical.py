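"""Cohort-comparison statistics and normality-gated clinical correlation.

Continuous variables are gated by Shapiro-Wilk (p > 0.05 means "treat as
normal"): normal pairs are correlated with Pearson and compared with
Student's t; otherwise Spearman and Mann-Whitney.  Categorical variables
use a two-sided Fisher exact test (the probability-mass convention: the
p-value sums the probabilities of all tables with fixed margins that are
no more probable than the observed one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet, ValidationError


@dataclass
class CorrelationResult:
    feature_id: str
    clinical_var: str
    method: str          # "pearson" | "spearman"
    r: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    variable: str
    test: str            # "student_t" | "mann_whitney" | "fisher_exact"
    statistic: float
    p_value: float
    normal: bool | None  # normality decision behind the test choice
    summary_a: str
    summary_b: str


def normality_gate(x) -> str:
    """Shapiro-Wilk gate: 'normal' when p > 0.05, else 'nonnormal'."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValidationError(f"normality test needs at least 3 observations (got {len(x)})")
    if np.ptp(x) == 0:
        warnings.warn("constant vector; treating as non-normal", stacklevel=2)
        return "nonnormal"
    _, p = stats.shapiro(x)
    return "normal" if p > 0.05 else "nonnormal"


def correlate(expr, clin, feature_id: str = "", clinical_var: str = "") -> CorrelationResult:
    """Pearson if both vectors pass the normality gate, else Spearman.

    Uses pairwise-complete observations (rows finite in both vectors).
    """
    expr = np.asarray(expr, float)
    clin = np.asarray(clin, float)
    if expr.shape != clin.shape:
        raise ValidationError("expression and clinical vectors differ in length")
    mask = np.isfinite(expr) & np.isfinite(clin)
    x, y = expr[mask], clin[mask]
    if len(x) < 3:
        raise ValidationError("fewer than 3 complete observations for correlation")
    if normality_gate(x) == "normal" and normality_gate(y) == "normal":
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(feature_id, clinical_var, method, float(r), float(p), int(len(x)))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table (odds ratio, p)."""
    res = stats.fisher_exact(np.asarray(table, int), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_groups(values, labels, variable: str = "", categorical: bool | None = None) -> GroupComparison:
    """Compare a variable between two groups.

    Continuous: Student's t when both groups pass the normality gate, else
    Mann-Whitney.  Categorical (binary): Fisher exact on the 2x2
    contingency table.  ``categorical`` is inferred from dtype when None.
    """
    values = pd.Series(values)
    labels = pd.Series(list(labels))
    groups = labels.unique()
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {list(groups)}")
    a = values[(labels == groups[0]).to_numpy()]
    b = values[(labels == groups[1]).to_numpy()]
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(values)
    if categorical:
        cats = pd.Series(values).dropna().unique()
        if len(cats) > 2:
            raise ValidationError(f"Fisher exact supports binary variables, got {list(cats)}")
        cats = sorted(cats)
        table = [
            [int((a == cats[0]).sum()), int((a == cats[-1]).sum())],
            [int((b == cats[0]).sum()), int((b == cats[-1]).sum())],
        ]
        odds, p = fisher_exact_2x2(table)
        pct = lambda g: f"{100.0 * (g == cats[-1]).mean():.0f}% {cats[-1]}"
        return GroupComparison(variable, "fisher_exact", odds, p, None, pct(a), pct(b))
    a = pd.to_numeric(a, errors="coerce").dropna()
    b = pd.to_numeric(b, errors="coerce").dropna()
    normal = normality_gate(a) == "normal" and normality_gate(b) == "normal"
    if normal:
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b)
        test = "student_t"
        fmt = lambda g: f"{g.mean():.3g} ± {g.std(ddof=1):.3g}"
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = len(a) * len(b) / 2.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
        fmt = lambda g: f"{g.median():.3g} [{g.quantile(0.25):.3g}-{g.quantile(0.75):.3g}]"
    return GroupComparison(variable, test, float(stat), float(p), normal, fmt(a), fmt(b))


def cohort_table(sheet: SampleSheet) -> pd.DataFrame:
    """Group-comparison table over every clinical column in the sheet
    (sex by Fisher exact; numeric covariates by gated t / Mann-Whitney)."""
    rows = []
    labels = sheet.group
    comp = compare_groups(sheet.sex, labels, variable="sex", categorical=True)
    rows.append(comp)
    for col in sheet.df.columns:
        if col in ("group", "sex"):
            continue
        vals = pd.to_numeric(sheet.df[col], errors="coerce")
        mask = vals.notna()
        if mask.sum() < 6 or labels[mask].nunique() < 2:
            continue
        rows.append(compare_groups(vals[mask], labels[mask], variable=col))
    return pd.DataFrame(
        [
            {
                "variable": c.variable,
                "test": c.test,
                "statistic": c.statistic,
                "p": c.p_value,
                "normal": c.normal,
                "CNT": c.summary_a if labels.iloc[0] == "CNT" else c.summary_b,
                "iDCM": c.summary_b if labels.iloc[0] == "CNT" else c.summary_a,
            }
            for c in rows
        ]
    )


def correlate_with_clinical(
    log_expr: pd.DataFrame,
    sheet: SampleSheet,
    feature_ids,
    clinical_var: str = "LVEF",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Normality-gated correlation of each feature's (log) expression with a
    clinical covariate, within the patient group by default."""
    sub = sheet.df.loc[log_expr.columns]
    if not include_controls:
        keep = (sub["group"] == "iDCM").to_numpy()
    else:
        keep = np.ones(len(sub), bool)
    clin = pd.to_numeric(sub[clinical_var], errors="coerce").to_numpy()[keep]
    rows = []
    for fid in feature_ids:
        if fid not in log_expr.index:
            continue
        res = correlate(
            log_expr.loc[fid].to_numpy()[keep], clin,
            feature_id=fid, clinical_var=clinical_var,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(
        rows, columns=["feature_id", "clinical_var", "method", "r", "p_value", "n"]
    )
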