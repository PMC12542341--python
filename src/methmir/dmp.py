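"""Differential methylation: per-probe linear models with a sex covariate,
empirical-Bayes variance moderation, BH FDR, and a median-based delta-beta
effect filter.

The moderation shrinks each probe's residual variance s2_g (on d residual
degrees of freedom) toward a prior (d0, s0^2) estimated by matching the
first two moments of log s2_g to those of a scaled F distribution:

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)
    t_mod   = coef / (se_unit * sqrt(s2_post)),  df = d + d0

When the observed spread of log s2_g is no larger than expected from the
chi-square sampling noise alone, d0 is infinite and every probe gets the
pooled variance s0^2 (the t becomes a normal deviate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Per-feature least-squares fit against a shared design matrix."""

    feature_ids: pd.Index
    coef: pd.DataFrame          # features x design columns
    sigma2: np.ndarray          # residual variance per feature
    df_residual: int
    se_unit: pd.Series          # sqrt of diag((X'X)^-1) per column
    design_columns: list[str]


@dataclass
class VarianceShrinkage:
    """Estimated prior (d0, s0^2) and per-feature posterior variances."""

    d0: float                   # prior df; may be np.inf
    s0_sq: float
    s2_post: np.ndarray


def build_design(sheet: SampleSheet, include_sex: bool = True) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator (iDCM=1) + optional sex indicator (M=1)."""
    group = (sheet.group == "iDCM").to_numpy(float)
    n_idcm, n_cnt = int(group.sum()), int((1 - group).sum())
    if n_idcm < 2 or n_cnt < 2:
        raise ValidationError(
            f"need at least 2 samples per group (got CNT={n_cnt}, iDCM={n_idcm})"
        )
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if include_sex:
        sex = (sheet.sex == "M").to_numpy(float)
        if len(np.unique(sex)) < 2:
            warnings.warn("sex has a single level; dropping the sex covariate", stacklevel=2)
        else:
            X_try = np.column_stack([*cols, sex])
            if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
                raise ValidationError(
                    "design matrix is rank deficient (sex is confounded with group); "
                    "drop the sex covariate"
                )
            cols.append(sex)
            names.append("sex")
    return np.column_stack(cols), names


def _fit(values: np.ndarray, X: np.ndarray, names: list[str], ids: pd.Index) -> ModelFit:
    n, p = X.shape
    if n - p <= 0:
        raise ValidationError(f"no residual degrees of freedom (n={n}, design columns={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T                        # p x n
    coef = values @ pinv.T                      # features x p
    resid = values - coef @ X.T
    sigma2 = (resid ** 2).sum(axis=1) / (n - p)
    se_unit = pd.Series(np.sqrt(np.diag(xtx_inv)), index=names)
    return ModelFit(
        feature_ids=ids,
        coef=pd.DataFrame(coef, index=ids, columns=names),
        sigma2=sigma2,
        df_residual=n - p,
        se_unit=se_unit,
        design_columns=names,
    )


def fit_linear_models(beta: BetaMatrix, sheet: SampleSheet, include_sex: bool = True) -> ModelFit:
    """Fit the shared (intercept, group, sex) design to every probe by OLS."""
    sub = sheet.df.loc[beta.sample_ids]
    X, names = build_design(SampleSheet(sub), include_sex=include_sex)
    return _fit(beta.values.to_numpy(float), X, names, beta.probe_ids)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def ebayes_moderate(fit: ModelFit) -> VarianceShrinkage:
    """Moment-match log residual variances to a scaled F prior and shrink.

    Returns the prior df d0 (possibly infinite), prior variance s0^2, and
    the posterior variances s2_post used by the moderated t.
    """
    s2 = np.asarray(fit.sigma2, float)
    d = float(fit.df_residual)
    if len(s2) < 2:
        raise ValidationError("need at least 2 features to moderate variances")
    m = np.median(s2)
    if m == 0:
        raise ValidationError("all residual variances are zero; nothing to moderate")
    if (s2 == 0).any():
        warnings.warn("zero residual variances offset away from zero", stacklevel=2)
    x = np.maximum(s2, 1e-5 * m)
    z = np.log(x)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # log-variance spread no larger than chi-square sampling noise:
        # the prior is a point mass and the pooled mean estimates it
        d0 = np.inf
        s0_sq = float(x.mean())
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    return VarianceShrinkage(d0=d0, s0_sq=s0_sq, s2_post=s2_post)


def moderated_t(
    fit: ModelFit, shrink: VarianceShrinkage, coef: str = "group"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t statistic and two-sided p for one design coefficient."""
    b = fit.coef[coef].to_numpy(float)
    se = fit.se_unit[coef] * np.sqrt(shrink.s2_post)
    df_total = fit.df_residual + shrink.d0
    t = np.zeros_like(b)
    nonzero_se = se > 0
    t[nonzero_se] = b[nonzero_se] / se[nonzero_se]
    degenerate = (~nonzero_se) & (b != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero posterior variance; p set to 0",
            stacklevel=2,
        )
        t[degenerate] = np.sign(b[degenerate]) * np.inf
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[b == 0] = 1.0
    return t, p, float(df_total)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_beta(beta: BetaMatrix, sheet: SampleSheet) -> pd.Series:
    """Median beta in iDCM minus median beta in CNT, per probe."""
    sub = sheet.df.loc[beta.sample_ids]
    idcm = beta.values.loc[:, (sub["group"] == "iDCM").to_numpy()]
    cnt = beta.values.loc[:, (sub["group"] == "CNT").to_numpy()]
    return idcm.median(axis=1) - cnt.median(axis=1)


def exclude_sex_dependent_probes(
    fit: ModelFit,
    beta: BetaMatrix,
    sheet: SampleSheet,
    fdr: float = 0.05,
) -> tuple[BetaMatrix, pd.Index]:
    """Remove probes whose sex coefficient is significant (BH FDR < ``fdr``)
    and residualize the sex effect out of the remaining betas.

    Adjustment subtracts coef_sex * (sex_indicator - mean sex_indicator)
    and clips back to [0, 1], preserving the beta scale.
    """
    if "sex" not in fit.design_columns:
        return beta, pd.Index([], name="probe_id")
    shrink = ebayes_moderate(fit)
    _, p_sex, _ = moderated_t(fit, shrink, coef="sex")
    q_sex = bh_adjust(p_sex)
    excluded = beta.probe_ids[q_sex < fdr]
    sub = sheet.df.loc[beta.sample_ids]
    sex = (sub["sex"] == "M").to_numpy(float)
    centered = sex - sex.mean()
    coef_sex = fit.coef["sex"].to_numpy(float)[:, None]
    adjusted = beta.values.to_numpy(float) - coef_sex * centered[None, :]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    adj = pd.DataFrame(adjusted, index=beta.probe_ids, columns=beta.sample_ids)
    adj = adj.drop(index=excluded)
    logger.info("excluded %d sex-dependent probe(s)", len(excluded))
    return BetaMatrix(adj), excluded


def call_dmps(
    probe_ids: pd.Index,
    annotation: ProbeAnnotation,
    db: pd.Series,
    t: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    fdr: float = 0.05,
    min_delta_beta: float = 0.10,
) -> pd.DataFrame:
    """Assemble the per-probe result table and apply the significance rule:
    FDR strictly below the cutoff AND |delta beta| at or above the floor."""
    annot = annotation.df.reindex(probe_ids)
    direction = np.where(db > 0, "hyper", np.where(db < 0, "hypo", "none"))
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": annot["chrom"].to_numpy(),
            "pos": annot["pos"].to_numpy(),
            "delta_beta": db.to_numpy(),
            "t_mod": t,
            "p": p,
            "fdr": q,
            "direction": direction,
        }
    )
    table["significant"] = (table["fdr"] < fdr) & (table["delta_beta"].abs() >= min_delta_beta)
    return table


def run_dmp_analysis(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    sheet: SampleSheet,
    fdr: float = 0.05,
    min_delta_beta: float = 0.10,
    flip_delta: bool = False,
    sex_adjust: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full differential-methylation stage.

    Fits the sex-adjusted linear model, drops sex-dependent probes,
    residualizes sex out of the remaining betas, refits, moderates, and
    calls DMPs at ``fdr`` / ``min_delta_beta``.  ``flip_delta`` reverses
    the delta-beta sign convention (CNT - iDCM instead of iDCM - CNT).
    """
    fit1 = fit_linear_models(beta, sheet, include_sex=sex_adjust)
    if sex_adjust and "sex" in fit1.design_columns:
        adj_beta, excluded = exclude_sex_dependent_probes(fit1, beta, sheet, fdr=fdr)
    else:
        adj_beta, excluded = beta, pd.Index([])
    fit2 = fit_linear_models(adj_beta, sheet, include_sex=sex_adjust)
    shrink = ebayes_moderate(fit2)
    t, p, _ = moderated_t(fit2, shrink, coef="group")
    q = bh_adjust(p)
    db = delta_beta(adj_beta, sheet)
    if flip_delta:
        db = -db
    table = call_dmps(adj_beta.probe_ids, annotation, db, t, p, q, fdr, min_delta_beta)
    sig = table[table["significant"]]
    summary = {
        "n_probes_tested": len(table),
        "n_excluded_sex_dependent": len(excluded),
        "n_significant": int(len(sig)),
        "n_hyper": int((sig["direction"] == "hyper").sum()),
        "n_hypo": int((sig["direction"] == "hypo").sum()),
        "d0": shrink.d0,
        "s0_sq": shrink.s0_sq,
    }
    return table, summary
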