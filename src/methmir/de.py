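"""Differential expression of pri- and mature miRNAs.

Counts are normalized per sample (median-of-ratios size factors by
default, plain CPM available); the fold change is the ratio of group means
on the normalized scale (matching how the cohort tables report FC), while
the test statistic is a moderated t on log2(normalized + 0.5) with a
group-only design, reusing the variance-shrinkage engine from the
methylation stage.  BH correction is applied separately within the pri and
mature universes.

Median-of-ratios is the default because per-library-size scaling (CPM) is
not robust to composition shifts: when a subset of features carries a
large expression change in one group, the inflated library size drags
every other feature's CPM in the opposite direction and manufactures
spurious fold changes.  Size factors anchored on the median ratio to a
geometric-mean reference ignore the shifted minority.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import SampleSheet, _fit, bh_adjust, build_design, ebayes_moderate, moderated_t
from .io import CountMatrix, PriMatureMap, ValidationError


def cpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = counts.counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total counts")
    return counts.counts / lib * 1e6


def median_ratio_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Median-of-ratios normalization, rescaled to a counts-per-million scale.

    Size factor per sample = median over all-positive features of
    count / geometric-mean reference; falls back to CPM when no feature is
    positive in every sample.  The output is rescaled so the mean sample
    total is 1e6, keeping values comparable with CPM.
    """
    c = counts.counts.to_numpy(float)
    lib = c.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[np.argmax(lib == 0)]
        raise ValidationError(f"sample {bad!r} has zero total counts")
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no feature observed in every sample; falling back to library-size "
            "normalization", stacklevel=2,
        )
        return cpm_normalize(counts)
    log_ref = np.log(c[all_pos]).mean(axis=1)
    size = np.exp(np.median(np.log(c[all_pos]) - log_ref[:, None], axis=0))
    normed = c / size[None, :]
    normed *= 1e6 / normed.sum(axis=0).mean()
    return pd.DataFrame(normed, index=counts.feature_ids, columns=counts.sample_ids)


def normalize(counts: CountMatrix, method: str = "median_ratio") -> pd.DataFrame:
    if method == "median_ratio":
        return median_ratio_normalize(counts)
    if method == "cpm":
        return cpm_normalize(counts)
    raise ValidationError(f"unknown normalization {method!r}")


def fold_change(normed: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """FC = mean(iDCM) / mean(CNT) per feature, with log2FC.

    Features with zero CNT mean get NaN fc and are flagged (excluded from
    significance calling downstream).
    """
    sub = sheet.df.loc[normed.columns]
    mean_idcm = normed.loc[:, (sub["group"] == "iDCM").to_numpy()].mean(axis=1)
    mean_cnt = normed.loc[:, (sub["group"] == "CNT").to_numpy()].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_idcm / mean_cnt
        fc = fc.where(mean_cnt > 0, np.nan)
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "mean_idcm": mean_idcm,
            "mean_cnt": mean_cnt,
            "fc": fc,
            "log2fc": log2fc,
            "fc_defined": (mean_cnt > 0).to_numpy(),
        }
    )


def de_test(normed: pd.DataFrame, sheet: SampleSheet, method: str = "moderated_t") -> np.ndarray:
    """Two-sided p-value per feature on log2(CPM + 0.5), group-only design.

    ``method`` is "moderated_t" (default, shared eBayes engine) or
    "mann_whitney".
    """
    sub = SampleSheet(sheet.df.loc[normed.columns])
    y = np.log2(normed.to_numpy(float) + 0.5)
    if method == "mann_whitney":
        g = (sub.group == "iDCM").to_numpy()
        p = np.empty(y.shape[0])
        for i in range(y.shape[0]):
            a, b = y[i, g], y[i, ~g]
            if np.ptp(y[i]) == 0:
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        return p
    if method != "moderated_t":
        raise ValidationError(f"unknown DE test {method!r}")
    X, names = build_design(sub, include_sex=False)
    fit = _fit(y, X, names, normed.index)
    constant = np.ptp(y, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); their p-values are 1", stacklevel=2
        )
    shrink = ebayes_moderate(fit)
    _, p, _ = moderated_t(fit, shrink, coef="group")
    p[constant] = 1.0
    return p


def call_de(
    fc_table: pd.DataFrame,
    p: np.ndarray,
    kind: str,
    fdr: float = 0.05,
    lfc: float = 0.6,
) -> pd.DataFrame:
    """Joint log2FC / FDR calling: |log2FC| >= lfc (inclusive) AND FDR < fdr (strict)."""
    defined = fc_table["fc_defined"].to_numpy()
    q = np.full(len(fc_table), np.nan)
    q[defined] = bh_adjust(p[defined])
    with np.errstate(divide="ignore"):
        neg_log10_fdr = np.where(q > 0, -np.log10(q), np.inf)
    log2fc = fc_table["log2fc"].to_numpy()
    sig = defined & (q < fdr) & (np.abs(log2fc) >= lfc)
    table = pd.DataFrame(
        {
            "feature_id": fc_table.index,
            "feature_kind": kind,
            "fc": fc_table["fc"].to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "fdr": q,
            "neg_log10_fdr": neg_log10_fdr,
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": sig,
        }
    )
    return table


def run_de_analysis(
    counts: CountMatrix,
    sheet: SampleSheet,
    fdr: float = 0.05,
    lfc: float = 0.6,
    method: str = "moderated_t",
    norm: str = "median_ratio",
) -> pd.DataFrame:
    """Normalize, compute FC on the normalized scale, test, and call."""
    normed = normalize(counts, norm)
    fc_table = fold_change(normed, sheet)
    p = de_test(normed, sheet, method=method)
    return call_de(fc_table, p, counts.kind, fdr=fdr, lfc=lfc)


def pair_pri_mature(
    pri_table: pd.DataFrame,
    mature_table: pd.DataFrame,
    pmap: PriMatureMap,
) -> pd.DataFrame:
    """Pairs where both the pri gene and the mature product are significant.

    Mature features without a mapping row raise a warning and are skipped;
    the result is sorted (gene_id, mature_id) so it is independent of
    input row order.
    """
    mature_sig = mature_table[mature_table["significant"]]
    unmapped = set(mature_sig["feature_id"]) - set(pmap.df["mature_id"])
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} significant mature miRNA(s) without a pri mapping: "
            f"{sorted(unmapped)[:5]}",
            stacklevel=2,
        )
    pri_sig = pri_table[pri_table["significant"]].set_index("feature_id")
    rows = []
    for _, m in mature_sig.iterrows():
        gene = pmap.gene_of(m["feature_id"])
        if gene is None or gene not in pri_sig.index:
            continue
        pri = pri_sig.loc[gene]
        rows.append(
            {
                "gene_id": gene,
                "mature_id": m["feature_id"],
                "pri_fc": pri["fc"],
                "pri_log2fc": pri["log2fc"],
                "pri_fdr": pri["fdr"],
                "mature_fc": m["fc"],
                "mature_log2fc": m["log2fc"],
                "mature_fdr": m["fdr"],
                "pri_direction": pri["direction"],
                "mature_direction": m["direction"],
                "concordant_direction": pri["direction"] == m["direction"],
            }
        )
    cols = [
        "gene_id", "mature_id", "pri_fc", "pri_log2fc", "pri_fdr",
        "mature_fc", "mature_log2fc", "mature_fdr",
        "pri_direction", "mature_direction", "concordant_direction",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["gene_id", "mature_id"]).reset_index(drop=True)
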