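"""Promoter-window integration of DMPs with differentially expressed miRNAs.

Each DE pri-miRNA gene gets a promoter window of +/- 20 kb around its
highest-scoring TSS (1-based, inclusive on both ends, floored at 1).
Significant DMPs falling inside a window are attributed to that gene; a
probe may belong to several overlapping windows.  Each (DMP, gene) pair is
classified against the gene's expression direction: hypomethylation with
upregulation or hypermethylation with downregulation is the canonical
pattern; the opposite pairing is non-canonical; a gene whose member DMPs
disagree is labelled mixed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ProbeAnnotation, PriMatureMap, TssAnnotation, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20_000


def build_windows(tss: TssAnnotation, de_genes, flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """One [tss - flank, tss + flank] window per DE gene with a known TSS.

    The flank is symmetric, so strand does not change the window; start is
    floored at 1.  Genes without a TSS row are logged and skipped.
    """
    de_genes = list(de_genes)
    missing = [g for g in de_genes if g not in tss.df.index]
    if missing:
        logger.info("%d DE gene(s) lack a TSS annotation: %s", len(missing), missing[:5])
    present = [g for g in de_genes if g in tss.df.index]
    sub = tss.df.loc[present]
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "chrom": sub["chrom"].to_numpy(),
            "start": np.maximum(1, sub["tss"].to_numpy() - flank),
            "end": sub["tss"].to_numpy() + flank,
            "tss": sub["tss"].to_numpy(),
        }
    ).reset_index(drop=True)


def assign_dmps(
    windows: pd.DataFrame,
    dmps: pd.DataFrame,
    annotation: ProbeAnnotation | None = None,
) -> pd.DataFrame:
    """Attribute significant DMPs to promoter windows (inclusive bounds).

    ``dmps`` must carry probe_id, chrom, pos and delta_beta columns (the
    significant subset of the DMP table).  Probes are indexed per
    chromosome and looked up by binary search, so overlapping windows each
    receive their own copy of a shared probe.
    """
    if len(windows) and len(dmps):
        if not set(windows["chrom"]) & set(dmps["chrom"]):
            raise ValidationError(
                "no chromosome names shared between TSS windows and probe annotation; "
                "check the naming convention (e.g. 'chr1' vs '1')"
            )
    rows = []
    by_chrom = {}
    for chrom, grp in dmps.groupby("chrom"):
        grp = grp.sort_values("pos")
        by_chrom[chrom] = (grp["pos"].to_numpy(), grp)
    for w in windows.itertuples(index=False):
        if w.chrom not in by_chrom:
            continue
        pos, grp = by_chrom[w.chrom]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        for _, probe in grp.iloc[lo:hi].iterrows():
            rows.append(
                {
                    "gene_id": w.gene_id,
                    "probe_id": probe["probe_id"],
                    "chrom": w.chrom,
                    "pos": int(probe["pos"]),
                    "delta_beta": probe["delta_beta"],
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "probe_id", "chrom", "pos", "delta_beta"])
    return out.sort_values(["gene_id", "probe_id"]).reset_index(drop=True)


def classify_pair(delta_beta: float, expression_direction: str) -> str:
    """Canonical when methylation and expression move oppositely."""
    hypo = delta_beta < 0
    up = expression_direction == "up"
    return "canonical" if hypo == up else "non_canonical"


def summarize_integration(
    pairs: pd.DataFrame,
    de_table: pd.DataFrame,
    pmap: PriMatureMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-gene summary (AΔβ = mean member Δβ, concordance label) plus the
    overall canonical fraction over (DMP, gene) pairs."""
    directions = de_table.set_index("feature_id")["direction"]
    gene_rows = []
    n_canonical = 0
    n_total = 0
    pair_labels = []
    for _, row in pairs.iterrows():
        label = classify_pair(row["delta_beta"], directions.get(row["gene_id"], "up"))
        pair_labels.append(label)
        n_total += 1
        n_canonical += label == "canonical"
    pairs = pairs.assign(concordance=pair_labels)
    for gene, grp in pairs.groupby("gene_id"):
        labels = set(grp["concordance"])
        gene_label = labels.pop() if len(labels) == 1 else "mixed"
        matures = pmap.matures_of(gene) if pmap is not None else []
        gene_rows.append(
            {
                "gene_id": gene,
                "mature_ids": ",".join(matures),
                "n_dmps": len(grp),
                "a_delta_beta": grp["delta_beta"].mean(),
                "expression_direction": directions.get(gene, "up"),
                "concordance": gene_label,
            }
        )
    summary = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "mature_ids", "n_dmps", "a_delta_beta",
                 "expression_direction", "concordance"],
    ).sort_values("gene_id").reset_index(drop=True)
    stats = {
        "n_pairs": n_total,
        "n_canonical": n_canonical,
        "n_non_canonical": n_total - n_canonical,
        "canonical_fraction": n_canonical / n_total if n_total else float("nan"),
    }
    return pairs, summary, stats


def run_integration(
    dmp_table: pd.DataFrame,
    de_table: pd.DataFrame,
    tss: TssAnnotation,
    pmap: PriMatureMap | None = None,
    flank: int = DEFAULT_FLANK,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Windows for significant DE genes, DMP assignment, and concordance."""
    de_genes = de_table.loc[de_table["significant"], "feature_id"].tolist()
    windows = build_windows(tss, de_genes, flank=flank)
    sig_dmps = dmp_table[dmp_table["significant"]]
    pairs = assign_dmps(windows, sig_dmps)
    pairs, summary, stats = summarize_integration(pairs, de_table, pmap)
    stats["n_de_genes"] = len(de_genes)
    stats["n_de_genes_with_dmp"] = int(summary["gene_id"].nunique())
    return pairs, summary, stats
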