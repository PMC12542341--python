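"""Hypergeometric gene-set enrichment and high-confidence miRNA target selection.

Enrichment tests each term for over-representation of a query gene list
against a background universe: with N universe genes, K of them in the
term, and a query of size n containing k term genes, the p-value is the
upper tail P(X >= k) of the hypergeometric distribution.  Target selection
keeps miRNA-gene interactions scoring at or above a threshold in the first
prediction table and also present in the second (dual-database
intersection).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust
from .io import ValidationError


def hypergeom_enrich(
    query,
    gene_sets: dict[str, list[str]],
    universe=None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    ``universe`` defaults to the union of all genes in ``gene_sets``.
    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe.  BH correction is applied across terms.
    """
    query = set(query)
    if not query:
        raise ValidationError("empty query gene list")
    if universe is None:
        universe = set().union(*(set(g) for g in gene_sets.values()))
    else:
        universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) not in universe were dropped", stacklevel=2
        )
        query &= universe
    if not query:
        raise ValidationError("no query genes remain after intersecting with the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(gene_sets):
        term_genes = set(gene_sets[term]) & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def select_targets(
    db1_table: pd.DataFrame,
    db2_genes,
    min_score: float = 95.0,
) -> pd.DataFrame:
    """High-confidence targets: db1 score >= ``min_score`` (inclusive) AND
    predicted by db2 as well.

    ``db1_table`` needs mature_id, gene_symbol and score columns;
    ``db2_genes`` is an iterable of gene symbols (list membership) or a
    DataFrame with mature_id/gene_symbol columns for per-pair membership.
    """
    for col in ("mature_id", "gene_symbol", "score"):
        if col not in db1_table.columns:
            raise ValidationError(f"target table missing column {col!r}")
    out = db1_table[["mature_id", "gene_symbol", "score"]].copy()
    if isinstance(db2_genes, pd.DataFrame):
        pairs = set(zip(db2_genes["mature_id"], db2_genes["gene_symbol"]))
        present = [
            (m, g) in pairs for m, g in zip(out["mature_id"], out["gene_symbol"])
        ]
    else:
        db2 = set(db2_genes)
        present = out["gene_symbol"].isin(db2).tolist()
    out["present_db2"] = present
    out["high_confidence"] = (out["score"] >= min_score) & out["present_db2"]
    return out.sort_values(["mature_id", "gene_symbol"]).reset_index(drop=True)
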