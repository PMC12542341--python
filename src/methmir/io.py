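"""Data model, validation, and readers/writers for every table the pipeline touches.

All tabular inputs are TSV with a header row; TSS annotations are BED6
(0-based half-open, converted to 1-based inclusive at the boundary); gene
sets are GMT.  Internal genomic coordinates are 1-based inclusive,
matching the Illumina manifest convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("CNT", "iDCM")
SEXES = ("M", "F")


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-sample metadata: group (CNT/iDCM), sex, and clinical covariates.

    ``df`` is indexed by sample_id; clinical covariates (e.g. LVEF, in
    percent) are numeric columns and may contain missing values for
    samples where the measurement does not exist (e.g. LVEF for donors).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicated sample_id {dup!r} in sample sheet")
        for col in ("group", "sex"):
            if col not in self.df.columns:
                raise ValidationError(f"sample sheet missing required column {col!r}")
            if self.df[col].isna().any():
                bad = self.df.index[self.df[col].isna()][0]
                raise ValidationError(f"missing {col} for sample {bad!r}")
        bad_group = set(self.df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group label(s) {sorted(bad_group)}; expected {GROUPS}")
        bad_sex = set(self.df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex label(s) {sorted(bad_sex)}; expected {SEXES}")
        if "LVEF" in self.df.columns:
            lvef = pd.to_numeric(self.df["LVEF"], errors="coerce")
            present = lvef.notna()
            if ((lvef[present] <= 0) | (lvef[present] > 100)).any():
                bad = self.df.index[present & ((lvef <= 0) | (lvef > 100))][0]
                raise ValidationError(f"LVEF out of (0, 100] for sample {bad!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def group(self) -> pd.Series:
        return self.df["group"]

    @property
    def sex(self) -> pd.Series:
        return self.df["sex"]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.df["group"] == group).to_numpy()

    def covariate(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise ValidationError(f"sample sheet has no covariate {name!r}")
        return pd.to_numeric(self.df[name], errors="coerce")


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples), each in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError(f"duplicated probe id {v.index[v.index.duplicated()][0]!r}")
        if v.columns.duplicated().any():
            raise ValidationError(f"duplicated sample id {v.columns[v.columns.duplicated()][0]!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("beta matrix contains non-numeric values")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing beta value at probe {v.index[i]!r}, sample {v.columns[j]!r}; "
                "NA values are not supported"
            )
        if (arr < 0).any() or (arr > 1).any():
            i, j = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValidationError(
                f"beta value {arr[i, j]} out of [0, 1] at probe {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProbeAnnotation:
    """Genomic location (chrom, 1-based pos) of each methylation probe."""

    df: pd.DataFrame  # columns: chrom, pos; indexed by probe_id

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError(
                f"duplicated probe id {self.df.index[self.df.index.duplicated()][0]!r} in annotation"
            )
        pos = self.df["pos"]
        if (pos < 1).any():
            bad = self.df.index[pos < 1][0]
            raise ValidationError(f"probe {bad!r} has position < 1")


@dataclass
class CountMatrix:
    """Raw sequencing counts (features x samples), tagged pri or mature."""

    counts: pd.DataFrame
    kind: str  # "pri" | "mature"

    def __post_init__(self) -> None:
        if self.kind not in ("pri", "mature"):
            raise ValidationError(f"feature_kind must be 'pri' or 'mature', got {self.kind!r}")
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError(f"duplicated feature id {c.index[c.index.duplicated()][0]!r}")
        arr = c.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("count matrix contains missing values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class TssAnnotation:
    """One transcription start site per miRNA gene (highest-scoring prediction)."""

    df: pd.DataFrame  # columns: chrom, tss, strand, score; indexed by gene_id

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError(
                f"duplicated gene id {self.df.index[self.df.index.duplicated()][0]!r} in TSS table"
            )
        if (self.df["tss"] < 1).any():
            bad = self.df.index[self.df["tss"] < 1][0]
            raise ValidationError(f"gene {bad!r} has TSS < 1")
        bad_strand = set(self.df["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"invalid strand value(s) {sorted(bad_strand)}")


@dataclass
class PriMatureMap:
    """Mapping from pri-miRNA gene (e.g. MIR433) to mature miRNA(s)."""

    df: pd.DataFrame  # columns: gene_id, mature_id

    def __post_init__(self) -> None:
        if self.df["mature_id"].duplicated().any():
            bad = self.df["mature_id"][self.df["mature_id"].duplicated()].iloc[0]
            raise ValidationError(f"mature id {bad!r} maps to more than one gene")

    def gene_of(self, mature_id: str) -> str | None:
        hit = self.df.loc[self.df["mature_id"] == mature_id, "gene_id"]
        return None if hit.empty else hit.iloc[0]

    def matures_of(self, gene_id: str) -> list[str]:
        return self.df.loc[self.df["gene_id"] == gene_id, "mature_id"].tolist()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("sample sheet must have a 'sample_id' column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def _align_samples(df: pd.DataFrame, sheet: SampleSheet, what: str) -> pd.DataFrame:
    extra = set(df.columns) - set(sheet.sample_ids)
    if extra:
        raise ValidationError(f"{what} sample(s) {sorted(extra)} not in sample sheet")
    # keep the sheet's sample ordering, restricted to samples present
    order = [s for s in sheet.sample_ids if s in df.columns]
    return df[order]


def read_beta_matrix(path, annotation_path, sheet: SampleSheet) -> tuple[BetaMatrix, ProbeAnnotation]:
    """Read a probes-x-samples beta TSV plus a probe annotation TSV.

    Probes without annotation are dropped (the count is logged); sample
    columns are reordered to match the sheet.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = _align_samples(df, sheet, "beta matrix")
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "pos"):
        if col not in annot.columns:
            raise ValidationError(f"probe annotation missing column {col!r}")
    annot = annot.set_index("probe_id")
    unannotated = df.index.difference(annot.index)
    if len(unannotated):
        logger.info("dropping %d probe(s) without genomic annotation", len(unannotated))
        df = df.drop(index=unannotated)
    annot = annot.loc[df.index, ["chrom", "pos"]]
    return BetaMatrix(df), ProbeAnnotation(annot)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    out = beta.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    out = annot.df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_counts(path, sheet: SampleSheet, kind: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = _align_samples(df, sheet, f"{kind} count matrix")
    return CountMatrix(df, kind)


def write_counts(counts: CountMatrix, path) -> None:
    out = counts.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_pri_mature_map(path) -> PriMatureMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "mature_id"):
        if col not in df.columns:
            raise ValidationError(f"pri/mature map missing column {col!r}")
    return PriMatureMap(df[["gene_id", "mature_id"]])


def write_pri_mature_map(pmap: PriMatureMap, path) -> None:
    pmap.df.to_csv(path, sep="\t", index=False)


def read_tss_bed(path) -> TssAnnotation:
    """Parse a BED6 TSS prediction table into one 1-based TSS per gene.

    BED is 0-based half-open; the TSS is start+1 on '+' and end on '-'.
    Where a gene has several predictions the highest-scoring row is kept
    (ties broken by smallest coordinate, then lexicographic chrom).
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str},
    )
    if df["strand"].isna().any() or (set(df["strand"]) - {"+", "-"}):
        raise ValidationError("BED row with missing or invalid strand")
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"BED interval with start >= end for gene {row['gene_id']!r} "
            f"({row['chrom']}:{row['start']}-{row['end']})"
        )
    df["tss"] = np.where(df["strand"] == "+", df["start"] + 1, df["end"])
    df = df.sort_values(
        ["gene_id", "score", "tss", "chrom"], ascending=[True, False, True, True]
    )
    best = df.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    return TssAnnotation(best[["chrom", "tss", "strand", "score"]])


def write_tss_bed(tss: TssAnnotation, path) -> None:
    """Write the TSS table back to BED6 (exact inverse of read_tss_bed)."""
    df = tss.df.reset_index()
    start = np.where(df["strand"] == "+", df["tss"] - 1, df["tss"] - 1)
    end = start + 1
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": start.astype(int),
            "end": end.astype(int),
            "gene_id": df["gene_id"],
            "score": df["score"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into {term: [genes]} (order-preserving, deduplicated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno}: term {fields[0]!r} has an empty gene list")
            term = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"GMT line {lineno}: term {term!r} has an empty gene list")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            sets[term] = list(seen)
    if not sets:
        raise ValidationError("GMT file contains no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, "na", *genes]) + "\n")
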