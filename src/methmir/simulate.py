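"""Seeded generator for every pipeline input, with planted, recorded truth.

The generator emulates the study design this pipeline targets: a
methylation cohort of left-ventricle samples (beta values in [0, 1] with
group shifts at planted differentially methylated positions, a hypo-
methylation majority, and a handful of sex-dependent probes), small-RNA
negative-binomial count matrices for pri- and mature miRNAs with spiked
fold changes (mature features inherit their pri gene's status), a
miRStart-style TSS table whose promoter windows contain planted DMPs for a
subset of the spiked genes, a clinical sheet with an LVEF variable carrying
a planted correlation to one mature miRNA, and gene-set / target-prediction
tables for the enrichment stage.

All randomness flows through one ``numpy.random.Generator`` derived from
the config seed; the same seed reproduces every table bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    CountMatrix,
    PriMatureMap,
    ProbeAnnotation,
    SampleSheet,
    TssAnnotation,
    ValidationError,
    write_beta_matrix,
    write_counts,
    write_gmt,
    write_pri_mature_map,
    write_probe_annotation,
    write_sample_sheet,
    write_tss_bed,
)

CHROMS = [f"chr{i}" for i in range(1, 6)]
CHROM_LEN = 20_000_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the regimes the pipeline is designed for: per-group
    sizes of a small tissue cohort, |delta beta| 0.15 shifts with a 70%
    hypomethylation majority, fold-change 3.5 count spikes with negative-
    binomial dispersion 0.1, promoter DMPs for 3 of every 4 spiked genes,
    and a planted miRNA-LVEF correlation of 0.67.
    """

    n_probes: int = 5000
    n_features_pri: int = 300
    n_features_mature: int = 300
    n_cnt: int = 9
    n_idcm: int = 20
    n_true_dmps: int = 200
    dmp_effect: float = 0.15
    hypo_fraction: float = 0.70
    n_sex_probes: int = 50
    sex_effect: float = 0.30
    n_true_de: int = 20
    de_fc: float = 3.5
    nb_dispersion: float = 0.1
    beta_concentration: float = 50.0
    # (a, b) of the Beta distribution the per-probe baseline means are drawn
    # from, one pair per methylation class (hypo / intermediate / hyper)
    baseline_beta_params: tuple = ((2.0, 10.0), (10.0, 10.0), (10.0, 2.0))
    promoter_gene_fraction: float = 0.75
    planted_corr: float = 0.67
    lvef_mean: float = 19.0
    lvef_sd: float = 8.0
    male_fraction_idcm: float = 0.80
    male_fraction_cnt: float = 0.65
    flank: int = 20_000
    n_universe_genes: int = 400
    n_terms: int = 15
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_features_pri", "n_features_mature",
                     "n_cnt", "n_idcm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.dmp_effect < 0.5:
            raise ValidationError("dmp_effect must keep group means inside (0, 1)")
        if not abs(self.planted_corr) < 1:
            raise ValidationError("planted_corr must satisfy |r| < 1")
        if self.n_true_dmps + self.n_sex_probes > self.n_probes:
            raise ValidationError("more planted probes than probes")
        if self.n_true_de > self.n_features_pri:
            raise ValidationError("more spiked DE genes than pri features")
        n_promoter = round(self.promoter_gene_fraction * self.n_true_de)
        if n_promoter > self.n_true_dmps:
            raise ValidationError(
                "not enough planted DMPs to dedicate one per promoter gene"
            )


@dataclass
class SimulationTruth:
    """Planted ground truth recorded alongside the generated tables."""

    true_dmp_probes: dict        # probe_id -> signed planted delta beta
    sex_probes: list
    true_de_genes: dict          # gene_id -> planted FC
    true_de_mature: dict         # mature_id -> planted FC
    promoter_dmp_map: dict       # gene_id -> [probe_id, ...]
    correlated_feature: str
    planted_corr: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sheet: SampleSheet
    beta: BetaMatrix
    annotation: ProbeAnnotation
    pri_counts: CountMatrix
    mature_counts: CountMatrix
    pmap: PriMatureMap
    tss: TssAnnotation
    gene_sets: dict
    targets_db1: pd.DataFrame
    targets_db2: pd.DataFrame
    truth: SimulationTruth


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"CNT{i + 1:02d}" for i in range(cfg.n_cnt)]
    ids += [f"DCM{i + 1:02d}" for i in range(cfg.n_idcm)]
    is_idcm = np.array([0] * cfg.n_cnt + [1] * cfg.n_idcm, bool)
    return ids, is_idcm


def _assign_sex(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic male counts per group (shuffled within group)."""
    n_male_cnt = max(1, round(cfg.male_fraction_cnt * cfg.n_cnt))
    n_male_idcm = max(1, round(cfg.male_fraction_idcm * cfg.n_idcm))
    sex = np.array(
        ["M"] * n_male_cnt + ["F"] * (cfg.n_cnt - n_male_cnt)
        + ["M"] * n_male_idcm + ["F"] * (cfg.n_idcm - n_male_idcm)
    )
    cnt_order = rng.permutation(cfg.n_cnt)
    idcm_order = cfg.n_cnt + rng.permutation(cfg.n_idcm)
    return np.concatenate([sex[:cfg.n_cnt][cnt_order], sex[cfg.n_cnt:][idcm_order - cfg.n_cnt]])


def simulate_methylation(
    cfg: SimulationConfig, rng: np.random.Generator, is_idcm: np.ndarray, is_male: np.ndarray,
    sample_ids: list[str],
) -> tuple[BetaMatrix, ProbeAnnotation, dict, list]:
    """Beta matrix with planted group shifts and sex-dependent probes.

    Per-probe baseline means come from a three-class Beta mixture; each
    sample's value is Beta-distributed with the probe's (group, sex)
    specific mean and a shared concentration, so values stay in [0, 1] by
    construction.
    """
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    classes = rng.integers(0, len(cfg.baseline_beta_params), cfg.n_probes)
    base = np.empty(cfg.n_probes)
    for c, (a, b) in enumerate(cfg.baseline_beta_params):
        mask = classes == c
        base[mask] = rng.beta(a, b, mask.sum())
    planted = rng.choice(cfg.n_probes, cfg.n_true_dmps + cfg.n_sex_probes, replace=False)
    dmp_idx = planted[: cfg.n_true_dmps]
    sex_idx = planted[cfg.n_true_dmps:]
    # keep shifted means well inside (0, 1)
    margin = max(cfg.dmp_effect, cfg.sex_effect) + 0.05
    base[planted] = rng.uniform(margin, 1 - margin, len(planted))
    n_hypo = round(cfg.hypo_fraction * cfg.n_true_dmps)
    signs = np.array([-1.0] * n_hypo + [1.0] * (cfg.n_true_dmps - n_hypo))
    rng.shuffle(signs)
    group_shift = np.zeros(cfg.n_probes)
    group_shift[dmp_idx] = signs * cfg.dmp_effect
    sex_shift = np.zeros(cfg.n_probes)
    sex_shift[sex_idx] = cfg.sex_effect * rng.choice([-1.0, 1.0], cfg.n_sex_probes)
    mean = (
        base[:, None]
        + group_shift[:, None] * is_idcm[None, :].astype(float)
        + sex_shift[:, None] * is_male[None, :].astype(float)
    )
    mean = np.clip(mean, 0.01, 0.99)
    c = cfg.beta_concentration
    values = rng.beta(mean * c, (1 - mean) * c)
    chrom = rng.choice(CHROMS, cfg.n_probes)
    pos = rng.integers(1, CHROM_LEN, cfg.n_probes)
    beta = BetaMatrix(pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                                   columns=sample_ids))
    annot = ProbeAnnotation(pd.DataFrame(
        {"chrom": chrom, "pos": pos}, index=pd.Index(probe_ids, name="probe_id")
    ))
    truth_dmps = {probe_ids[i]: float(group_shift[i]) for i in dmp_idx}
    sex_probes = [probe_ids[i] for i in sex_idx]
    return beta, annot, truth_dmps, sex_probes


def simulate_counts(
    cfg: SimulationConfig, rng: np.random.Generator, is_idcm: np.ndarray, sample_ids: list[str],
) -> tuple[CountMatrix, CountMatrix, PriMatureMap, dict, dict]:
    """Negative-binomial pri/mature count matrices with spiked fold changes.

    Baseline means are log-normal; library sizes vary +/-30%; mature
    features inherit their pri gene's DE status and fold change.
    """
    genes = [f"MIR{i + 1:04d}" for i in range(cfg.n_features_pri)]
    matures = [f"hsa-miR-{i + 1:04d}-3p" for i in range(cfg.n_features_mature)]
    gene_of_mature = {m: genes[i % cfg.n_features_pri] for i, m in enumerate(matures)}
    de_idx = rng.choice(cfg.n_features_pri, cfg.n_true_de, replace=False)
    de_genes = {genes[i]: cfg.de_fc for i in de_idx}
    de_mature = {m: cfg.de_fc for m in matures if gene_of_mature[m] in de_genes}
    lib = rng.uniform(0.7, 1.3, len(sample_ids))

    def nb_matrix(feature_ids: list[str], is_de: np.ndarray) -> pd.DataFrame:
        base = rng.lognormal(np.log(200.0), 1.0, len(feature_ids))
        fc = np.where(is_de, cfg.de_fc, 1.0)
        mu = base[:, None] * lib[None, :] * np.where(is_idcm[None, :], fc[:, None], 1.0)
        n_param = 1.0 / cfg.nb_dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
        return pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                            columns=sample_ids)

    pri_de = np.array([g in de_genes for g in genes])
    mat_de = np.array([m in de_mature for m in matures])
    pri = CountMatrix(nb_matrix(genes, pri_de), "pri")
    mat = CountMatrix(nb_matrix(matures, mat_de), "mature")
    pmap = PriMatureMap(pd.DataFrame(
        {"gene_id": [gene_of_mature[m] for m in matures], "mature_id": matures}
    ))
    return pri, mat, pmap, de_genes, de_mature


def simulate_tss(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    annotation: ProbeAnnotation,
    true_dmp_probes: dict,
    de_genes: dict,
    all_genes: list[str],
) -> tuple[TssAnnotation, ProbeAnnotation, dict]:
    """TSS table whose DE-gene windows contain exactly the planted DMPs.

    Every gene gets one TSS placed at least flank + 1 kb away from every
    planted DMP; for a ``promoter_gene_fraction`` subset of the spiked DE
    genes, one dedicated planted DMP probe is then relocated inside the
    gene's +/- flank window and recorded in the promoter map.
    """
    dmp_probes = list(true_dmp_probes)
    dmp_pos = annotation.df.loc[dmp_probes]
    placed: dict[str, list[int]] = {c: [] for c in CHROMS}
    rows = []
    for gene in all_genes:
        while True:
            chrom = str(rng.choice(CHROMS))
            tss = int(rng.integers(cfg.flank + 1, CHROM_LEN - cfg.flank))
            near = dmp_pos[dmp_pos["chrom"] == chrom]
            if ((near["pos"] - tss).abs() <= cfg.flank + 1000).any():
                continue
            # keep windows of distinct genes disjoint so a planted promoter
            # probe can belong to exactly one gene
            if any(abs(t - tss) <= 2 * cfg.flank + 2000 for t in placed[chrom]):
                continue
            break
        placed[chrom].append(tss)
        rows.append({"gene_id": gene, "chrom": chrom, "tss": tss,
                     "strand": rng.choice(["+", "-"]), "score": float(rng.integers(500, 1000))})
    tss_df = pd.DataFrame(rows).set_index("gene_id")
    de_list = sorted(de_genes)
    n_promoter = round(cfg.promoter_gene_fraction * len(de_list))
    promoter_genes = list(rng.choice(de_list, n_promoter, replace=False))
    # dedicate one distinct planted DMP probe to each promoter gene
    reserved = list(rng.choice(dmp_probes, n_promoter, replace=False))
    annot_df = annotation.df.copy()
    promoter_map: dict[str, list[str]] = {}
    for gene, probe in zip(promoter_genes, reserved):
        t = tss_df.loc[gene]
        lo = max(1, int(t["tss"]) - cfg.flank)
        hi = int(t["tss"]) + cfg.flank
        annot_df.loc[probe, "chrom"] = t["chrom"]
        annot_df.loc[probe, "pos"] = int(rng.integers(lo, hi + 1))
        promoter_map[gene] = [probe]
    return TssAnnotation(tss_df), ProbeAnnotation(annot_df), promoter_map


def simulate_clinical(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mature_counts: CountMatrix,
    de_mature: dict,
    is_idcm: np.ndarray,
    is_male: np.ndarray,
    sample_ids: list[str],
) -> tuple[SampleSheet, str]:
    """Sample sheet with an LVEF variable correlated to one DE mature miRNA.

    LVEF (patients only) is built from the chosen feature's log2(CPM + 0.5)
    plus Gaussian noise orthogonalized against it in-sample, with the two
    components scaled so the sample correlation equals ``planted_corr``
    before clipping to (5, 45) — the scale of a reduced-ejection-fraction
    cohort.  The in-sample calibration keeps the planted coefficient
    recoverable at small n instead of leaving it to sampling noise.
    """
    from .de import median_ratio_normalize

    feature = sorted(de_mature)[0] if de_mature else mature_counts.feature_ids[0]
    normed = median_ratio_normalize(mature_counts)
    z = np.log2(normed.loc[feature].to_numpy(float) + 0.5)[is_idcm]
    n = len(z)
    r = cfg.planted_corr
    zc = z - z.mean()
    eps = rng.normal(0.0, 1.0, n)
    if zc @ zc > 0:
        eps = eps - (eps @ zc) / (zc @ zc) * zc   # noise orthogonal to signal
    eps -= eps.mean()
    signal = np.zeros(n)
    if zc @ zc > 0 and r != 0:
        signal = r * cfg.lvef_sd * zc / zc.std(ddof=1)
    noise = np.sqrt(max(1.0 - r ** 2, 0.0)) * cfg.lvef_sd * (
        eps / eps.std(ddof=1) if eps.std(ddof=1) > 0 else eps
    )
    lvef_idcm = np.clip(cfg.lvef_mean + signal + noise, 5.01, 44.99)
    lvef = np.full(len(sample_ids), np.nan)
    lvef[is_idcm] = lvef_idcm
    age = np.round(rng.normal(53, 10, len(sample_ids))).clip(20, 80)
    df = pd.DataFrame(
        {
            "group": np.where(is_idcm, "iDCM", "CNT"),
            "sex": np.where(is_male, "M", "F"),
            "age": age,
            "LVEF": lvef,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleSheet(df), feature


def simulate_gene_sets(
    cfg: SimulationConfig, rng: np.random.Generator, de_mature: dict,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """GMT terms over a synthetic gene universe plus two target-prediction
    tables; targets of spiked miRNAs are drawn preferentially from the
    first term so the enrichment stage has signal to find."""
    universe = [f"GENE{i + 1:04d}" for i in range(cfg.n_universe_genes)]
    sets = {}
    for t in range(cfg.n_terms):
        size = int(rng.integers(10, 40))
        sets[f"TERM{t + 1:03d}"] = sorted(rng.choice(universe, size, replace=False))
    planted_term = sets["TERM001"]
    rows = []
    for m in sorted(de_mature):
        n_targets = int(rng.integers(8, 15))
        n_planted = max(1, n_targets // 2)
        genes = list(rng.choice(planted_term, n_planted, replace=False))
        genes += list(rng.choice(universe, n_targets - n_planted, replace=False))
        for g in genes:
            rows.append({"mature_id": m, "gene_symbol": g,
                         "score": float(np.round(rng.uniform(60, 100), 1))})
    db1 = pd.DataFrame(rows, columns=["mature_id", "gene_symbol", "score"])
    if len(db1):
        keep = rng.random(len(db1)) < 0.7
        db2 = db1.loc[keep, ["mature_id", "gene_symbol"]].reset_index(drop=True)
    else:
        db2 = pd.DataFrame(columns=["mature_id", "gene_symbol"])
    return sets, db1, db2


def simulate_study(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate every pipeline input for one synthetic cohort."""
    if cfg is None:
        cfg = SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    sample_ids, is_idcm = _sample_ids(cfg)
    sex = _assign_sex(cfg, rng)
    is_male = sex == "M"
    beta, annot, truth_dmps, sex_probes = simulate_methylation(
        cfg, rng, is_idcm, is_male, sample_ids
    )
    pri, mat, pmap, de_genes, de_mature = simulate_counts(cfg, rng, is_idcm, sample_ids)
    tss, annot, promoter_map = simulate_tss(
        cfg, rng, annot, truth_dmps, de_genes, list(pri.feature_ids)
    )
    sheet, corr_feature = simulate_clinical(cfg, rng, mat, de_mature, is_idcm, is_male, sample_ids)
    sets, db1, db2 = simulate_gene_sets(cfg, rng, de_mature)
    truth = SimulationTruth(
        true_dmp_probes=truth_dmps,
        sex_probes=sex_probes,
        true_de_genes=de_genes,
        true_de_mature=de_mature,
        promoter_dmp_map=promoter_map,
        correlated_feature=corr_feature,
        planted_corr=cfg.planted_corr,
    )
    return SimulatedStudy(cfg, sheet, beta, annot, pri, mat, pmap, tss, sets, db1, db2, truth)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write every generated table (TSV/BED/GMT) plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sheet": outdir / "samples.tsv",
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "probes.tsv",
        "pri_counts": outdir / "pri_counts.tsv",
        "mature_counts": outdir / "mature_counts.tsv",
        "pri_mature_map": outdir / "pri_mature_map.tsv",
        "tss": outdir / "tss.bed",
        "gmt": outdir / "gene_sets.gmt",
        "targets_db1": outdir / "targets_db1.tsv",
        "targets_db2": outdir / "targets_db2.tsv",
        "truth": outdir / "truth.json",
    }
    write_sample_sheet(study.sheet, paths["sheet"])
    write_beta_matrix(study.beta, paths["beta"])
    write_probe_annotation(study.annotation, paths["annotation"])
    write_counts(study.pri_counts, paths["pri_counts"])
    write_counts(study.mature_counts, paths["mature_counts"])
    write_pri_mature_map(study.pmap, paths["pri_mature_map"])
    write_tss_bed(study.tss, paths["tss"])
    write_gmt(study.gene_sets, paths["gmt"])
    study.targets_db1.to_csv(paths["targets_db1"], sep="\t", index=False)
    study.targets_db2.to_csv(paths["targets_db2"], sep="\t", index=False)
    study.truth.to_json(paths["truth"])
    return paths
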