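"""End-to-end driver: simulate (or load) inputs, run every stage, and emit
one structured report (JSON-serializable dict plus a human-readable text
rendering)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import de as de_mod
from . import dmp as dmp_mod
from . import enrich as enrich_mod
from . import integrate as int_mod
from .io import SampleSheet
from .simulate import SimulatedStudy, SimulationConfig, SimulationTruth, simulate_study


@dataclass
class PipelineConfig:
    """Thresholds and flags for a full run; defaults are the published
    cutoffs (FDR 0.05, |delta beta| 0.10, |log2FC| 0.6, +/-20 kb promoter
    flank, target score 95)."""

    fdr: float = 0.05
    min_delta_beta: float = 0.10
    lfc: float = 0.6
    flank: int = 20_000
    target_score: float = 95.0
    clinical_var: str = "LVEF"
    flip_delta: bool = False
    include_controls: bool = False
    de_test: str = "moderated_t"
    norm: str = "median_ratio"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("fdr", "min_delta_beta", "lfc", "flank", "target_score"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def recovery_metrics(
    dmp_table: pd.DataFrame,
    de_pri: pd.DataFrame,
    pairs: pd.DataFrame,
    corr_table: pd.DataFrame,
    truth: SimulationTruth,
) -> dict:
    """Planted-truth recovery: sensitivity and empirical FDR of DMP and DE
    calls, exactness of promoter-DMP assignment, and the recovered
    correlation of the planted miRNA-LVEF pair."""
    called = set(dmp_table.loc[dmp_table["significant"], "probe_id"])
    true_dmps = set(truth.true_dmp_probes)
    tp = len(called & true_dmps)
    dmp_sens = tp / len(true_dmps) if true_dmps else float("nan")
    dmp_fdr = (len(called) - tp) / len(called) if called else 0.0

    de_called = set(de_pri.loc[de_pri["significant"], "feature_id"])
    true_de = set(truth.true_de_genes)
    tp_de = len(de_called & true_de)
    de_sens = tp_de / len(true_de) if true_de else float("nan")
    de_fdr = (len(de_called) - tp_de) / len(de_called) if de_called else 0.0

    # promoter assignment among planted probes: the recovered (gene, probe)
    # pairs restricted to planted DMPs must equal the planted map entries
    # whose probe and gene survived the significance calls
    expected = {
        (g, p)
        for g, probes in truth.promoter_dmp_map.items()
        for p in probes
        if p in called and g in de_called
    }
    recovered_true = {
        (g, p)
        for g, p in zip(pairs["gene_id"], pairs["probe_id"])
        if p in true_dmps
    }
    assignment_exact = expected == recovered_true

    r_obs = float("nan")
    hit = corr_table[corr_table["feature_id"] == truth.correlated_feature]
    if len(hit):
        r_obs = float(hit["r"].iloc[0])
    return {
        "dmp_sensitivity": dmp_sens,
        "dmp_empirical_fdr": dmp_fdr,
        "de_sensitivity": de_sens,
        "de_empirical_fdr": de_fdr,
        "promoter_assignment_exact": bool(assignment_exact),
        "n_promoter_pairs_expected": len(expected),
        "n_promoter_pairs_recovered_true": len(recovered_true),
        "recovered_corr": r_obs,
        "planted_corr": truth.planted_corr,
    }


def run_all(
    study: SimulatedStudy | None = None,
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """Run simulate -> dmp -> de -> integrate -> enrich -> clinical and
    return the combined report."""
    config = config or PipelineConfig()
    if study is None:
        sim_config = sim_config or SimulationConfig(seed=config.seed)
        study = simulate_study(sim_config)

    dmp_table, dmp_summary = dmp_mod.run_dmp_analysis(
        study.beta, study.annotation, study.sheet,
        fdr=config.fdr, min_delta_beta=config.min_delta_beta,
        flip_delta=config.flip_delta,
    )
    de_pri = de_mod.run_de_analysis(
        study.pri_counts, study.sheet, fdr=config.fdr, lfc=config.lfc,
        method=config.de_test, norm=config.norm,
    )
    de_mature = de_mod.run_de_analysis(
        study.mature_counts, study.sheet, fdr=config.fdr, lfc=config.lfc,
        method=config.de_test, norm=config.norm,
    )
    paired = de_mod.pair_pri_mature(de_pri, de_mature, study.pmap)
    pairs, integration_summary, integration_stats = int_mod.run_integration(
        dmp_table, de_pri, study.tss, study.pmap, flank=config.flank,
    )

    targets = enrich_mod.select_targets(
        study.targets_db1, study.targets_db2, min_score=config.target_score
    )
    sig_matures = set(de_mature.loc[de_mature["significant"], "feature_id"])
    query = sorted(
        set(
            targets.loc[
                targets["high_confidence"] & targets["mature_id"].isin(sig_matures),
                "gene_symbol",
            ]
        )
    )
    enrichment = None
    if query and study.gene_sets:
        enrichment = enrich_mod.hypergeom_enrich(query, study.gene_sets)

    log_cpm = np.log2(de_mod.normalize(study.mature_counts, config.norm) + 0.5)
    corr_features = sorted(sig_matures) or list(study.mature_counts.feature_ids[:1])
    corr_table = clin.correlate_with_clinical(
        log_cpm, study.sheet, corr_features,
        clinical_var=config.clinical_var, include_controls=config.include_controls,
    )
    cohort = clin.cohort_table(study.sheet)

    report = {
        "thresholds": asdict(config),
        "dmp": dmp_summary,
        "de": {
            "pri_universe": int(len(de_pri)),
            "pri_significant": int(de_pri["significant"].sum()),
            "mature_universe": int(len(de_mature)),
            "mature_significant": int(de_mature["significant"].sum()),
            "n_concordant_pairs": int(paired["concordant_direction"].sum()) if len(paired) else 0,
        },
        "integration": integration_stats,
        "enrichment": {
            "n_query_genes": len(query),
            "top_term": enrichment.iloc[0]["term"] if enrichment is not None and len(enrichment) else None,
            "top_term_fdr": float(enrichment.iloc[0]["fdr"]) if enrichment is not None and len(enrichment) else None,
        },
        "clinical": corr_table.to_dict("records"),
        "tables": {
            "dmp_table": dmp_table,
            "de_pri": de_pri,
            "de_mature": de_mature,
            "paired": paired,
            "integration_pairs": pairs,
            "integration_summary": integration_summary,
            "targets": targets,
            "enrichment": enrichment,
            "cohort": cohort,
        },
    }
    if study.truth is not None:
        report["truth_recovery"] = recovery_metrics(
            dmp_table, de_pri, pairs, corr_table, study.truth
        )
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a run_all report."""
    lines = ["# methmir pipeline report", "", "## thresholds"]
    for k, v in report["thresholds"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "## differential methylation"]
    for k, v in report["dmp"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "## differential expression"]
    for k, v in report["de"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "## promoter integration"]
    for k, v in report["integration"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "## enrichment"]
    for k, v in report["enrichment"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "## clinical correlations"]
    for row in report["clinical"]:
        lines.append(
            f"  {row['feature_id']} vs {row['clinical_var']}: "
            f"{row['method']} r={row['r']:.3f} p={row['p_value']:.3g} (n={row['n']})"
        )
    if "truth_recovery" in report:
        lines += ["", "## planted-truth recovery"]
        for k, v in report["truth_recovery"].items():
            lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    """JSON rendering (tables excluded)."""
    slim = {k: v for k, v in report.items() if k != "tables"}
    return json.dumps(slim, indent=1, default=str)


def write_report(report: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_to_json(report))
    (outdir / "report.txt").write_text(render_report(report))
    for name, table in report["tables"].items():
        if table is not None:
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
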