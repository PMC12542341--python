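# methmir

Integrative analysis of promoter DNA methylation and miRNA expression in
case/control cardiac cohorts — in particular idiopathic dilated
cardiomyopathy (iDCM) patients versus non-diseased control (CNT) donors.
The package links EPIC-style methylation array data to small-RNA
sequencing of primary (pri-miRNA) and mature miRNAs, asks which
differentially expressed miRNAs carry differentially methylated positions
(DMPs) in their promoters, classifies whether the methylation change moves
in the canonical direction relative to expression, and correlates miRNA
expression with echocardiographic function (LVEF).

It is written for epigenomics/regulatory-genomics analysts who have
normalized beta-value matrices and small-RNA count tables in hand and want
a tested, scriptable pipeline rather than a collection of notebook
snippets. All stages run on synthetic cohorts with planted, recorded
ground truth, so every statistical claim the pipeline makes is exercised
against a known answer.

## What it computes

**Differential methylation.** Per CpG probe, a linear model of the beta
value β ∈ [0, 1] with an intercept, a group indicator (iDCM = 1) and a sex
covariate. Probes with a significant sex effect (BH-FDR < 0.05 on the sex
coefficient) are removed; the sex effect is residualized out of the rest.
The group t-statistics are moderated by empirical-Bayes variance
shrinkage: per-probe residual variances s²_g on d degrees of freedom are
shrunk toward a prior (d₀, s₀²) fitted by matching the moments of log s²_g
to a scaled-F distribution,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t_g = β̂_g / (c·s̃_g),  df = d + d₀.

A probe is a DMP when BH-FDR < 0.05 **and** |Δβ| ≥ 0.10, where
Δβ = median β(iDCM) − median β(CNT).

**Differential expression.** Counts are normalized by median-of-ratios
size factors (plain CPM available via `--norm cpm`); FC is the ratio of
normalized group means, tested by the same moderated-t engine on
log2(normalized + 0.5). A feature is DE when BH-FDR < 0.05 and
|log2FC| ≥ 0.6; pri and mature universes are corrected separately.

**Promoter integration.** Each DE pri-miRNA gene gets a ±20,000 bp window
around its highest-scoring predicted TSS; DMPs inside a window are
attributed to the gene. Per gene, AΔβ is the mean of member-DMP Δβ values;
each (DMP, gene) pair is *canonical* when hypomethylation pairs with
upregulation or hypermethylation with downregulation, else
*non-canonical*; genes with disagreeing members are *mixed*.

**Enrichment & targets.** High-confidence miRNA targets are interactions
scoring ≥ 95 in one prediction table and also present in a second;
enrichment of any gene list against GMT terms uses the upper-tail
hypergeometric test with BH correction.

**Clinical statistics.** Shapiro–Wilk gates every continuous comparison:
normal pairs use Pearson / Student's t, otherwise Spearman / Mann–Whitney;
binary variables use the two-sided Fisher exact test.

## Worked example

Run the whole pipeline on a synthetic cohort (5,000 probes, 300 pri + 300
mature miRNAs, 9 CNT vs 20 iDCM, 200 planted DMPs, 20 spiked DE genes, a
planted miRNA–LVEF correlation of 0.67):

```bash
methmir all --outdir out/ --seed 1
```

`out/report.txt` (abridged, actual output):

```
## differential methylation
  n_probes_tested: 4947
  n_excluded_sex_dependent: 53
  n_significant: 183
  n_hyper: 58
  n_hypo: 125

## differential expression
  pri_significant: 20
  mature_significant: 22
  n_concordant_pairs: 20

## promoter integration
  n_pairs: 15
  n_canonical: 11
  canonical_fraction: 0.7333333333333333

## clinical correlations
  hsa-miR-0002-3p vs LVEF: pearson r=0.655 p=0.00172 (n=20)

## planted-truth recovery
  dmp_sensitivity: 0.91
  dmp_empirical_fdr: 0.005
  de_sensitivity: 1.0
  promoter_assignment_exact: True
```

Reading: 183 of 4,947 probes are DMPs (125 hypo-, 58 hypermethylated in
patients — the generator plants a 70% hypomethylation majority); all 20
spiked pri-miRNAs are recovered with no false DE calls; 15 of the 20 DE
genes carry a promoter DMP, 73% of the (DMP, gene) pairs follow the
canonical methylation–expression pattern; and the planted
expression–LVEF correlation is estimated at r = 0.655 (true 0.67). The
recovery block appears because the inputs were simulated — with real data
the pipeline prints the same report without it.

Individual stages run standalone (`methmir dmp`, `methmir de`,
`methmir integrate`, `methmir enrich`, `methmir targets`,
`methmir clinical`, `methmir cohort-table`) on TSV/BED/GMT files; see
`methmir <cmd> --help`.

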