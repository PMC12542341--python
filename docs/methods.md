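# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator's design, the numerical choices, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential methylation

Beta values (methylated / total intensity, in [0, 1]) are modelled
directly on the beta scale with ordinary least squares per probe against a
shared design matrix: intercept, group indicator (iDCM = 1), sex indicator
(male = 1). Modelling β rather than M-values keeps the effect sizes on the
same scale as the Δβ filter and the adjusted matrices interpretable as
methylation fractions; the cost is mild heteroscedasticity near the
boundaries, which the moderated test absorbs in practice (null calibration
below). If sex has a single level it is dropped with a warning; if sex is
perfectly confounded with group the fit refuses with an error rather than
silently absorbing the group effect.

**Sex handling.** "Sex-dependent" is operationalized as a BH-FDR < 0.05 on
the sex coefficient under the same moderated framework as the group test —
the pipeline's own FDR convention, since no external threshold exists.
Excluded probes are removed; for the remainder the sex effect is
residualized with a centered indicator, β − β̂_sex·(x_sex − x̄_sex), and
clipped back to [0, 1], preserving each probe's overall mean. The model is
then refitted on the adjusted matrix with the full design (the residual
sex coefficient is ≈ 0; keeping the column keeps the residual degrees of
freedom definition uniform across both fits).

**Empirical-Bayes moderation.** Residual variances s²_g on d df are
assumed to follow s²_g | σ²_g ~ σ²_g·χ²_d/d with an inverse-chi-square
prior σ²_g ~ s₀²·d₀/χ²_{d₀}. The prior is fitted by moment-matching
log s²_g: with e_g = log s²_g − ψ(d/2) + log(d/2),

  mean(e) estimates log s₀² + ψ(d₀/2) − log(d₀/2),
  var(e) − ψ′(d/2) estimates ψ′(d₀/2),

so d₀ = 2·ψ′⁻¹(var(e) − ψ′(d/2)), with the trigamma inverse solved by
Newton iteration (tolerance 1e-8, cap 50 iterations; converges in < 10 in
practice). When the observed spread of log-variances does not exceed the
chi-square sampling noise, the prior is a point mass: d₀ = ∞ and
s₀² = mean(s²_g), the pooled estimator, so an exactly-constant variance
vector is returned unchanged. Zero variances are offset to
1e-5 × median(s²) before taking logs (an all-zero matrix is an error).
The posterior is the precision-weighted blend
s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d), always between s²_g and s₀²; the
moderated t uses d + d₀ df, degrading to the classical t at d₀ = 0 and to
a normal deviate at d₀ = ∞ (both limits are pinned numerically in the
tests).

**Calling.** Benjamini–Hochberg is applied over all tested probes
(statsmodels step-up; the test suite pins it against the brute-force
min-over-j definition). A probe is a DMP when FDR < 0.05 (strict) and
|Δβ| ≥ 0.10 (inclusive), with Δβ = median(iDCM) − median(CNT) computed on
the sex-adjusted matrix. The test statistic uses the model coefficient
while the effect filter uses group medians — deliberately two different
summaries, one powering inference and one guarding effect size. The sign
convention is patients minus controls (`--flip-delta` reverses it for
interoperability with tables written the other way around).

## Differential expression

Counts are normalized to a counts-per-million scale using median-of-ratios
size factors: each sample's factor is the median, over features positive
in every sample, of its ratio to the geometric-mean reference profile.
Plain library-size CPM is available (`--norm cpm`) but is not the default
because it is not robust to composition shifts: when a minority of
features carries a strong one-sided expression change, the inflated
library total deflates every other feature's CPM and manufactures
spurious opposite-direction fold changes. On this package's default
synthetic cohorts (20 of 300 genes spiked 3.5-fold up, 12–22% of library
mass) CPM produces an empirical DE false-discovery proportion of ≈ 0.26
versus ≈ 0.03 for median-of-ratios — the test
`test_median_ratio_resists_composition_shift` demonstrates the mechanism
in isolation.

FC is the ratio of normalized group means (features with a zero control
mean are flagged and excluded from calling); significance comes from the
same moderated-t engine applied to log2(normalized + 0.5) with a
group-only design (Mann–Whitney available via `--de-test`). The
pseudocount 0.5 keeps zeros finite while distorting high-count features
negligibly. A feature is DE when FDR < 0.05 and |log2FC| ≥ 0.6, corrected
separately within the pri and mature universes — they are different
measurement spaces and are never pooled. Pri/mature pairs where both
forms are significant are reported with a direction-concordance flag.

## Promoter integration

Promoters are the ±20,000 bp windows flanking each gene's highest-scoring
predicted TSS (ties broken by smallest coordinate, then chromosome name,
for determinism). Coordinates are 1-based inclusive internally (the
array-manifest convention); BED input converts at the boundary
(TSS = start + 1 on '+', = end on '−'). Window bounds are inclusive on
both ends and floored at 1; the flank is symmetric, so strand does not
change the window. A DMP belongs to a window iff the chromosome matches
and start ≤ pos ≤ end; overlapping windows each receive the probe, and
window membership is pinned against a brute-force all-pairs scan in the
tests. Per gene, AΔβ is the arithmetic mean over member DMPs (per-probe
Δβ values are also reported, since a mean over disagreeing probes hides
structure — the *mixed* label exists for exactly that case). Concordance:
(hypo, up) and (hyper, down) are canonical; the reverse pairings are
non-canonical; the pipeline reports the canonical fraction with its
numerator and denominator.

## Enrichment and targets

Term enrichment is the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) via the survival function (computed in log space
internally, so genome-scale universes do not overflow), BH-corrected
across terms. The universe defaults to the union of the supplied gene
sets and is user-overridable; query genes outside it are dropped with a
warning. Target selection keeps interactions with a prediction score ≥ 95
(inclusive) that also appear in the second database — an intersection, not
a union.

## Clinical statistics

Every continuous comparison is gated by Shapiro–Wilk at p > 0.05
("normal"): correlation uses Pearson when both vectors pass, else
Spearman; two-group location uses Student's t when both groups pass, else
Mann–Whitney. Constant vectors are treated as non-normal with a warning;
fewer than 3 observations is an error. Binary variables use the two-sided
Fisher exact test under the probability-mass convention (sum of
fixed-margin table probabilities no larger than the observed one), pinned
against full enumeration in the tests. Correlations with clinical
covariates are computed within the patient group by default
(`--include-controls` exists), on pairwise-complete observations, and no
multiple-testing correction is applied across them — the number of
correlations is logged so users can Bonferroni if they wish.

## Synthetic-data generator

The generator emulates the targeted study design: a small LV-tissue
cohort, 9 CNT / 20 iDCM by default.

* **Methylation.** Per-probe baseline means from a three-class Beta
  mixture (hypo (2,10) / intermediate (10,10) / hyper (10,2)); per-sample
  values Beta-distributed with the probe's (group, sex)-specific mean and
  concentration 50 (per-sample SD ≈ 0.07 at β = 0.5), so values lie in
  [0, 1] by construction rather than by clipping a Gaussian. 200 of 5,000
  probes get a ±0.15 group shift (70% hypomethylated in patients); 50
  probes get a ±0.30 sex shift; planted probes' baselines are kept inside
  (margin, 1 − margin) so shifted means never saturate.
* **Counts.** Negative-binomial with log-normal baselines
  (median ≈ 200 counts, log-SD 1), dispersion 0.1, library sizes ±30%.
  20 of 300 pri genes are spiked 3.5-fold up in patients; mature features
  inherit their pri gene's status and fold change.
* **TSS geometry.** Every gene gets a TSS at least flank + 1 kb from
  every planted DMP, with inter-TSS spacing > 2·flank, so windows of
  distinct genes are disjoint. For 75% of the spiked genes one dedicated
  planted DMP is then relocated uniformly inside the gene's window and
  recorded in the truth map — by construction each promoter window
  contains exactly its planted DMPs and no other planted probe, making
  "assignment exact" a well-defined oracle.
* **Clinical.** LVEF exists for patients only, mean 19, SD 8, clipped to
  (5, 45) — a reduced-ejection-fraction scale. It is built from the
  chosen spiked mature miRNA's log2 normalized expression plus Gaussian
  noise orthogonalized against that signal in-sample, with the two
  components scaled so the sample correlation equals the planted r
  (default 0.67) before clipping. The calibration is exact in-sample
  rather than in expectation deliberately: at n = 20 the sampling SD of a
  correlation is ≈ 0.24 on the Fisher-z scale, so an expectation-level
  plant leaves the realized coefficient too variable to serve as a
  recovery oracle (theoretical coverage of [0.5, 0.8] would be ≈ 74%).
  Sex is ≈ 80% male in patients and ≈ 65% in controls, with deterministic
  per-group counts.
* **Enrichment inputs.** A 400-gene synthetic universe, 15 GMT terms, and
  two target tables; targets of spiked miRNAs are drawn half from the
  first term, giving the enrichment stage real signal.

All randomness flows through a single `numpy.random.Generator` seeded
from the config; identical seeds reproduce every table bit for bit.

What the generator does **not** emulate: probe cross-hybridization and
SNP-affected probes, CpG-island/region structure, batch and bead-chip
effects, sequencing error, isoform/arm complexity, correlated clinical
covariates. Passing recovery tests therefore show that the statistics do
what they claim under a clean generative model of the data types — not
that real cohorts are free of the artefacts listed above.

## Problem sizes and runtime

Defaults were chosen so a full pipeline run (5,000 probes, 600 count
features, 29 samples) completes in well under a minute on one CPU, and the
repeated-cohort checks (10 replicates for call recovery, 100 for
correlation recovery, 20 for null calibration) in about half a minute
total. Recovery metrics are averaged over the replicates because a single
20-spike cohort quantizes a false-discovery proportion in steps of ~0.05.

## Known limitations

* Position-level only: no region (DMR) calling, no cell-type
  deconvolution, no batch correction.
* Beta-scale OLS is an approximation; an M-value option is a natural
  extension but is not implemented.
* The moderated test on log-normalized counts is a small-n workhorse, not
  a count likelihood; strongly dispersed low-count features are better
  served by a dedicated NB model.
* The normality gate at n = 20 has limited power, so the Pearson/Spearman
  switch is itself noisy; Spearman measures rank association and will not
  numerically reproduce a linearly planted Pearson coefficient.
* Enrichment results depend entirely on the supplied gene sets and
  universe; no attempt is made to ship a term database.
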