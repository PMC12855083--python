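# Methods

This package reproduces, on fully synthetic data with known ground truth, a
rare-event mass-cytometry analysis of whole blood: enumeration of circulating
fibroblasts (PDPN⁺CD45⁻ lineage-negative events), circulating fibrocytes
(CD34⁺HLA-DR⁺CD45⁺ lineage-negative events) and CDH11⁺CD90⁺ leukocytes,
conversion of gated counts to absolute frequencies, the nonparametric
statistics used to compare patient groups, and a plasma NPX proteomics arm
(moderated differential expression, preranked enrichment, correlation
screens). Because no event-level patient data are available, every stage is
exercised against a generator whose parameters are the study conditions: the
validity claim of a passing suite is *the pipeline recovers known truth under
a realistic noise model*, not that any particular clinical result is correct.

## Synthetic acquisition model

One simulated acquisition mixes calibration beads, DNA-low debris,
summed-pair doublets, bulk leukocytes from a 12-lineage mixture, and spiked
rare cells, shuffled into a random acquisition order.

**Spike counts.** The number of rare cells of a class captured in an
acquisition is Poisson(rate × V_eff), where V_eff = stained_volume_ml ×
acquisition_fraction (default 0.27 ml × 1.0). This is the counting law for
cells sampled from a fixed analyzed volume; the instrument never reports
V_eff directly, so the acquisition fraction is an explicit configuration
parameter rather than a measured quantity. With the default patient
fibroblast rate of 7 cells/ml the expected spike is 1.89 cells/sample, which
is what makes this a genuinely rare-event problem.

**Defaults as study conditions.** Group sizes 9/11/12 (controls, RA, PsA);
patient fibroblast rate 7 cells/ml and fibrocyte rate 70 cells/ml (the
reported cohort medians); control rates 1.6 and 50 cells/ml (back-computed
from the reported control totals); bone-marrow fibrocyte fold 70 (midpoint
of the reported 50–100× range); CDH11⁺CD90⁺ leukocytes at 1% of CD45⁺;
phenotype mixtures whose supports give 7/6/2 distinct fibroblast and
13/11/5 distinct fibrocyte combinations in RA/PsA/controls, with CDH11- or
CD90-carrying fibroblast combinations at zero weight in controls and
control fibrocytes limited to single-marker phenotypes; CCR7 and HLA-DR on
fibroblasts patient-exclusive. Receptor positivity probabilities (CCR6 0.6
dominant, then CCR7/CCR4) and the leukocyte mixture (55% neutrophils, 12%
CD4 T, …) are realistic round numbers chosen once; only their order of
magnitude matters to any test.

**Intensity model.** Positive marker states draw from a zero-inflated
log-normal (raw median 100 dual counts, σ = 0.5 on the natural-log scale,
zero-inflation 0 by default); negative states from an exponential background
(scale 0.5 counts). DNA intercalator channels use a tighter log-normal
(median 500, σ = 0.15) so the singlet/doublet DNA bands are resolvable;
calibration beads use median 1000, σ = 0.02 (metal-embedded beads are
nearly uniform). On the arcsinh(x/5) scale this puts positives at ≈3.7 and
backgrounds at ≈0.1 with <10⁻⁵ overlap across the default threshold of
1.5 — the "clean separation" regime in which the gate-recovery contracts
(sensitivity ≥95%, zero false positives) are stated. Zero-inflation on
positives directly trades against those contracts and is therefore off by
default but available for robustness experiments.

**What the generator does not emulate.** Spillover and isotopic impurity,
barcoding, cell loss during staining, biological marker-intensity
correlation structure, batch effects across acquisitions, and real
population autofluorescence/background heterogeneity. Passing tests show the
*logic* of gating and enumeration recovers truth under well-separated noise;
they do not show that a fixed arcsinh threshold of 1.5 would gate a real
Helios run correctly — on real data thresholds would need per-batch review,
which is why the threshold strategy (fixed vs density-valley) and every
threshold are configuration, not constants.

**Doublets, debris, beads.** Doublets are sums of two leukocyte event rows
(DNA and event length both roughly double); debris has exponential DNA
(scale 5); beads are bead-channel-positive and DNA-low. Default composition
3% beads, 5% debris, 2% doublets.

**Determinism.** Per-sample seeds derive from the master seed as
`SeedSequence([master, counter])` with the counter running over cohort
slots, so any sample can be regenerated alone; identical seeds give
bitwise-identical tables.

## FCS I/O and bead normalization

Files are written as FCS 3.1, single float32 list-mode data segment,
`$PnN` = metal, `$PnS` = marker, with stained volume, acquisition fraction
and sample id in custom TEXT keywords. The reader accepts FCS 3.0/3.1
little- or big-endian float data and falls back to `$PnN` names when `$PnS`
is absent. Round trips are lossless because both sides are float32.

Drift correction assumes sensitivity decays smoothly in acquisition order.
Events are cut into fixed windows (default 2000 events — large enough that
the per-window bead median has sub-percent sampling error at a 3% bead
fraction), the bead-channel median is computed per window, and all channels
except event length are rescaled so window medians equal the mean of window
medians. Using unsmoothed medians with that particular reference makes the
operation exactly idempotent; a 20% injected linear decay leaves <2%
residual fitted drift. Windows without beads inherit interpolated medians.
Fewer than 50 bead events is a hard error rather than a silent pass-through.
Equivalence with any vendor normalizer is not claimed.

## Gating

All calls are 1-D thresholds on arcsinh(x/5). The cleanup gate flags beads,
debris (either DNA channel below the window, default 4.5) and doublets
(either DNA channel above 5.7, or event length outside 10–45). The
leukocyte tree assigns intact CD45⁺ singlets by first match in a fixed,
logged order (eosinophils CD66b⁺CD294⁺ before neutrophils CD66b⁺CD16⁺, then
basophils, B, γδ T, MAIT/iNKT before CD4/CD8 T, NK, monocytes CD14⁺ or
CD33⁺, DC as HLA-DR⁺ lineage⁻, ILC as CD127⁺ lineage⁻HLA-DR⁻); the order and
thresholds are hashed into every result. The marker definitions follow
standard commercial immune-profiling panel conventions; they are
configuration, and numerical equality with any manually gated dataset is
not claimed.

Rare-cell gates apply the lineage-exclusion panel
(CD3, CD19, CD4, CD8, CD56, CD66b, CD294) exactly as printed in the
operational definitions, including CD4/CD8 which also serve as T-subset
markers: fibroblasts are intact PDPN⁺CD45⁻ exclusion-negative events,
fibrocytes intact CD34⁺HLA-DR⁺CD45⁺ exclusion-negative events; the CD45
requirement makes the two gates disjoint by construction.

## Phenotype codes and frequencies

Four binary mesenchymal markers give 16 combinations, coded
`1 + Σ bᵢ·2ⁱ` over the ordered basis (fibroblasts: CDH11, CD34, CD90,
Notch3; fibrocytes: CDH11, PDPN, CD90, Notch3); code 1 is all-negative,
code 16 quadruple-positive. This binary order is defined by this package;
external FB1–FB16-style labels need not follow it, so cross-study
comparisons should use cardinalities of distinct phenotypes, which all
outputs flag. Frequencies are count/V_eff exactly; percentages are rounded
half-up when printed.

## Statistics

Mann-Whitney is exact (rank-split enumeration) for nA+nB ≤ 12 without ties,
else normal with tie and continuity correction. Kruskal-Wallis enumerates
all distinct assignments for total n ≤ 10, else uses the χ² approximation.
Wilcoxon drops zero differences (this changes n and is reported), exact for
≤15 untied nonzero pairs. Fisher's two-sided p sums hypergeometric
probabilities ≤ the observed table's. The post-hoc family for a
Kruskal-Wallis screen is all pairwise Mann-Whitney comparisons corrected as
one family with the two-stage adaptive step-up procedure: stage 1 runs BH at
α′ = α/(1+α) to estimate m₀ = m − r₁, stage 2 re-runs BH at α′·m/m₀ — the
literal two-stage definition, which reduces to BH at α′ when stage 1 rejects
nothing. Adaptive adjusted p-values are BH values scaled by m₀/m. Spearman
screens use average ranks and BH control across the screen.

## NPX arm

The generator emits 368 assays on a log2 scale: per-assay baselines
N(5, 1.5), Gaussian residual σ = 0.3, and +2 log2 shifts on CXCL1, ANGPT1
and TIMP3 in samples whose ground truth contains ≥1 CDH11⁺ fibroblast; 10
assays carry QC warnings. QC removes warned assays and assays below LOD in
>50% of samples (both configurable), and removing all assays is an error.

Differential expression moderates per-assay variances with the
empirical-Bayes shrinkage described in the module docstring: (d₀, s₀²) by
moment-matching log-variances via trigamma inversion, posterior variance
(d₀s₀² + d·s²)/(d₀+d), moderated t on d+d₀ df, BH across assays. The
closed-form moment match was chosen over marginal ML because it is exactly
checkable against an independent reference implementation (the test suite
verifies agreement with R limma to ~10⁻⁸ and the d₀ = 0 / d₀ = ∞ limits
analytically). DEPs require adjusted p < 0.05 and |log2FC| > 1.

Preranked enrichment uses the weighted running sum with w = 1 (hit
increments ∝ |statistic|), a gene-label permutation null (default 10,000
draws, seeded; exhaustive enumeration available and used as the test
oracle), NES = ES / mean |null| of the matching sign, and
p = (1 + #extreme)/(n_null + 1). ES is invariant to monotone rescaling of
the statistic only at w = 0; both behaviors are tested. Gene-set
collections are consumed as GMT files or built synthetically; no ontology
snapshot is bundled (collections are version-dependent). With only a
3-protein effect signature, set-level enrichment on the synthetic NPX data
is underpowered — the demo driver reports whatever it finds and falls back
to screening DEPs when no set clears the threshold, which is the expected
behavior of the method at this signature size, not a defect.

Protein-vs-count screens are Pearson correlations restricted (per the
analysis design) to proteins of significant sets, BH-adjusted with
significance at 0.1; constant vectors and pairs with n < 3 are skipped with
warnings.

## Problem sizes used in the shipped studies

Recovery studies run at reduced bulk size because rare-cell recovery
depends only on rate × V_eff, not on bulk events: cohort-frequency recovery
uses 10 replicate 23-patient cohorts at 20,000 events/sample and reports
the mean of the replicate cohort medians (a single 23-sample cohort median
of a Poisson(1.89) count is itself strongly quantized — 2/0.27 ≈ 7.4 or
1/0.27 ≈ 3.7 cells/ml — so averaging replicate medians reports the estimand
rather than one quantization draw). The paired bone-marrow comparison uses
two patients per replicate, matching the paired-sample design, with 100
replicates; the CD45⁺ co-expression fraction uses one full 500,000-event
acquisition; the neutrophil proportion check uses 10,000 neutrophil events.

## Known limitations

* Positivity is 1-D thresholding; no 2-D manual-gate geometry, clustering,
  or embedding. Real-data gating would need threshold review per batch.
* The generator draws marker states independently given the cell class;
  real co-expression correlation structure is absent, which flatters any
  Boolean-combination analysis.
* The exact-vs-asymptotic switchovers (n ≤ 12, n ≤ 10, ≤15 pairs) follow
  common practice but are conventions, exposed in the result's method label.
* Bead normalization corrects smooth multiplicative drift only; step
  changes or channel-specific drift are out of scope.
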