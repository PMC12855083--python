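# fibrocyto

Rare-event analysis of whole-blood mass cytometry (CyTOF) for circulating
mesenchymal cells, with a matched plasma proteomics arm — built as a fully
synthetic, ground-truthed reimplementation for method validation.

## The problem

In chronic inflammatory arthritis (rheumatoid and psoriatic), a handful of
circulating fibroblasts (PDPN⁺CD45⁻, lineage-negative) and fibrocytes
(CD34⁺HLA-DR⁺CD45⁺, lineage-negative) per millilitre of blood — plus a ~1%
CDH11⁺CD90⁺ fraction of ordinary leukocytes — are candidate vehicles for
"arthritis spreading" between joints. Quantifying them means finding ~2
cells among ~500,000 events per acquisition, so every step (bead drift
normalization, singlet cleanup, hierarchical gating, Boolean phenotype
combinatorics, per-ml frequency estimation, nonparametric group comparison,
and Olink NPX differential expression) has to be exact and auditable. This
package implements that pipeline as a library with a synthetic-data
generator whose parameters are the study's reported conditions, so every
stage is testable against known truth without any patient data. It is
aimed at cytometrists and computational biologists who want a transparent,
scriptable alternative to manual gating for rare-event enumeration, and at
anyone who needs the statistical machinery (exact small-sample tests,
two-stage adaptive FDR, moderated t, preranked GSEA) with verifiable
implementations.

## The model in brief

* Spiked rare-cell counts per acquisition: `K ~ Poisson(rate × V_eff)` with
  `V_eff = stained_volume × acquisition_fraction` (default 0.27 ml);
  estimated frequency is `K / V_eff` cells/ml.
* Positivity calls: thresholds on `asinh(x / 5)`; positive states are
  log-normal (median ≈100 counts), negatives exponential (≈0–2 counts).
* Phenotype codes: 4 binary mesenchymal markers → codes
  `1 + Σ bᵢ2ⁱ` ∈ 1…16 (fibroblasts over CDH11/CD34/CD90/Notch3, fibrocytes
  over CDH11/PDPN/CD90/Notch3).
* Moderated t: `s̃² = (d₀s₀² + d s²)/(d₀ + d)` with `(d₀, s₀²)` from
  trigamma moment-matching of log-variances; `t = Δ/(s̃√(1/n₁+1/n₂))` on
  `d + d₀` df (matches R limma to numerical precision).
* Preranked GSEA: weighted KS running sum (w = 1), gene-label permutation
  null, sign-matched NES.
* FDR: Benjamini-Hochberg, and the two-stage adaptive step-up (stage 1 BH
  at α/(1+α) to estimate m₀, stage 2 BH at α/(1+α)·m/m₀).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated 32-sample cohort (9 controls, 11 RA, 12 PsA):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_gate_and_enumerate.py
python analysis/03_cohort_stats.py
python analysis/04_proteomics.py
```

Output of step 02 on seed 1 (abridged):

```
median estimated frequencies (cells/ml) by group:
       fibroblasts_per_ml  fibrocytes_per_ml
group
HC                   0.00              51.85
PsA                  5.56              66.67
RA                   7.41              66.67

distinct phenotypes observed:
group  cell_class
HC     fibrocyte      5
PsA    fibroblast     6
       fibrocyte     11
RA     fibroblast     7
       fibrocyte     13
```

Patient samples are spiked at 7 fibroblasts and 70 fibrocytes per ml; the
gated medians recover those rates up to Poisson quantization (a median
fibroblast count of 2 per 0.27 ml reads as 7.41 cells/ml), and the distinct
phenotype counts per group reproduce the generating mixture supports
(7/6 fibroblast and 13/11/5 fibrocyte combinations). Step 03 then finds
elevated fibroblast counts in patients (Kruskal-Wallis p = 2×10⁻⁴; both
HC-vs-patient post-hoc comparisons rejected by the two-stage adaptive
procedure), and step 04 reports

```
QC: 368 assays, 358 retained (97%)
contrast: 13 patients with detectable CDH11+ fibroblasts vs 10 without
DEPs (p_adj<0.05, |log2FC|>1): CXCL1, ANGPT1
correlation screen: 4 pairs, 2 significant at adjusted p<0.1
```

i.e. the designated effect proteins come out as the differentially
expressed set (TIMP3 was removed by the simulated QC flags on this seed —
the driver prints a note when that happens) and their levels correlate with
gated fibroblast counts (ANGPT1 r = 0.52, adjusted p = 0.044).

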