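# flowgwas

A statistical-genetics toolkit for genome-wide association studies of
flow-cytometry blood-cell traits — the side-scatter, side-fluorescence
and forward-scatter summaries a haematology analyser measures but does
not put on a standard clinical report. These phenotypes carry strong
technical structure (which analyser ran the sample, when, how long
after venipuncture) on top of ordinary physiology, and their GWAS
workflow needs several bespoke stages beyond an off-the-shelf scan.
`flowgwas` implements that workflow as a tested, reusable library,
together with a synthetic-cohort generator so every stage can be
validated against known ground truth.

## What the package computes

**Phenotype adjustment.** Each measured trait *y* is pre-transformed by
a support-appropriate map *a* (log for positive traits, logit for
proportions) and adjusted in two stages of penalised additive smooth
models:

    E[a(y_i)] = s[t(i) ⊗ m(i)] + c[t_year(i)] + tp[(t_day(i), t_ven(i)) ⊗ (m(i), I(i))] + Σ_D 1{D(i)=D}

removes technical variation (drift in time *t* per analyser *m*, an
annual cycle, a bivariate time-of-day × venipuncture-interval surface,
day-of-week), and a second stage removes baseline physiology (smooths
of age and of (log weight, log height) per menopause level, smoking,
alcohol, trial arm). Residuals pass median/MAD outlier rules (3.5 MADs
on the adjustment magnitude, 4.5 on the residual), a χ²_d filter on
leading principal-component scores (10⁻⁷ tail), and a stratified
quantile-inverse-normal transform (by analyser × sex × menopause).

**Association and conditional selection.** Additive-allelic OLS scans
with genotype-PC and clinic covariates, genomic-control λ diagnostics,
then Efroymson stepwise selection within 10-Mb blocks at the
genome-wide threshold *P* < 8.31×10⁻⁹ with an LD cap (no candidate
enters a model containing a variant at r² > 0.9), and an
elimination-first joint refit over the pooled block selections.

**Signal interpretation.** Greedy LD clumping (connected components at
r² > 0.8) with per-cell-type novelty calls against a prior catalogue;
exhaustive Bayesian fine-mapping (effect prior SD 0.08, configuration
enumeration, 95% credible sets); regional colocalisation of a trait
signal with an eQTL/pQTL/disease partner via approximate Bayes factors,
with secondary signals removed by residual re-scanning; and a
directional enrichment analysis of a variant's plasma-proteomic effects
by α-granule localisation (2×2 Fisher's exact test and an
expression-adjusted regression).

## Worked example

`examples/04_conditional_selection.py` simulates two causal variants
(β = 0.3 and 0.25 trait-SD) on different chromosomes with LD tags at
n = 3000 and runs the scan plus stepwise selection:

```
19 genome-wide-significant variants
conditionally significant variants (joint model):
      variant  block  beta     se        p
1:1100000:A:G      0 0.345 0.0275 3.15e-35
2:1100000:A:G      1 0.206 0.0266 1.37e-14
```

Nineteen correlated tags clear the genome-wide threshold, but the joint
model keeps exactly one variant per underlying signal — the two causal
variants — with joint effects close to the injected values.
`examples/05_finemapping.py` then fine-maps a simulated signal
(posterior inclusion probability 1.000 on the causal variant; singleton
95% credible set), and `examples/07_granule_enrichment.py` evaluates
the published protein cross-classification:

```
published 2x2 table [[40, 4], [101, 70]]: Fisher two-sided p = 3.17e-05
granule shift estimate -0.0424 SD (se 0.0037, p = 6.4e-29); injected -0.038
```

The other scripts in `examples/` cover cohort simulation, phenotype
adjustment, the association scan, colocalisation and the end-to-end
pipeline runner (`flowgwas.pipeline.run_pipeline`, which writes every
stage's tables plus a reproducibility manifest).

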