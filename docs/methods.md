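# Methods

## Variance decomposition and ITVS

Each gene's expression across a multi-region cohort is modelled as a
one-way random-intercept model

    y_pr = mu + b_p + e_pr,   b_p ~ N(0, B),   e_pr ~ N(0, W)

with p indexing patients and r regions. The intra-tumoral variability
score is ITVS = W/(W+B). The model assumes expression on a
variance-stabilized (VST-like) scale, where gene-level noise is
approximately Gaussian and homoscedastic; raw counts must be normalized
upstream (a `log2_cpm` convenience is provided but is explicitly a
stand-in, not a variance-stabilizing transform).

The default estimator is the closed-form one-way ANOVA method of
moments: W = MSW, B = (MSB − MSW)/n0 with the unbalanced-design
effective group size n0 = (N − Σn_p²/N)/(a − 1). It is deterministic,
exact on balanced designs, and vectorizes over ~10⁴ genes in
milliseconds. Negative moment estimates of B are truncated to zero
(standard variance-components practice) and flagged in `degenerate`;
constant genes get an undefined (NaN) ITVS. REML via statsmodels
`MixedLM` is available (`method="reml"`); per-gene optimizer failures
walk a fallback chain (lbfgs → bfgs → powell) and flag rather than
abort. On balanced designs the two estimators agree on ITVS to well
under 0.02. Estimating W requires at least one patient with ≥ 2
regions; single-region patients still inform B through the unbalanced
formula.

## Clustering consistency: PGOR, AUPC, CCS

Per gene, samples are clustered on the 1-D expression values (distance
= absolute difference) by agglomerative linkage, and the dendrogram is
cut into k = 1..N clusters. A multi-region patient is "correctly
grouped" at level k iff all of its regions share one cluster;
single-region patients are excluded from the denominator because they
carry no grouping information. PGOR(k) is the fraction of correctly
grouped patients, AUPC its trapezoidal integral over unit steps in k,
and CCS = 1 − AUPC/(N−1), clipped to [0,1].

Orientation: genes whose regions cluster by patient keep PGOR high for
many k, giving large AUPC and therefore *small* CCS — low CCS means low
ITH, which makes the geometric-mean IHS coherent (both factors small
for stable genes).

Design choices that were genuinely open:

- **Linkage.** No linkage rule is canonical for 1-D single-gene
  clustering. We compared average, complete, single and ward on
  simulated cohorts with known within-patient variance fraction ρ
  (P=20, r=4, 500 genes): Spearman correlation between ρ and CCS was
  0.72 / 0.82 / 0.49 / 0.87 respectively. Ward is the default because
  it makes CCS the most faithful monotone readout of the generating
  heterogeneity; the other rules remain selectable.
- **Endpoints.** Only the forced endpoints are guaranteed (PGOR = 1 at
  k = 1; PGOR = 0 at k = N when every evaluable patient is
  multi-region); monotonicity in between is not assumed or enforced.
- **Determinism.** scipy's agglomeration order is deterministic, and
  exact distance ties are measure-zero on continuous data, so repeated
  runs give identical tables.
- **Correctness oracle.** For N ≤ 6 the implementation is checked
  against a scipy-independent brute-force agglomeration (explicit
  Lance-Williams-free cluster-pair search) at every cut level and every
  linkage rule.

## IHS and classification

IHS = sqrt(ITVS × CCS), undefined if either factor is undefined
(undefined genes are counted and excluded from classification). Genes
with IHS ≤ 0.5 are "low-ITH"; the boundary is inclusive on the low
side. The threshold is a parameter (default 0.5).

## MATH

MATH = 100 × MAD/median over a sample's VAFs, with MAD scaled by the
conventional rounded normal-consistency constant 1.4826 (omitting it
would rescale every score by ~1.48, so it is hard-coded and tested).
Samples need ≥ 3 usable VAFs (configurable) and a nonzero median;
otherwise the score is NaN, never silently dropped. An optional VAF
floor removes noise-level calls before counting. No purity or
copy-number correction is applied.

## Differential expression stand-in

`simple_de` is a per-gene Welch t-test on the normalized scale with
log2FC = mean difference and Benjamini-Hochberg FDR. It is a
lightweight built-in, not a moderated-variance DE engine; users wanting
a specific DE method supply a precomputed table (gene_id, log2fc, fdr).
DEG thresholds are strict inequalities: |log2FC| > 0.137 (≈ 10%
expression change) and FDR < 0.05.

## Univariate Cox screen and PH diagnostic

The screen fits one proportional-hazards model per gene (expression as
a continuous covariate) by Newton-Raphson on the Efron partial
likelihood, vectorized over genes on (samples × genes) arrays — the
per-gene-CoxPHFitter route is two to three orders of magnitude slower
at screening scale. Wald p-values and 95% CIs come from the observed
information. Constant covariates and monotone-likelihood fits
(|log HR| > 15) are flagged. The implementation is validated against
lifelines: coefficients agree to ~1e-5 (our solver drives the score to
machine zero; lifelines stops earlier).

The proportional-hazards diagnostic is the Grambsch-Therneau
correlation of Schoenfeld residuals with KM-transformed time,
chi-square on 1 df; `ph_ok` means PH is not rejected at `ph_alpha`
(default 0.05). Residuals use the full-risk-set (Breslow) form, which
with heavy ties deviates from tie-adjusted references by at most a few
hundredths in p. Measured null rejection is at the nominal 5%.

A consequence worth stating: requiring `ph_ok` in two cohorts for a
two-gene signature applies a calibrated 5%-level test four times, so
even a perfectly specified simulation recovers the exact planted pair
in only ~80% of replicates — attrition inherent to filtering on a
significance test, not an implementation defect. The funnel exposes
`require_ph` for callers who prefer to treat the diagnostic as advisory.

## Survival evaluation

Kaplan-Meier curves and the two-sample log-rank test use lifelines;
time-dependent cumulative/dynamic AUC uses scikit-survival with
inverse-probability-of-censoring weights from the KM censoring
estimator on the same data; Harrell's C uses lifelines, oriented so
higher score = higher risk (ties give 0.5). Stratification defaults to
a median split (> median = high risk; ties go low); tertile and fixed
cuts are available because no split rule is canonical.

## Synthetic data

The generator is the sampling counterpart of the variance model:
Gaussian patient effects and regional noise with per-gene (W, B), so
true ρ = W/(W+B) is known per gene. Defaults emulate a small
multi-region study (10 patients × 3 regions); region counts may be
unbalanced. Survival is exponential with log-hazard = log λ + score
(controllable PH effects) and independent Uniform(0, u) censoring, u
calibrated numerically to the target censoring fraction. VAFs are Beta
with given center and spread (spread = SD; zero spread degenerates to
constant VAFs). One integer seed determines all output bit-for-bit.

The two-cohort funnel scenario plants 2 genes that are low-ρ (0.05),
strongly differential (shift 1.2 at n = 60/60, BH-effective power
> 0.999) and survival-associated (per-gene log-HR 0.45 at n = 250,
~200 events; Cox power ≈ 1) in both cohorts, against 498 background
genes with ρ ∈ U(0.5, 0.95), weak shifts U(0, 0.3) and no survival
effect. Effect sizes were set by power analysis so that every funnel
stage except the PH diagnostic operates at ~full power, and the
moderate hazard effect keeps omitted-covariate (frailty) distortion of
the marginal PH fits small.

What the generator does *not* emulate: count-level noise and
normalization artifacts, gene-gene correlation structure, subtype
mixtures, immune-cell composition, spatial coordinates, and
copy-number-driven VAF shifts. Passing tests therefore demonstrate
estimator correctness and calibration under the stated model, not
robustness to real-data violations of it.

## Numerical conventions

- Negative variance components truncated at 0 before ITVS; CCS clipped
  to [0,1]; IHS boundary inclusive-low.
- Trapezoidal integration for AUPC over unit steps in k.
- Newton steps clipped to ±1 per iteration (damps early overshoot);
  convergence at |step| < 1e-9; exp arguments clipped at ±500.
- Per-gene failures (constant gene, non-convergence) yield flagged rows,
  never batch aborts.
- Pipeline outputs are TSV with `%.10g` floats plus a JSON manifest
  (input SHA-256 hashes, parameters, seed, version); identical config +
  seed reproduces outputs byte-for-byte.

## Problem sizes in the test and acceptance runs

Validation simulations use P = 10–20 patients, 3–4 regions, 100–500
genes, cohorts of n = 200–250 with 200 replicates for calibration
checks and 10–20 replicates for recovery rates — sizes at which the
checked quantities are statistically decisive while the whole suite
runs in a couple of minutes on one core.

## Known limitations

- ITVS assumes a two-level (patient/region) design; deeper nesting and
  covariate adjustment are out of scope.
- CCS on a single gene's 1-D values is coarse for mid-range
  heterogeneity (few distinct partitions at small N); its information
  content grows with cohort size.
- The built-in DE test does not moderate variances; small-sample DE is
  better supplied externally.
- The published two-gene weights are consumed as configuration; the
  forest-based importance estimation that produced them is not
  re-trained here. When the funnel output is used without external
  weights, the pipeline falls back to training-cohort Cox coefficients
  as linear weights.
- Whether genes should be pre-filtered by expression level before
  heterogeneity scoring is data-dependent; a `min_mean_expression`
  filter exists but defaults to off.
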