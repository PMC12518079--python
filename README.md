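# tumorhet

Gene-level intra-tumor heterogeneity (ITH) scoring for multi-region
tumor RNA-seq, plus the downstream machinery for building a
heterogeneity-aware prognostic signature.

Multi-region sequencing shows that many genes vary as much between
regions of one tumor as between patients, which makes them unreliable
biomarkers: a single biopsy may not represent the tumor. `tumorhet`
quantifies that instability per gene and selects prognostic genes that
are *stable* within tumors.

## The scores

For each gene, expression across P patients with multiple regions each
is decomposed with a one-way random-effects model into within-tumor
variance *W* and between-tumor variance *B*:

- **ITVS** = W / (W + B) — the intra-tumoral variability score; near 1
  means regional noise dominates patient identity.
- **CCS**: the gene's values are hierarchically clustered and the tree is
  cut into k = 1..N clusters. At each k, PGOR is the fraction of
  multi-region patients whose regions stay in one cluster; AUPC is the
  trapezoidal area under the PGOR-vs-k curve, and
  CCS = 1 − AUPC/(N−1). Genes that keep patients together score low.
- **IHS** = √(ITVS × CCS) — the integrated heterogeneity score. Genes
  with IHS ≤ 0.5 are classified **low-ITH**.
- **MATH** = 100 × MAD/median of a sample's variant-allele fractions
  (MAD scaled by 1.4826) — the genomic-heterogeneity companion score.

Prognostic selection funnels differential genes (|log₂FC| > 0.137,
FDR < 0.05) through univariate Cox screens with a proportional-hazards
check in two independent cohorts, keeps genes with consistent hazard
direction, and intersects them with the low-ITH set. The surviving
genes form a linear risk score; the packaged default is the published
two-gene model

    risk score = 0.024 × CYP4B1 + 0.02 × GBP1

evaluated with Kaplan-Meier/log-rank, time-dependent AUC (IPCW) and
Harrell's C.

## Worked example

Everything runs on synthetic cohorts with known ground truth (no
external data needed). Scoring a 10-patient × 3-region cohort where
half the genes are generated patient-stable (true within-fraction
ρ = 0.1) and half noisy (ρ = 0.9) — `examples/01_score_heterogeneity.py`:

```text
gene_id        W        B     ITVS      CCS      IHS ith_class  rho
 G00001 0.078737 0.555146 0.124214 0.820690 0.319282       low  0.1
 G00002 0.158468 0.668481 0.191629 0.917241 0.419250       low  0.1
...
low-rho (stable): {'low': 49, 'high': 1}
high-rho (noisy): {'high': 50}
```

The estimated ITVS tracks the generating ρ, and the IHS ≤ 0.5 rule
separates the two populations almost perfectly. The other examples
cover MATH (`24.71` for the hand set {0.2, 0.25, 0.3, 0.35, 0.4}), the
full selection funnel (recovers the two planted low-ITH prognostic
genes), risk-model evaluation (log-rank χ² = 50.4, C-index = 0.712 on a
score-driven cohort) and the end-to-end configured pipeline.

There is also a thin CLI:

```bash
tumorhet run --out demo --seed 1        # full synthetic pipeline
tumorhet synth --out cohort             # write a synthetic cohort as TSVs
tumorhet ihs --expr cohort/expression.tsv --map cohort/sample_map.tsv
tumorhet math --mutations cohort/mutations.tsv
```

## Layout

- `src/tumorhet/` — `datamodel` (types + TSV I/O), `simulate`
  (ground-truth generators), `variance` (W/B/ITVS), `consistency`
  (PGOR/AUPC/CCS/IHS), `mathscore`, `survival` (Cox screen, KM,
  log-rank, AUC, C), `signature` (funnel + risk model), `pipeline` +
  `cli` (orchestration).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices and known
  limitations.
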