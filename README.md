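# metac — transcriptomic MetA-C subtyping of prostate-cancer metastases

Metastatic prostate cancer is treated primarily by androgen deprivation, but
patients respond very differently, and bulk metastasis samples are rarely pure:
most carry a *mixture* of transcriptomic subtypes. The MetA-C framework
describes three such subtypes of prostate-cancer metastases — **MetA** (high
androgen-receptor activity, relatively favorable prognosis), **MetB** (high
proliferation and DNA-repair activity, poor prognosis, enriched for *RB1*
loss), and **MetC** (EMT/inflammation phenotype). `metac` implements the full
analysis pipeline around this classification for computational biologists who
want to apply it to their own expression cohorts or study its statistical
behavior:

1. **Signature construction** (`metac.signature`) — one-vs-rest Mann-Whitney
   marker selection with a median fold-change floor (FC = 2^(Δ log2 medians) ≥
   1.5), a cross-cohort consistency filter, and a genes × 3 reference profile
   matrix **S** built from representative (centroid-nearest) samples.
2. **Fraction deconvolution** (`metac.deconvolution`) — per sample, solve
   *m ≈ S f* with *f ≥ 0, Σf = 1* by linear ν-support-vector regression over a
   ν grid (CIBERSORT-style), with a deterministic NNLS reference solver, and
   call the dominant subtype per sample.
3. **Phenotype scores** (`metac.scores`) — AR-activity / proliferation /
   NEPC-like scores as first-principal-component *t1* values of predefined
   gene-set submatrices.
4. **Enrichment** (`metac.enrichment`) — empirical-Bayes moderated-t gene
   ranking and preranked GSEA (weighted Kolmogorov-Smirnov ES, permutation
   NES, positive/negative-pool FDR), plus cross-cohort hallmark consistency.
5. **Genomics** (`metac.genomics`) — SNV retention rules (truncating classes
   plus SIFT∧PolyPhen-damaging nonsynonymous), CNV calls (gain ≥ 4, loss ≤ 1),
   frequency/expression filters, dual Mann-Whitney lesion selection, and OPLS
   modeling of the MetB fraction from CNV-linked transcripts.
6. **Survival** (`metac.survival`) — Kaplan-Meier curves with log-rank tests
   and Cox proportional-hazards regression (Newton-Raphson on the Efron
   partial likelihood; hazard ratio = exp(β)).
7. **Synthetic cohorts** (`metac.synthetic_data`) — generator with full ground
   truth (Dirichlet subtype fractions, planted markers, a deleterious-SNV gene
   and 21-gene deletion block logistic in the MetB fraction, exponential
   survival with log-hazard linear in MetB), so every stage is testable
   without patient data.

## Worked example

```bash
metac simulate --seed 3 --n-samples 30 --out sim/
metac signature --expr sim/reference_expression_linear.tsv \
                --labels sim/reference_labels.tsv --scale linear --out sig/
metac fractions --expr sim/expression_linear.tsv --signature sig/signature.tsv \
                --scale linear --no-quantile-norm --out fractions.tsv
metac survival  --fractions fractions.tsv --annotation sim/annotation.tsv \
                --out surv/
```

which prints (numbers from this exact run):

```
wrote synthetic cohort (2000 genes x 30 samples) to sim
selected 180 markers; signature (180, 3)
wrote fractions for 30 samples to fractions.tsv
median survival by dominant subtype - MetA: 3.90y, MetC: 4.40y, MetB: 0.75y
log-rank p = 0.0037
```

`fractions.tsv` holds one row per sample: the estimated MetA/MetB/MetC
fractions (nonnegative, summing to 1), the reconstruction RMSE and
correlation, and the dominant-subtype call. The survival report shows the
MetB-dominant group with the shortest median survival — the planted hazard
structure (log-hazard slope ≈ 2.77 per unit MetB fraction) recovered by the
pipeline. The same stages are available as library functions
(`metac.pipeline.run_pipeline` chains them).

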