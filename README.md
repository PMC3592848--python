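# pathassoc

A case-control association pipeline for candidate-gene panels organised into
biological pathways, of the kind used to study immune-related susceptibility
to papillary thyroid cancer. It covers the full analytic chain for a panel of
tag SNPs in candidate gene regions:

1. **Genotype QC** — assay failure, monoallelic calls, replicate
   concordance, call-rate, an exact Hardy–Weinberg test in controls, minor
   allele frequency, and the Tarone minimum-attainable-significance filter
   for uninformative discrete tests.
2. **Per-SNP inference** — logistic regression of case status on
   minor-allele dosage (0/1/2), crude or adjusted for sex, attained age in
   four categories and year of birth as an ordinal; a 1-df trend test,
   genotype-category odds ratios against the common homozygote, and
   interaction likelihood-ratio tests.
3. **Multiplicity** — Benjamini–Hochberg step-up FDR, with an `m` override
   so the top-k hits of an m-test scan can be adjusted against the full scan.
4. **Hierarchical p-value combination** — the permutation-based adaptive
   rank truncated product (ARTP), combining SNP trend p-values into gene
   regions, regions into pathways, and pathways into one overall p-value,
   with or without multi-pathway gene overlap.
5. **Two-locus LD** — EM haplotype-frequency estimation from unphased
   dosages and the D′ / r² summaries, by default in controls.
6. **Synthetic cohorts** — a generator that emulates the frequency-matched
   study design (344 cases / 452 controls, heavily female controls, LD
   blocks, planted per-allele odds ratios, a rare comorbidity with a large
   odds ratio), plus the referent-age assignment algorithm that copies a
   matched case's diagnosis age onto each control.

## The statistics in brief

For SNP *i* with dosage *g* ∈ {0,1,2}, the trend model is

    logit P(case) = β₀ + β₁ g + γ′z,   OR_allele = exp(β₁),

with covariates *z* per the model spec; `p_trend` is the 1-df Wald (or LRT)
p-value for β₁. Given per-SNP p-values within a group and a candidate
truncation set J, the RTP statistic is `W_j = Σ_{i≤j} log p_(i)` (the j
smallest p-values). ARTP estimates each W_j's significance `ŝ_j` by its rank
across B case/control label permutations, adapts over j via `MinP =
min_j ŝ_j`, and assesses MinP's own significance on the same permutations —
one permutation layer serves the SNP→region→pathway→overall hierarchy, which
is what makes the method respect LD within regions and the number of SNPs
combined. Permutation p-values use the add-one convention `(1 + count)/(B+1)`.

## Worked example

```python
from pathassoc import bh_adjust, pathway_analysis
from pathassoc.synthetic_cohort import default_config, simulate_cohort

ds = simulate_cohort(default_config(), seed=1)   # 344 cases, 452 controls
res = pathway_analysis(ds, B=500, seed=1, adjusted_in_permutations=False)
print({k: round(v.p, 4) for k, v in res.region_results.items()})
print(round(res.overall.p, 4))
```

prints

```
{'GENE_A': 0.004, 'GENE_B': 0.002, 'GENE_C': 0.7226, 'GENE_D': 0.9082}
0.002
```

— the two regions carrying planted effects (per-allele OR 1.6 in `GENE_A`,
2.0 in `GENE_B`) give small region-level p-values, the null regions do not,
and the overall p-value reflects the aggregated signal. The FDR arithmetic
for a scan where only the top hits are listed:

```python
>>> bh_adjust([6.08e-6, 2.23e-5, 2.8e-4], m=3985).round(4)
array([0.0242, 0.0444, 0.3719])
```

A shell workflow mirroring the library (`pathassoc simulate | qc | assoc |
fdr | ld | artp | run`) writes TSV reports shaped like a study's SNP,
gene-region and pathway tables; `pathassoc run --config run.yaml` executes
every stage with a manifest of seeds and output checksums.

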