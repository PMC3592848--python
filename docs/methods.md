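# Methods

## Data model

All analyses run over four index-aligned tables: a subjects × SNPs
minor-allele dosage matrix (values 0/1/2, `NaN` for missing calls), a
subject table (case status, sex, birth year, attained/referent age,
comorbidity indicator, extra covariates), a SNP → gene-region annotation,
and a gene-region → pathway map in which a region may belong to several
pathways. Genotypes are read from TSV (cells `0/1/2/NA`) or VCF; for VCF the
minor allele is determined per site from the sample allele frequency, with
ties broken toward ALT, and dosage counts copies of that minor allele.
Missing genotypes are dropped listwise per SNP in every analysis; there is
no imputation. When case/control status is available the minor allele and
MAF are defined in controls (matching the convention of testing
Hardy–Weinberg equilibrium in controls); otherwise in the full sample.

## Quality control

Filters run in a fixed order — assay failure (all calls missing),
monoallelic, replicate concordance (< 0.95 when replicate pairs are
supplied), SNP completion (< 0.90), exact HWE in controls (p < 1e-5),
subject completion (< 0.90), MAF (< 0.10, the boundary value kept), and the
Tarone informativeness filter — and a SNP failing several filters is charged
to the first. The HWE test is the exact conditional test: with the allele
counts fixed, the heterozygote count h has probability proportional to
`n! / (n_AA! h! n_aa!) · 2^h`, and the p-value sums the probabilities no
larger than the observed table's. It is computed in log space (gammaln) and
is exact to ~1e-12 against integer enumeration for any table size used in
practice. The chi-square alternative is deliberately not the default: at a
1e-5 threshold the chi-square approximation misbehaves for the rare-genotype
tables the filter is meant to catch.

The Tarone filter computes the smallest two-sided p-value attainable by any
2×3 case-control table with the observed margins, where each table's p is
the multivariate-hypergeometric tail probability under the ordering induced
by the trend statistic `T = a₁ + 2a₂` (two-sided around its conditional
expectation). Tables whose deviation from the mean is analytically tied —
exact for symmetric margins — share one p-value; the tie tolerance scales
with the deviation (1e-9·(1+dev)) because floating error in the conditional
mean grows with the statistic. The exclusion threshold has no defensible
universal default and ships unset; it is a config parameter.

## Per-SNP models

Logistic regressions are fit by Newton scoring (statsmodels) with covariance
from the observed information. The adjusted model uses sex, attained (for
controls: referent) age in four categories (<35, 35–44, 45–54, 55+;
boundaries left-closed so age 35 falls in 35–44) and birth year as an
ordinal (<1940 → 0, 1940–1949 → 1, 1950+ → 2). The trend p is Wald by
default; an LRT variant is behind a flag since either is defensible and they
agree to graphical precision at these sample sizes. Quasi-complete
separation is detected (|β| > 15 on the logit scale, or non-convergence) and
flagged; flagged fits propagate as undefined odds ratios rather than
numbers. No Firth penalty is applied by default. Rank-deficient designs drop
aliased columns deterministically from the right, recorded in the fit
summary.

A second, fully vectorised implementation of the crude (covariate-free)
trend fit exists for the permutation inner loop: Newton iterations on the
two-parameter model for every (permutation, SNP) cell simultaneously, with
closed-form 2×2 information inversion. It is validated against the
statsmodels route cell by cell in the tests. Cells that diverge, and SNPs
monomorphic among observed calls, report p = 1 and are tallied.

## FDR

Benjamini–Hochberg step-up: `q_(i) = min_{j ≥ i} min(1, m p_(j) / j)`. The
total test count m may exceed the number of supplied p-values; this exists
because published tables typically list only the top hits of an m-test scan
while their FDR column was computed against the full scan. The caller
asserts the supplied values are the m smallest. No Benjamini–Yekutieli or
Storey variants.

## ARTP combination

For a group of K units with per-unit p-values and truncation candidates
J ⊆ {1..K}, the RTP statistic at j is the log-product of the j smallest
p-values. The permutation layer is built once at SNP level: case/control
labels are permuted B times across subjects (covariates and genotypes stay
attached to their subjects, so LD and covariate structure are preserved
under the null), and per-SNP trend p-values are recomputed for every row;
row 0 holds the observed labels. For each group, each row's W_j gets a
significance estimate from its rank among the other rows,
`ŝ_j = (1 + #{b′≠b : W_j^{b′} ≤ W_j^{b}})/(B+1)`, the adaptive statistic is
`MinP = min_j ŝ_j`, and the group p-value is MinP's add-one rank among the
permuted rows. The per-row MinP values become the next level's p-value
matrix, so regions → pathways → overall reuse the same permutations — the
construction that keeps the hierarchy honest about selection over j. Ties
rank as "≤" for observed and permuted rows alike (slightly conservative),
and all permutation p-values live on {1/(B+1), …, 1}; requesting resolution
beyond 1/(B+1) reports the floor.

Defaults that the method itself does not dictate: J = {1, …, min(K, 10)} at
each level; B = 10,000 for real runs and 500 in tests; unrestricted label
permutation (a within-sex stratified variant is behind a flag); and a speed
knob that uses the crude trend p inside permutations, since refitting the
adjusted model B×K times is the dominant cost. The "without overlap"
pathway variant removes every multi-allocated gene region from all of its
pathways before combining; a pathway emptied by the removal is reported as
not estimable. The overall p-value combines the pathway-level columns.

## Two-locus LD

Haplotype frequencies for a SNP pair are estimated from unphased dosages by
EM: only double heterozygotes are phase-ambiguous, the E-step splits them
between cis and trans in proportion to the current frequency products, and
the M-step re-counts; initialisation is linkage equilibrium at the observed
allele frequencies, convergence at max|Δf| < 1e-10 or 1000 iterations. From
the fitted frequencies, `D = f₁₁ − p₁q₁`, D′ normalises |D| by its
frequency-bound maximum in the direction of D, and `r² = D²/(p₁(1−p₁)
q₁(1−q₁))`. LD summaries default to controls only. Monomorphic loci make LD
undefined and are flagged rather than zeroed.

## Synthetic cohorts

The generator emulates a frequency-matched case-control study of papillary
thyroid cancer, and its defaults are the emulated study's conditions:
344 cases / 452 controls; a source population 85% female with a male
log-odds-ratio of log(3.7), which yields ≈93% female controls and ≈80%
female cases after case-control selection; haplotype-block genotypes with
all MAFs ≥ 0.10, including one tag-SNP pair at D′ = 0.95, r² ≈ 0.46;
planted per-allele odds ratios of 1.6 and 2.0 in two of four gene regions;
and an autoimmune-thyroiditis-like comorbidity with conditional odds ratio
6.4 targeted at 2% prevalence *in controls*. Genotypes are drawn as two
i.i.d. haplotypes per subject from block-specific pools, so within-block LD
is exactly the pool's. Disease status follows the logistic model
`logit P(case) = β₀ + β_male·[male] + Σ β_g·g + β_com·[comorbid]`, and
subjects are rejection-sampled in batches until the case and control quotas
fill exactly. Because the comorbidity raises disease risk, its carriers are
depleted among sampled controls; a pilot batch estimates the depletion and
the population draw probability is calibrated so the control prevalence hits
the configured value. The crude comorbidity odds ratio measured in pooled
simulated cohorts comes out slightly below the conditional 6.4 (≈6.0) — the
expected non-collapsibility attenuation from the other risk factors.

Referent ages: each control receives the diagnosis age of a case selected
uniformly at random from the stratum matching on sex and birth year ± 2
years; if the stratum is empty the sex criterion is dropped first, then the
birth-year criterion, so every control is eventually assigned. Cases may be
reused across controls. The relaxation order and window are configurable;
all randomness flows from one seed and the assignment is deterministic
given it.

What the generator does not emulate: coalescent population structure,
genotyping-error processes, relatedness, ancestry admixture, or realistic
genome-scale panel sizes. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the assumed
model, not robustness to those real-data complications.

## Numerical and testing choices

Logistic convergence: Newton, tol 1e-10, 100 iterations; vectorised crude
fitter: score tolerance 1e-8, 25 iterations, divergence guard at |β| > 15.
EM likelihood is verified non-decreasing in tests. Exact tests are compared
against independent enumeration oracles (exact-integer arithmetic for HWE,
scipy's multivariate hypergeometric for the Tarone bound) to 1e-12:
exhaustively for all genotype tables up to 50 subjects (HWE) and all margin
configurations up to 10 subjects plus random margins up to 50 (Tarone,
where full enumeration to 50 is combinatorially out of reach of a test
suite). The ARTP implementation is checked against a literal plain-loop
transcription of its definition on random matrices and against brute-force
evaluation over all C(8,4) label assignments on an 8-subject fixture. The
permutation type-I calibration uses 200 null cohorts of 50/50 subjects at
B = 500 with the crude-p knob — the calibration property does not depend on
cohort size, and these sizes keep the check fast. Parameter recovery uses
500 replicates at the study's 344/452. The EM recovery check averages 10
draws at n = 5,000 because phase ambiguity inflates the estimator's
variance above the binomial bound that a single-draw 3-SE check assumes.

## Known limitations

Adjusted-model permutations are computed fit-by-fit and are slow for large
B×K; use the crude knob or stratified permutation for big runs. The Tarone
filter threshold is study-specific and ships unset. The LD module handles
pairs of biallelic loci only; no haplotype blocks or multi-locus phasing.
P-values from permutation are bounded below by 1/(B+1), so genuinely tiny
pathway p-values need B sized accordingly.
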