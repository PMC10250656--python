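# Methods

This note documents the models and procedures implemented in `dytburden`,
the defaults chosen where the design was open, and what the synthetic
validation does and does not establish.

## Variant classification

A variant's analysis class is derived purely from its annotation row:

- **LoF**: exonic function stop gain, stop loss, or frameshift; or splicing
  with a junction offset of at most 2 bp in absolute value. A splicing
  variant without an offset is an error rather than a silent non-LoF,
  because the 2 bp rule cannot be evaluated.
- **Dmis** (damaging missense): missense with ReVe ≥ 0.7 (inclusive). A
  missense variant with no ReVe score is treated as non-damaging and
  logged — this is conservative for candidate calling, anticonservative for
  nothing (the variant still enters the plain missense burden cells).
- **deleterious** = LoF ∪ Dmis. The plain *missense* subgroup deliberately
  ignores pathogenicity scores.

Rarity uses the *effective* gnomAD East-Asian frequency: the maximum of the
exome and genome values when both are present, the available one otherwise,
and 0 when both are missing ("novel"). Maximum-combination is the
conservative choice — a variant common in either source is not rare. The
two pairings are otherwise treated symmetrically since nothing distinguishes
them downstream. Rarity comparisons are strict (`< 0.01`, `< 0.001`), and
the 0.001 cells are by construction nested in the 0.01 cells.

## Candidate prioritization

Recessive model (genes annotated AR or with both patterns): per case sample,
every deleterious homozygote with effective MAF < 0.01, and every unordered
pair of distinct deleterious heterozygotes in the same gene (both MAF
< 0.01). Phase is not required — pairs are *putative* compound
heterozygotes, and a sample with three qualifying heterozygotes yields three
pair findings. Dominant model (AD or both): deleterious heterozygotes with
MAF < 0.001; homozygotes are not emitted under this model. Dual-pattern
genes run through both models independently. Missing genotypes count as
non-carrier (conservative calling). Familial recessive/dominant probands go
through the same machinery; only sporadic subgroups enter the burden scan.

Control screening removes a dominant finding if any healthy control carries
the variant, and a recessive finding only if some control is biallelic
(homozygous for the variant, or — for a pair — homozygous for either member
or carrying both). Screening is monotone: adding control carriers can only
remove findings.

### ACMG engine

The published classifications reflect expert judgment, so the evidence
engine is configuration-driven (YAML): each evidence code is a predicate
with parameters, and the combining table lists, per class, the code sets
that suffice, optionally restricted to an inheritance model. The shipped
default assigns

- `PVS1` — LoF in a gene on the LoF-mechanism allowlist (default: all
  panel genes; the allowlist exists because LoF pathogenicity is
  gene-mechanism dependent),
- `PM2` — effective MAF exactly 0 and no control carrier,
- `PP3` — at least 4 of 7 computational predictors damaging, where CADD
  counts as damaging at phred ≥ 20 (configurable; the six categorical
  predictors contribute their stored calls),

and combines: P ⇐ PVS1+PM2 or PVS1+PP3; LP ⇐ PVS1 alone, or PM2+PP3 *under
the dominant model only*; otherwise US. The model-scoped LP rule is the
load-bearing choice: novel, well-supported missense variants reach LP as
heterozygous dominant candidates but stay US inside recessive genotypes,
which reproduces the worked-example classes exactly (a shipped regression
test). A compound-heterozygous finding takes the weaker of its two members'
classes.

## Runs of homozygosity

A PLINK-style scan: per chromosome, windows of 50 consecutive SNPs are
homozygous-compatible when they contain ≤ 1 heterozygote and ≤ 5 missing
genotypes; a SNP is marked when ≥ 5% of the windows covering it are
compatible; maximal runs of marked SNPs with ≥ 50 SNPs spanning ≥ 1 Mb
become intervals. All five numbers are parameters (`RohParams`) — they are
declared defaults in common usage, not inferred from any dataset. Interval
length is `end − start` in bp, matching how printed interval endpoints are
normally differenced. Window support thins at tract edges, so a detected
interval is slightly narrower than the underlying tract; containment checks
use closed endpoints.

## Burden testing

### Null model

Logistic regression of case status on age, sex (0 = female, 1 = male), and
five principal components, fitted by IRLS (statsmodels GLM; tolerance 1e-8,
25 iterations). Samples missing age or sex are dropped with a logged count
— no covariate imputation. Separation and non-convergence raise; the
cohort-level scan additionally falls back to an intercept-only null with a
logged warning when the covariate model separates, which keeps degenerate
(e.g. very small) cohorts testable with an unadjusted score test.

### Statistics and p-values

For a cell's genotype matrix `G` (missing dosages mean-imputed per variant
within the analyzed samples), scores `S = Gᵀ(y − μ)`, weights `w`, and

    Q(ρ) = (1 − ρ) Σ (w_j S_j)² + ρ (Σ w_j S_j)².

Under the null, `Q(ρ)` is a quadratic form in the variance-weighted,
covariate-projected genotypes `Z₁ = V^{1/2}(I − H)GW`, with null
distribution `Σ_k λ_k χ²₁` given the eigenvalues of
`R_ρ^{1/2} Z₁ᵀZ₁ R_ρ^{1/2}` (`R_ρ = (1−ρ)I + ρJ`, square root in closed
form). Tail probabilities come from Imhof's characteristic-function
integral, evaluated by a vectorized composite Gauss–Legendre rule whose
truncation point and node density follow the integrand's envelope and
oscillation frequency; the error target is 0.1% of a moment-matching
pre-estimate (floored at 1e-12 absolute), validated against adaptive
quadrature and Monte-Carlo simulation. Equal-eigenvalue cases reduce to an
exact scaled χ². The Liu–Tang–Zhang noncentral-χ² approximation serves as
the fallback on numerical failure. An empty cell or an all-zero kernel is
reported *untested*, which is distinct from p = 1.

SKAT-O minimizes the per-ρ p-value over the grid
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (the method's published default;
configurable) and converts the minimum `T` back to a p-value via the
decomposition of the `Q(ρ)` family into a shared burden component `η₀ ~ χ²₁`
and an orthogonal remainder: per-ρ quantiles at level `T` are obtained from
moment-matched per-ρ null distributions, and
`P(all Q(ρ) below their quantiles)` is integrated over `η₀` (substituting
`x = t²` removes the density's origin singularity; 80 Gauss–Legendre
nodes). Inside that integral the remainder's tail is evaluated by Imhof
when `T` < 0.2 — where accuracy determines the result — and by the Liu
approximation otherwise (the two differ by < 0.007 in the bulk, a speed
choice). The final p is clamped to `[T, |grid| · T]`, the analytic envelope
of a minimum-p combination; ρ = 1 is capped at 0.999 inside the integral to
keep the change of variables finite. Single-variant cells reduce exactly to
the χ²₁ score test, and one-point grids reduce to pure SKAT (ρ = 0) or pure
burden (ρ = 1).

A label-permutation evaluation (`skat_o_permutation`) recomputes `Q(ρ)`
under phenotype permutations, ranks per-ρ p-values empirically, and returns
the rank of the observed minimum — an oracle that shares no numerical
machinery with the analytic path. It is exact only for exchangeable
phenotypes (intercept-only null).

### Scan conventions

- Weights: Beta(1, 25) density at the cohort alternate-allele frequency
  (the rare-variant convention); flat weights by config.
- Cell membership uses the annotation's population frequency; the cohort
  frequency enters only through the weights.
- Carrier counts use raw (non-imputed) dosages, dosage ≥ 1.
- Bonferroni divides by the number of panel genes only (0.05/47 ≈ 0.001),
  mirroring standard practice for gene-panel scans; with 8 cells per gene
  this is anti-conservative across cells, which is why the uncorrected
  p < 0.05 band is labeled merely "suggestive".
- Early-onset sporadic cases pair with control group 1 and late-onset with
  control group 2 (WES- and WGS-matched); familial probands are excluded
  from burden testing.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per-gene variant
counts Poisson (mean 30), population MAFs log-uniform on (1e-4, 0.01) — the
1/f shape of the rare end of a neutral site-frequency spectrum — consequence
classes drawn from a configurable mix (default 45% missense, 20% Dmis, 10%
LoF, 25% synonymous, with ReVe drawn inside/outside the damaging range
accordingly), Hardy–Weinberg genotypes, covariates (age normal with
subgroup-appropriate means 43/62 ± 8, sex Bernoulli(½), PCs standard
normal), and case status from a logistic model with optional per-gene
carrier log-odds. The annotation frequency equals the simulated population
frequency (optional missingness), so database/cohort frequency divergence is
not modeled; nor are linkage disequilibrium, phasing, sequencing error, or
pedigrees. Desk-scale defaults are 200 cases vs 200 controls over 10 genes;
a study-shaped configuration (1,508 vs 1,652 and 1,962 vs 1,279) is
provided. Under a fixed seed the generated file triple is byte-identical.

The worked-example fixtures hard-code the published candidate variants
(positions, alleles, frequency pairs, CADD, ReVe, carriers) and add decoys,
each engineered to violate exactly one filter (common frequency, low ReVe,
synonymous class, unpaired heterozygote, control carrier/biallelic, or
homozygosity under the dominant model), so a fixture failure localizes the
broken filter. The ROH fixture embeds a ~5.36 Mb homozygous tract with
heterozygous flanks around the recessive candidate position.

## Calibration choices for the validation suite

- Type-I error is measured at the stated conditions n = 500, five variants,
  covariates present, MAF uniform on (0.001, 0.01) — uniform chosen as the
  neutral reading of a stated range; 2,000 replicates at α = 0.05.
- Oracle agreement uses 10,000 permutations and a 3-standard-error band.
- The spiked-gene power property uses the desk-scale defaults with a
  five-fold carrier log-odds spike on one gene and asks how often that gene
  attains the scan's minimum p over 50 seeded replicates.

Passing these tests shows the statistical core is calibrated and the filters
implement their definitions — not that the method would reproduce any
particular real-cohort result, since the synthetic data lack the real
cohort's LD, annotation error, and frequency misspecification.

## Known limitations

- At desk scale, a gene's deleterious-carrier count is often ≤ 15, so the
  spiked-gene power property is materially weaker than at study scale: with
  tens of correlated cells in the scan, replicates in which the spiked gene
  happens to draw few carriers cannot be rescued by any effect size. Power
  statements therefore depend strongly on simulated cohort size.
- No small-sample moment adjustment is applied to the kernel statistics;
  with very few carriers the analytic tail is slightly conservative at
  α = 0.05 (measured rejection ≈ 0.04–0.05) and less reliable deep in the
  tail.
- The ACMG engine is a reduced, three-code default intended to be
  configured; it does not implement the full guideline's evidence codes.
- Haploid/hemizygous genotypes are rejected (the panel is autosomal), and
  multi-allelic records must be split upstream or by the VCF reader.
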