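# Methods

## Scope and model

`targetmr` estimates the causal effect of a druggable gene's expression on
a binary disease outcome from two independent sets of summary statistics:
cis-eQTLs (exposure) and a case-control GWAS (outcome).  The underlying
identification assumptions are the usual instrumental-variable triad —
relevance (the SNP affects expression), exchangeability (no confounding of
SNP–outcome), and exclusion (the SNP affects the outcome only through
expression).  Restricting instruments to the cis window and removing
confounder-associated SNPs addresses the second and third assumptions
operationally; the Steiger test, MR-Egger intercept and colocalization act
as falsification checks rather than guarantees.

All coordinates are 1-based GRCh37-convention base pairs; no genome-build
conversion is attempted.  Exposure effects are in SD units of expression,
outcome effects in log-odds, so every causal estimate is log-odds per SD of
expression and is reported as OR = exp(β) with a Wald 95% CI.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| cis window | ±100,000 bp of the TSS, boundary inclusive | standard cis definition; inclusivity is frozen in tests because the prose convention ("within ±100 kb") does not specify the boundary |
| eQTL FDR | < 0.05, strict | per-record FDR from the eQTL catalogue |
| clump r² | < 0.001 | instruments approximately independent; ties on identical p broken by larger F, then snp_id, so output is order-invariant |
| palindromic EAF zone | [0.42, 0.58] | community convention; palindromic SNPs inside the zone, with missing frequency, or with discordant minor-allele sides are dropped |
| frequency concordance | |Δeaf| ≤ 0.2 | catches build/population mismatches on non-palindromic SNPs |
| coloc priors | p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵ | standard single-causal-variant priors |
| coloc effect priors W | 0.15² quantitative / 0.2² case-control | coloc-convention defaults; configurable, since the catalogue priors are not identified from the data |
| PP4 threshold | > 0.75, strict | high-support colocalization verdict |
| MR FDR | BH q < 0.05, one family per exposure-dataset × outcome | mirrors separate per-tissue gene lists |

Instrument strength F = (β/se)² is computed and reported for every
instrument; no automatic F filter is applied (a config flag can enforce
F ≥ 10).

## Estimators and numerical choices

- **Routing**: 1 instrument → Wald ratio; ≥2 → fixed-effect IVW (the
  multiplicative random-effects inflation `max(1, √(Q/(n−1)))` is a flag);
  ≥3 → MR-Egger and weighted median recorded as sensitivity columns.  The
  "more than two variants" gate for sensitivity analyses is read as
  nsnp ≥ 3, the minimum both estimators require.
- **Wald SE**: first-order delta method se(β̂ᵧ)/|β̂ₓ| by default — the
  dominant convention.  It ignores exposure-side noise, so with instrument
  strength around F ≈ 1600 and a non-zero causal effect the 95% CI covers
  at ≈ 0.93 rather than 0.95 (the acceptance suite measures this); the
  second-order variant (adds β̂ᵧ²se(β̂ₓ)²/β̂ₓ⁴) restores near-nominal
  coverage and is available by flag.
- **MR-Egger** is fit by weighted least squares (weights 1/se(β̂ᵧ)²) after
  orienting all instruments to β̂ₓ ≥ 0; inference uses the t reference on
  n−2 df.  An all-equal-β̂ₓ design raises a singularity error.
- **Weighted median**: order statistics of the per-instrument ratios
  interpolated linearly at cumulative weight 0.5 with weights
  β̂ₓ²/se(β̂ᵧ)²; the SE is a parametric bootstrap (1000 resamples of both
  betas from their Normal sampling distributions, seed-controlled for
  determinism).
- **Steiger flag at gene level**: a gene is marked orientation-correct only
  if *every* retained instrument individually explains more variance in
  expression than in the outcome (conservative conjunction; the aggregation
  across instruments is otherwise unspecified).
- **BH-FDR** is the exact step-up adjustment (cross-checked in the tests
  against statsmodels), input order preserved.
- **Colocalization** accumulates hypothesis evidence entirely on the log
  scale with log-sum-exp; the H3 sum excludes the shared-SNP diagonal
  explicitly rather than using the cancellation-prone S₁S₂ − S₄ identity,
  and is stable for |z| well beyond 50.  SNP intersection is by id;
  alleles are ignored at this stage because the ABF depends on z² and se
  only.  The coloc region is the full cis region supplied per gene
  (configurable), not just the clumped instrument window.
- **p-values** are clamped to ≥ 1e-300 to stay in (0, 1] under extreme z.
- Stage outputs are written with 7 significant digits so a write/read
  round trip reproduces every value within 1e-6 relative; coloc posteriors
  are renormalized on read so they sum to one at full precision.

## The synthetic-data generator

The generator works at the summary-statistics level; no individual-level
genotypes exist anywhere.  For a region with LD matrix R (block-diagonal
AR(1): r(i,j) = ρ^|i−j| within blocks of 10, ρ = 0.8, zero across blocks)
and true standardized effects b, observed marginals are drawn as

  β̂ ~ MVN(R b, D R D),  D = diag(se),  seᵢ = 1/√(2 mafᵢ(1−mafᵢ) n),

so each estimate has exactly its nominal SE plus the LD-consistent
correlation structure that clumping and colocalization implicitly assume.
Binary-trait SEs use the effective sample size 4/(1/n_cases + 1/n_controls)
with a unit phenotype-variance proxy — an approximation, documented as
such; nothing downstream depends on its absolute scale.

Defaults are frozen to the emulated study conditions: eQTL panel
n = 31,684; outcome GWAS 29,612 cases / 122,656 controls; one causal cis
variant per gene with standardized expression effect 0.35 (F ≈ 1600, about
5% of expression variance); causal expression→outcome effect θ = 0.25
log-odds per SD under the causal scenarios and 0 under the null.  Scenarios:
`null`, `causal_shared` (outcome effect propagated through the eQTL causal
variants), `causal_distinct` (outcome effect on a disjoint SNP set in a
different LD block), `pleiotropic` (adds per-SNP direct effects
N(0, σ_pleio)).  Allele pairs are non-palindromic unless requested, so
palindromic-drop behavior is exercised deliberately; a configurable
fraction of outcome rows is emitted allele-swapped and/or
strand-complemented to exercise harmonization.

What the generator does *not* emulate: realistic MAF spectra, haplotype
LD beyond AR(1) blocks, case-control ascertainment, winner's-curse
selection (available as an off-by-default significance-conditioned
resampling switch at the bundle level — not used by any default test), or
cross-tissue effect heterogeneity.  Passing tests therefore demonstrate
correctness of the statistical machinery under a known generative model,
not robustness to every pathology of real consortium data.

## Design decisions taken where the design was open

- Allele-frequency reconciliation between exposure and outcome catalogues
  is governed by an explicit tolerance (0.2) rather than a hidden rule.
- Traits in the phenome screen whose GWAS lacks the instrument SNP are
  reported "not-testable" and excluded from the BH family.
- Druggability tiers, drug safety and approval status are curated inputs
  in the gene panel and drug table, not live database calls; the Level
  I–III rubric is thereby explicit and data-driven.
- Opposite risk directions of the same gene in different tissues are kept
  as separate per-tissue rows; no cross-tissue reconciliation.
- The pipeline config hash covers analysis parameters only (not the output
  directory), so identical analyses produce byte-identical outputs
  wherever they are written.

## Problem sizes used by the validation suite

The acceptance suite and `scripts/acceptance.py` use: 1000 random
instrument sets for the estimator oracles (plus 200 regions of ≤ 10 SNPs
for the coloc enumeration oracle); 2000 replicate genes for parameter
recovery and CI coverage; 20 null panels of 500 genes for FDR control and
500 genes for Steiger; 200 + 200 fifty-SNP regions for coloc
discrimination; and one 500-gene bundle with 5 implanted causal genes for
the end-to-end run.  These sizes keep Monte Carlo error small relative to
every acceptance band while the whole validation completes in well under a
minute on one CPU.

## Known limitations

- Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition, no more-than-two-trait extension).
- No proxy-SNP substitution for instruments missing from the outcome GWAS.
- No MR-PRESSO, mode-based, or multivariable MR estimators.
- The weighted-median bootstrap SE is parametric; with very few
  instruments it can understate uncertainty.
- First-order Wald CIs slightly undercover when the causal effect is
  non-zero, as quantified above.
- With mostly single-SNP instruments (a direct consequence of clumping at
  r² < 0.001), the Egger/weighted-median sensitivity layer is exercised
  only for multi-block genes.
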