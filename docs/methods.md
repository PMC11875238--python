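# Methods

## Overview

The package evaluates drug-repurposing hypotheses for a disease outcome
(MASLD in the motivating use) entirely from GWAS summary statistics. The
chain is: summary-statistic TWAS of genetically predicted gene expression
(GPGE) → colocalization support → cis-protein MR for protein-level
targets → drug–gene mapping with directional concordance → MR of the
proxied drug effect on the outcome using tissue-level GPGE instruments.
Everything below states what each stage computes, the assumptions it
leans on, and the numerical choices made where a choice was genuinely
open.

## Summary-statistic TWAS (GPGE)

For a gene with sparse prediction weights `w_l` over cis variants, GWAS
marginal effects `β_l` (se `se_l`), and a reference LD panel giving
per-variant dosage SDs `σ_l` and correlations `r_lm`:

    σ_g² = Σ_l Σ_m w_l w_m σ_l σ_m r_lm
    Z_g  = Σ_l w_l (σ_l/σ_g) (β_l/se_l)
    effect per SD expression = Σ_l w_l (σ_l²/σ_g²) β_l,   se = effect/Z_g

Assumptions: marginal GWAS effects are well approximated as linear
projections of a polygenic trait onto single variants; the reference LD
panel matches the GWAS population. Choices:

* `σ_l` comes from the LD panel, not from GWAS allele frequencies, so the
  covariance `Σ` is internally consistent.
* Weights are **not** renormalized when some model variants are missing
  from the GWAS; `n_variants_used` is reported so users can filter.
* p-values are computed and stored in log10 space: strong loci reach
  p ≈ 1e-160, far beyond linear-scale underflow once squared. Every gate
  that compares p-values compares log10 values.
* `σ_g = 0` (exact cancellation of weights under perfect LD) is a
  degenerate-model error, not a zero division.
* The Bonferroni gate (default 2.03e-7, strict `<`) is a parameter, not a
  constant — the test count depends on how many gene×tissue pairs a user
  runs.

## Allele harmonization

GWAS, weight, and LD alleles are oriented to a common reference before any
formula is applied: direct match passes, swapped alleles negate β and flip
eaf, strand-flipped alleles are complemented first. Palindromic A/T and
C/G variants whose eaf is missing or in [0.42, 0.58] cannot be oriented
reliably and are dropped — a conservative default, since a wrong strand
call silently flips the effect sign. Multi-base alleles are accepted but
never strand-flipped. Harmonization is involution-safe (applying it twice
equals once).

## Colocalization

Per-variant Wakefield log-ABFs, `lABF = ½log(1−r) + z²r/2` with
`r = W/(W+V)`, feed the standard single-causal-variant enumeration over
H0–H4 with per-variant priors p1 = p2 = 1e-4, p12 = 1e-5 and prior effect
SDs 0.15 (quantitative) / 0.2 (case-control) — the field-standard defaults
of the ABF method, exposed as configuration. All sums use log-sum-exp; the
H3 cross term is computed as a guarded log-difference; posteriors are
renormalized at the end and a brute-force O(m²) enumerator is kept as a
test oracle. A single-variant locus has an empty H3 configuration set, so
PP.H3 = 0 exactly. Decision gates are strict: PP.H4 > 0.8 in the
expression context, > 0.7 in the protein context. The one-causal-variant-
per-trait assumption is inherited from the method.

## cis-instrument MR

Instruments: exposure variants within ±250 kb of the encoding gene with
p < 5e-8, greedily LD-pruned (ascending p, ties broken lexicographically
on variant id) to pairwise r² < 0.01. Estimator: GLS through the origin
with `Ω_ij = se_yi se_yj r_ij` — the first-order LD-aware IVW; exposure
standard errors do not enter Ω (the no-measurement-error convention of
this estimator family). Ω is PSD-clipped by eigenvalue truncation and
ridged by 1e-8 × mean diagonal before solving; a still-singular Ω raises
with advice to prune harder. One instrument delegates to the Wald ratio
with delta-method se. Discovery across targets uses Benjamini–Hochberg at
q = 0.05 (the FDR procedure was an open choice; BH is the default the
field reaches for).

## Drug–gene rules

Mechanism vocabulary is collapsed to {agonist, inhibitor} via a synonym
map (blocker, antagonist, negative modulator → inhibitor; activator,
positive modulator → agonist). A gene's risk direction is the
tissue-majority sign of its *significant* TWAS effects; ties are excluded
as "ambiguous direction". Concordance keeps (inhibitor, risk-increasing)
and (agonist, risk-decreasing). Oncology-indicated drugs are removed; a
drug reached via several genes keeps all rows but carries a
`duplicate_of` flag pointing at its primary (gene-lexicographic) pair, so
unique-medication counts stay unambiguous. Hepatotoxicity
(LiverTox-class / DILIrank-concern tables, joined on case-folded names
with salt suffixes stripped) annotates but never filters. Every removal
carries a machine-readable reason.

## Proxied-drug MR

Each tissue whose GPGE association with the drug's primary indication has
p < 0.05 and which also has an outcome GPGE contributes one instrument
(b_x = effect on indication, b_y = effect on outcome, per SD expression).
Mechanism harmonization restates inhibitor instruments per one SD
*decrease* in expression by negating b_x and b_y jointly — an instrument
redefinition that leaves the MR ratio exactly invariant, so only the
reported exposure-change sign follows the mechanism.

* Pooled exposure change: DerSimonian–Laird random-effects meta-analysis
  (τ² by the moment estimator, floored at 0; k = 1 passes through).
* Outcome effect: fixed-effects IVW across tissues, `se = (Σ b_x²/se_y²)^-½`;
  Wald ratio for k = 1. Tissues are treated as independent instruments —
  an acknowledged simplification, since tissues share eQTL architecture;
  the report flags the method per row.
* MR-Egger needs ≥ 3 instruments (reported as N/A otherwise); b_x is
  oriented non-negative before the weighted fit, the residual scale is
  floored at 1 (no under-dispersion), and the intercept is tested
  two-sided normal.
* Cochran's Q uses per-tissue Wald ratios with weights b_x²/se_y²; when
  its p < 0.05 the IVW se is inflated multiplicatively by √(Q/(k−1))
  (floor 1) — the "inflated standard errors" random-effects flavor; an
  additive DL variant would change the weighting, not just the se, and
  was deliberately not made the default.
* The outcome GWAS is assumed to be on the log-odds scale; the report
  exponentiates to odds ratios with Wald 95% CIs.

The MR coefficient is interpreted as outcome log-odds per unit genetically
proxied change in the primary indication: with true per-SD expression
effects θ_ind and θ_out, its estimand is θ_out/θ_ind, which the end-to-end
validation targets (0.4 and −0.3, hence −0.75).

## Synthetic-data generator

What it emulates: a reference LD panel, sparse tissue-shared prediction
weights, and two-trait GWAS summary statistics with known ground truth.

* **Genotypes**: Gaussian AR(1) copula — each haplotype is a latent AR(1)
  Gaussian (adjacent correlation `ld_rho`, chain restarting at each
  gene's cis block so genes are unlinked) thresholded at the normal
  quantile of a per-variant MAF ~ U(maf_range); dosage = sum of two
  haplotypes. Defaults: n = 10,000, 200 variants, MAF 0.05–0.5,
  ld_rho = 0.5.
* **Weights**: each gene×tissue gets `weights_per_gene` nonzero N(0,1)
  weights on cis variants. Tissue 0 is the causal tissue; other tissues
  reuse each of its causal variants with probability `tissue_sharing`
  (default 0.7), redrawing the weight magnitude but keeping its sign —
  cross-tissue eQTLs are overwhelmingly direction-concordant in real
  data, and the tissue-majority direction rule downstream is only
  meaningful under that concordance. Non-shared slots draw a fresh cis
  variant and a fresh signed weight.
* **Traits**: y = Σ_g θ_g · standardize(X w_g) + X α + N(0,1), with the
  causal-tissue weights defining the genetic expression score
  (standardized in-sample so "per SD expression" is exact) and
  α ~ N(0, pleiotropy_sd) optional direct variant effects to exercise the
  Egger intercept. Summary statistics are exact per-variant OLS with
  residual-variance standard errors; two-sided normal p-values.
* Alleles are drawn from non-palindromic pairs only, so generated tables
  survive harmonization losslessly. All randomness flows from the config
  seed (trait streams keyed by seed + CRC32 of the trait id); outputs are
  byte-reproducible.

What it does **not** emulate: realistic human LD maps and allele-frequency
spectra, imputation noise, binary outcome likelihoods (case-control GWAS
is approximated by a linear trait read on the log-odds scale), sample
overlap between exposure and outcome cohorts, and aptamer- or
platform-specific pQTL artifacts. Passing validation therefore shows the
estimators implement their formulas correctly and recover parameters
under the stated generative model — not that the pipeline is robust to
every pathology of real cohort data.

## Validation battery and problem sizes

`gpgemr.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses these study conditions:

* TWAS oracle: one cohort of 50,000 individuals × 2,000 variants, 50
  genes with true effects spread over [−0.3, 0.3]; agreement with the
  individual-level regression z across genes (observed r > 0.9999).
* Colocalization: 200 random ≤12-variant loci for the enumeration oracle;
  100 shared- and 100 distinct-causal loci (z≈10, AR(1) ρ = 0.9, 100
  variants) for discrimination.
* cis-MR: θ ∈ {−0.3, 0, 0.3}, 50 cohorts each of 10,000 individuals × 40
  variants; the exposure trait carries the gene's standardized score with
  coefficient 1 (a noisy protein), making θ the exact MR estimand.
  Type-I error is measured over 400 null cohorts — at 50 replicates the
  binomial noise of a rate near 0.05 swamps the quantity being measured.
* Proxied-drug MR: 50 ten-tissue cohorts of 20,000 individuals, true
  effects 0.4 (indication) and −0.3 (outcome), estimand −0.75.
* Egger/Q calibration runs at the tissue-instrument level (b_x ~
  U(0.2, 1), se_y = 0.05, directional pleiotropy N(0.2, 0.05) per
  instrument at k = 20): that is the generative scale of the quantity
  Egger tests, whereas variant-level direct effects do not map one-to-one
  onto tissue-level intercepts.
* BH-FDR: 200 mixtures of 100 p-values, 60% null, alternatives
  z ~ N(3, 1).

## Known limitations

* Single-causal-variant colocalization; no multi-signal (SuSiE-style)
  extension.
* LD-aware IVW ignores exposure-side uncertainty (NOME); weak-instrument
  regimes will under-cover.
* Tissue instruments are treated as independent; correlated tissues make
  the fixed-effects IVW se anti-conservative, partially absorbed by the
  random-effects fallback.
* The drug catalogue, LiverTox, and DILIrank contents are user-supplied;
  the package implements the joins and rules, not the databases.
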