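# Methods

This document records the statistical model, the default parameters and
their rationale, the scope of the synthetic data generator, and the
numerical choices behind `nagpipe`. Conventions stated here are the
package's contract; the test suite enforces them at the boundaries.

## 1. Alteration calling and burden score

A gene is **altered** in a tumor when at least one of the following holds:

* it carries a somatic non-synonymous variant (synonymous records are
  rejected at construction time), or
* its gene-level copy-number log-R ratio (LRR) satisfies LRR > 0.5 (gain)
  or LRR < −0.5 (loss). Both inequalities are **strict**: a value of
  exactly ±0.5 is neutral.

Gene symbols are normalized once (trim + uppercase). The binary
patients × genes indicator drops genes altered in fewer than
`min_patients_recurrent = 2` tumors before modeling — a singleton
alteration cannot support a reproducible panel membership.

The **NAG score** of a patient is the number of altered genes within the
prognostic panel. Cohorts are dichotomized at the first quartile of the
score distribution (linear-interpolation "type 7" quantile; scores exactly
at the cutoff go to **low**). In validation, a frozen absolute threshold
*t* may be supplied instead: a patient is **high** iff score ≥ *t*.

## 2. Elastic-net Cox panel selection

The panel is the support of an elastic-net penalized Cox model
(Breslow tie handling) on the alteration matrix:

* Objective: negative log partial likelihood / n plus
  λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²), with **α = 0.1** — mostly ridge, so that
  correlated panel genes are retained together rather than arbitrarily
  pruned, with just enough ℓ₁ to produce a finite panel.
* Covariates are standardized internally with population (1/n) standard
  deviations; coefficients are reported on the original scale.
* λ grid: 100 geometrically spaced values from λ_max down to
  λ_max·10⁻⁴, where λ_max = max_j |x_jᵀ g₀| / (n·max(α, 10⁻³)) is the
  smallest λ with an all-zero solution. λ_max is inflated by a relative
  10⁻⁹ so the first path point is *exactly* zero in floating point.
* Solver: inexact proximal Newton in the glmnet style — each IRLS
  relinearization of the Breslow likelihood is followed by a fixed small
  number (5) of coordinate-descent sweeps rather than an inner solve to
  convergence. Warm starts along the grid. Convergence is declared on the
  maximum weighted coefficient change; first-order optimality is verified
  separately: the subgradient (KKT) residual must not exceed 10⁻⁶ at
  every grid point.
* Early stopping (on by default) truncates the path once the fractional
  gain in deviance explained becomes negligible, matching the usual
  path-fitting practice. Computations that need the full grid (reference
  comparisons, cross-validation fold fits on a shared grid) disable it.
* λ selection: the deviance-ratio rule takes the **first** λ attaining
  the maximal deviance ratio, i.e. ties break toward the larger
  (sparser) λ. Cross-validated selection uses the Verweij–van Houwelingen
  partial-likelihood deviance with event-stratified folds and the same
  largest-λ tie-break.

## 3. Survival statistics

Implemented from the likelihood up and cross-validated against lifelines
and scikit-survival in the tests:

* **Kaplan–Meier**: product-limit estimate; at tied times, events are
  processed before censorings.
* **Log-rank**: k-group statistic with hypergeometric variance.
* **Cox regression**: Newton–Raphson with step halving; Breslow ties by
  default, Efron optional. Collinear designs, cohorts with too few
  events, and monotone likelihood (separation, flagged when a coefficient
  exceeds 15 in absolute value) are detected and reported rather than
  returning unstable estimates.
* The score (Rao) test at β = 0 for a binary covariate equals the
  two-group log-rank chi-square **when event times are untied**; with
  ties the two differ by the (n−d)/(n−1) hypergeometric variance factor.
* Follow-up is administratively truncated at the 5-year horizon: longer
  times are censored at 5 years.

## 4. Expression proxy signature

Expression values are asinh-transformed once; all statistics operate on
that scale. Differential expression between NAG groups uses Welch's
t-test with significance at raw p < 0.05 (Benjamini–Hochberg q-values are
reported alongside as a flag, not a filter) and a fold-change criterion on
the linear scale that is symmetric in direction: mean ratio > 2 or < 1/2.
The signature risk score is Σ coefficient × asinh(expression); patients
at or above the third quartile of the score are **high expression risk**
(ties to high risk). A patient's *combined* outlook is "better" iff their
NAG group is high **or** their expression risk is low.

## 5. Neoantigen immunogenicity

Each missense variant is applied to the protein (1-based position; the
reference residue must match, otherwise the record is rejected as a
wrong-isoform error), and all 8–11-mer windows fully inside the protein
that contain the mutated residue are enumerated; duplicate peptide
strings are deduplicated. An interior mutation (≥ 11 residues from both
ends) yields 8+9+10+11 = 38 windows.

* A peptide is **antigenic** iff predicted IC50 < 500 nM for **both** of
  the patient's HLA-A alleles (strict; exactly 500 nM fails). A
  homozygous genotype therefore needs only its single allele to bind.
* A peptide is **immunogenic** iff it is antigenic **and** the source
  gene's expression exceeds the cohort median **and** the patient's HLA-A
  expression exceeds the cohort median (both strict; exactly at the
  median fails).
* A patient is immunogenic iff they carry ≥ 1 immunogenic peptide.
  High-NAG patients then split into immunogenic / non-immunogenic strata
  for the three-group survival comparison; variant allele fractions of
  immunogenic vs non-immunogenic variants are compared with the
  asymptotic Mann–Whitney U test (no continuity correction).

The affinity predictor is a pluggable backend interface. The shipped
surrogate backend is a deterministic hash of (peptide, allele) mapped
into 600–50,000 nM for ordinary pairs and 20–420 nM for designated binder
pairs, which gives reproducible, planted-truth-aware affinities without a
trained predictor; a lookup-table backend reads (peptide, allele, IC50)
TSVs produced by any external tool.

## 6. Synthetic cohort generator

The generator draws from a PCG64 stream seeded by the config. Defaults
are the study conditions and are fixed independently of any test outcome:

| Parameter | Default | Rationale |
|---|---|---|
| `n_patients` | 300 | early-stage surgical cohort scale |
| `n_genes` | 500 | panel is a small fraction of the universe |
| `n_panel_genes` | 50 | realistic prognostic panel size |
| `alteration_rate_background` | 0.05 | sporadic passenger alterations |
| `alteration_rate_panel` | (0.2, 0.7) | bimodal burden across the latent groups |
| `latent_high_fraction` | 0.75 | aligns the Q1 burden cut with the latent mode boundary |
| `beta_per_alteration` | −0.05 | modest protective log-hazard per altered panel gene |
| `baseline_hazard` | 0.35 /yr | plausible event rate within 5 years |
| `weibull_shape` | 1.0 | exponential baseline by default |
| `censoring_rate` | 0.05 /yr | light random loss to follow-up |
| `followup_horizon` | 5 yr | administrative censoring |
| `n_signature_genes` | 40 | planted DE genes, disjoint from the panel |
| `signature_shift` | 1.0 | asinh-scale group mean difference |
| `noise_sd` | 0.5 | asinh-scale expression noise |
| `n_immunogenic_patients` | 10 | patients with planted strong binders |
| `protein_length_range` | (50, 200) | all mutations can be interior or near-terminal |

Survival times follow a Weibull (default exponential) model with
per-patient hazard `baseline_hazard · exp(beta_per_alteration · burden)`,
independent exponential censoring, and truncation at the horizon. The
config validator rejects **unfittable designs** — any latent group whose
expected event count within the horizon falls below 2.

The generator's scope is deliberately narrow: independent per-gene
alteration draws within a latent two-group rate structure, additive
Gaussian noise on the asinh expression scale, uniform missense positions,
and a proportional-hazards outcome. It plants every signal the pipeline
claims to detect (panel membership, protective burden effect, shifted
signature genes, immunogenic patients with designated binder peptides)
and records the truth in the bundle, but it does not attempt mutational
signatures, subclonality, pathway structure, or non-proportional hazards.

## 7. Determinism and I/O

All computations are deterministic given the config and seed. Bundles are
written as UTF-8 TSV/JSON text files with floats rendered as `%.17g` and
read back with pandas' `float_precision="round_trip"` parser, so a
write/read cycle is bit-exact (the default pandas float parser is fast
but not exactly invertible). Pipeline runs write a `manifest.json`
recording every threshold in force — LRR ±0.5, fold change 2,
p < 0.05, 500 nM, the Q1/Q3 quantile cuts, α = 0.1, the follow-up
horizon and the seed — so any output directory is self-describing, and
re-running a stage with the same inputs reproduces every output file
byte for byte.

## 8. Limitations

* The surrogate affinity backend is a reproducibility device, not a
  binding predictor; real analyses should plug in a trained predictor via
  the table backend.
* Only HLA-A genotypes are modeled; B/C loci and class II are out of
  scope.
* The elastic-net solver targets the problem sizes used here (hundreds of
  patients, a few thousand genes); it makes no claims at GWAS scale.
* The expression signature uses raw p < 0.05 by design; the BH q-values
  are informational.
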