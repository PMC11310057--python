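# Methods

## Design

`mrtriage` estimates, per candidate gene, the causal effect of gene
expression on a binary disease outcome from two independent sets of
summary statistics (a cis-eQTL study and a disease GWAS), and triages
genes through discovery significance, sensitivity diagnostics,
replication in a second GWAS, and colocalization. Everything operates
on marginal per-SNP associations — no genotype-level data.

The package is organised around two statsmodels-style model objects:

- `MRModel(beta_exp, se_exp, beta_out, se_out)` — built directly or
  from an `InstrumentSet`; `fit(method)` returns an `MREstimate`,
  `fit_all()` an `MRResults` collection with `summary()` and
  `plot_forest()`.
- `ColocModel(trait1, trait2)` — per-region evidence; `fit(priors)`
  returns `ColocResults` with the five posterior hypothesis
  probabilities.

`pipeline.run_pipeline` orchestrates the phases and writes tidy TSV
tables plus a JSON manifest containing the full configuration, seeds
and per-stage SNP counts, so a run is reproducible from its manifest.

## Assumptions

Standard instrumental-variable assumptions: instruments associate with
the exposure (enforced by the p < 5e-8 and F ≥ 10 filters), are
independent of confounders, and affect the outcome only through the
exposure. The diagnostics probe the third assumption (Egger intercept,
heterogeneity) without guaranteeing it. All estimators additionally
treat instruments as mutually independent after LD clumping and use
first-order ("no measurement error") weights that ignore the sampling
noise of the exposure betas; both approximations are standard and both
are deliberately stressed by the test suite (see *Calibration* below).

## Instrument construction

Fixed stage order: cis window → significance/MAF → harmonization →
LD clumping → strength → Steiger. Thresholds (all configurable via
`PipelineConfig` / YAML):

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 100,000 | cis window around the gene body (closed interval, bp) |
| `p_max` | 5e-8 | exposure significance cut (strict <) |
| `maf_min` | 0.01 | minor-allele frequency cut (strict >) |
| `clump_r2` | 0.1 | max pairwise r² among kept instruments (strict >) |
| `clump_window_bp` | 10,000,000 | clumping window |
| `f_min` | 10 | per-SNP F-statistic floor |
| `palindrome_eaf_band` | 0.08 | EAF half-width around 0.5 that marks a palindromic SNP strand-ambiguous |
| `family_alpha` | 0.05 | family-wise error rate per phase |
| `coloc_flank_bp` | 1,000,000 | colocalization region around the gene |
| `coloc_p1/p2/p12` | 1e-4 / 1e-4 / 1e-5 | per-SNP causal priors |
| `pp_h4_cut` | 0.80 | shared-variant call threshold |

Harmonization aligns outcome records to the exposure effect allele:
swapped alleles negate the outcome beta and reflect its EAF; strand
complements (A/G vs T/C) are reconciled before any mismatch verdict and
logged; palindromic SNPs (A/T, C/G) are dropped when either trait's EAF
lies within 0.5 ± band (frequency alignment is unreliable there) and
otherwise aligned by frequency agreement. A band of 0.5 reproduces the
stricter convention of dropping every palindrome. The instrument
F-statistic is per-SNP (each variant must individually reach F ≥ 10);
the gene-level R² sums feed the Steiger check, which removes whole
genes whose instruments explain more outcome than exposure variance.
For the binary outcome the Steiger R² applies the same 2p(1−p)β²
formula to log-odds betas — a scale-consistent approximation, not a
liability-scale R².

Clumping is greedy on ascending exposure p-value with deterministic
tie-breaks (position, then SNP id) and is verified against a
re-scanning reference implementation on small instances.

## Estimators

- Wald ratio (single instrument): first-order delta SE
  σ<sub>Y</sub>/|β<sub>X</sub>|; a second-order variant adding the
  exposure-noise term is available behind a flag.
- IVW: weighted regression through the origin; the
  multiplicative-random-effects SE factor √(Q/(k−1)) is floored at 1
  so it never deflates. IVW-FE is algebraically the inverse-variance
  mean of the per-SNP Wald ratios, asserted numerically to 1e-10.
- MR-Egger: each instrument oriented to β<sub>X</sub> ≥ 0 (the fit is
  invariant to per-SNP sign flips); weighted least squares via
  statsmodels; SEs inflated by max(1, √(Q′/(k−2))); slope and
  intercept p-values from t with k−2 df.
- Weighted median: half-weight cumulative interpolation at 0.5;
  SE from a seeded parametric bootstrap (default 5000 replicates) that
  redraws both betas from their sampling normals.
- Maximum likelihood: the per-SNP true exposure effects ξ_j are
  profiled out in closed form, leaving a 1-D profile likelihood in θ
  maximised by bounded Brent search (bracket centred on the IVW
  estimate and doubled until it encloses a minimum; tolerance 1e-10);
  the SE is the inverse square root of the numerical curvature
  (central differences, step 1e-4 of the IVW SE).

p-values are two-sided normal for Wald/IVW/ML and t(k−2) for Egger.
All five estimators agree exactly on noiseless single-ratio data
(property-tested).

## Triage logic

The primary estimate is the Wald ratio when one instrument survives QC,
otherwise IVW-MRE; Egger, weighted median and ML corroborate direction
only. Per phase, the Bonferroni denominator m counts genes with at
least one valid instrument, and the same per-phase threshold feeds the
weighted-median rescue rule: a gene flagged heterogeneous (IVW Q
p < 0.05) survives only if its weighted-median p clears the phase
threshold ("accountable" heterogeneity); otherwise it is excluded. A
gene is also excluded for discordant estimator directions (any zero or
opposite-signed beta) or a significant Egger intercept. Replication
validates a carried hit only when significant at α/(number of hits)
with the same primary-effect sign as discovery. Colocalization
annotates the verdict table (PP.H4, call at 0.80) but never gates it.
Displayed thresholds are rounded to 2 significant figures
(0.05/499 → 1.00e-4, 0.05/31 → 0.0016); gating always uses exact
values.

## Colocalization

Per-SNP Wakefield log-ABFs with effect-size prior SD 0.15 for the
quantitative trait and 0.20 for the binary trait (conventional
defaults; configurable). Hypothesis masses accumulate entirely in log
space; the H3 mass log(Σe^{L1}·Σe^{L2} − Σe^{L1+L2}) switches to a
direct pairwise j ≠ k accumulation whenever the subtraction would
cancel below 1e-10 in log units (which happens exactly when one SNP
dominates both traits). Results are invariant to SNP order, sum to 1
within 1e-9, and match naive linear-space enumeration on small regions
to 1e-8. The single-causal-variant-per-trait assumption is inherited
from the enumeration; multi-signal regions dilute PP.H4.

## Synthetic data

`simdata` emulates region-level two-sample summary statistics:

- AR-1 LD, r_jk = ρ^|j−k| (positive definite for 0 ≤ ρ < 1);
- joint causal eQTL effects mapped to marginals by β_marg = R·β_joint;
- exposure SE 1/√(2p(1−p)·N_exp) (unit-variance expression);
- outcome SE 1/√(2p(1−p)·N_out·φ(1−φ)) — the large-sample logistic
  approximation for a case-control trait with case fraction φ.
  Defaults N_out = 898,130 and φ = 0.0825 match a large T2D
  case-control meta-GWAS; `case_fraction=None` treats the outcome as
  quantitative. Effects are simulated directly on the log-odds scale;
  no liability-scale conversion is attempted;
- outcome true marginals θ·(exposure marginals) plus LD-propagated
  per-SNP direct (pleiotropic) effects drawn N(mean, sd);
- observed betas are multivariate-normal draws whose correlation
  follows R, independent between exposure and outcome (non-overlapping
  samples);
- SNP ids derive from chromosome and position, so independent cohort
  draws over one region share identifiers and harmonize naturally.

Default region: 10 common SNPs (EAF ~ U(0.05, 0.95)) at ρ = 0.5 with
two causal eQTLs of 0.25 SD per allele at N_exp = 31,684 (marginal z
near 30, the scale of strong consortium cis-eQTLs). All randomness
flows from one master seed through named, process-stable substreams
(eaf, noise_exp, noise_out, pleiotropy), so stages re-run in isolation
and identical truth implies byte-identical tables.

What the generator does *not* emulate: realistic human LD maps (AR-1
only), allele-frequency mismatch between cohorts, sample overlap,
multi-allelic or palindromic-strand errors (all simulated alleles are
A/G), winner's-curse selection of the exposure study, and
liability-scale effects. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to every artefact of real consortium data.

## Calibration, problem sizes, and known limitations

The suite measures calibration at these sizes: type-I error over 2000
null regions; estimate bias and 95% CI coverage over 500 regions with
θ = 0.3; Q/df expectation over 1000 homogeneous regions; Egger
intercept recovery over 50 strong instruments; colocalization call
rates over 100 replicates per scenario.

Two approximations visibly limit calibration under the default
simulation conditions, and the suite measures rather than hides them:

1. **Residual LD.** Clumping at r² ≤ 0.1 still admits instrument pairs
   with r up to ~0.3; the independence-weighted IVW z-statistic is then
   over-dispersed, so the null rejection rate exceeds the nominal 5% by
   a percentage point or two when many neighbouring SNPs reach
   genome-wide significance. A correlation-aware (generalised) IVW
   would remove this and is a natural extension.
2. **First-order weights.** At larger θ the neglected
   θ²σ<sub>X</sub>²/σ<sub>Y</sub>² term shrinks CIs below nominal
   coverage; the multiplicative-random-effects inflation absorbs part
   but not all of it.

Other limitations: no MR-PRESSO/mode-based/multivariable estimators, no
SuSiE-style multi-signal colocalization, no genome-build liftover, no
GWAS-VCF input, and the weighted-median bootstrap SE (not the
asymptotic formula) is the only SE offered for that estimator.
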