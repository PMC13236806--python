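# Methods

## Causal model and estimators

The package treats a CpG's methylation M-value as an exposure whose effect
on type 2 diabetes (T2D) liability is to be estimated with genetic
instruments. The structural model behind both the estimators and the
synthetic generator is

```
M_i  = a_j + Σ_k γ_jk G_ik + covariate terms + ε_ij          (cis-meQTL)
L_i  = α + Σ_j θ_j (M_ij − mean_j) + Σ_k δ_k G_ik + covars   (liability)
T2D_i ~ Bernoulli(expit(L_i))
```

θ_j is the causal log-odds per M-value unit (OR = e^θ), γ_jk the cis-meQTL
effects, and δ_k optional direct (pleiotropic) SNP effects that violate the
exclusion restriction when nonzero.

Estimation follows the Rucker decision tree. Single instrument: Wald ratio
Γ/γ with the first-order delta SE se(Γ)/|γ| (a second-order form adding
Γ²se(γ)²/γ⁴ is available; the first-order form is the default convention).
Multiple instruments: fixed-effects IVW, which is exactly zero-intercept
WLS of Γ on γ with weights 1/se(Γ)²; Cochran's Q with J−1 df flags
heterogeneity; when Q's p < 0.05 the multiplicative random-effects IVW
keeps the point estimate and inflates the SE by max(1, √(Q/(J−1))) — the SE
never drops below the fixed-effects SE, which is the sensible behaviour at
J as small as 2–3 (an additive random-effects variance would be
unestimable there). With J ≥ 3 the Egger regression (free intercept, same
weights) is fitted and the transition Q_IVW − Q_Egger is referred to χ²₁ at
α = 0.05: significant → report Egger, else random-effects IVW. Every fitted
statistic (both Q's, the Egger intercept and slope, all SEs) is retained on
the result regardless of the selected method. Because the Egger slope is
only identified with a consistent instrument orientation, harmonisation
flips every pair so γ ≥ 0 (jointly negating γ and Γ, which leaves Wald and
IVW invariant). Confidence intervals are exp(θ̂ ± 1.959964·se); no
small-sample t correction. MR p-values are interpreted at the nominal 0.05
level — instrument counts per CpG are tiny and the framework treats MR as
confirmatory of EWAS hits — but a BH-FDR column is included in the results
table for transparency.

Egger SEs come from the known-variance WLS covariance (X'WX)⁻¹ without a
residual-dispersion rescale; under the generating model the weights are the
true inverse variances and the intercept test is then correctly calibrated
(verified by simulation in the test suite).

## Instrument construction

* **Genotype QC** mirrors standard imputed-array filters: per-marker
  missingness > 5%, MAF < 1%, exact Hardy–Weinberg test p ≤ 1e-6 (the exact
  conditional test rather than the χ² approximation, which misbehaves at
  small genotype counts), imputation INFO < 0.8. The exact HWE test is
  implemented with the outward two-sided recurrence from the modal
  heterozygote count.
* **cis window**: "a 2 Mb region around the CpG" is interpreted as ±1 Mb,
  consistent with the eQTM cis definition (within 1 Mb); one shared interval
  utility backs the meQTL window, the clumping radius and the cis/trans
  eQTM classification. Variants whose coordinate coincides with the probe's
  interrogated cytosine are excluded before testing (array probes overlapping
  a variant measure genotype, not methylation).
* **meQTL model**: fixed-effects OLS of M-values on dosage with the stage
  covariates (blood: age, sex, medication use, cell proportions;
  hepatocytes: age, sex, ancestry fraction). Relatedness/mixed-model
  machinery is out of scope; with the generator's unrelated samples OLS is
  the correct model, and on real data this choice would understate SEs in
  the presence of cryptic relatedness — a documented divergence.
* **Clumping** is greedy: sort by ascending p (ties broken by position then
  id, making results deterministic), take the best unassigned variant as an
  index, absorb everything with r² ≥ 0.1 to it, repeat. Indices are the
  independent instruments; independence is strict r² < 0.1.
* **Instrument strength**: per-instrument r² is the squared partial
  correlation implied by the marginal fit, t²/(t²+n−2); the cumulative R²
  sums these over the (approximately independent) clumped indices — an
  approximation documented as such; a joint multi-SNP refit is available via
  `f_mode="joint"`. F = ((n−k−1)/k)·R²/(1−R²) with admission at F > 10.
* **Confounder screen**: each index variant is tested against age, sex,
  BMI, waist, hip and smoking (simple per-confounder models; logistic
  confounder-on-dosage for the binary ones — for simple linear fits the two
  regression directions give identical p-values, so the direction choice
  only matters for the logistic cases). Any p < 0.05 excludes the
  instrument; a relaxed mode screens age and sex only. With six independent
  nominal tests a truly clean instrument survives with probability
  ≈ 0.95⁶ ≈ 0.74 — the strict screen deliberately trades instruments for
  robustness.

## Association machinery

EWAS and GWAS scans are complete-case per unit. The epigenome-wide scans
use the Frisch–Waugh–Lovell decomposition (residualise the response and all
probe columns on the covariate design once, then per-probe slopes/SEs are
exact OLS), which makes a 10,000-probe scan essentially one matrix
operation. The binary-T2D EWAS regresses the 0/1 case label linearly on
methylation by default (the common linear-on-binary EWAS convention);
logistic is available. Glycaemic traits (HbA1c, HOMA-S, HOMA-B) are
ln-transformed. The six cell-proportion covariates are compositional, so
the neutrophil column is dropped from the design to avoid rank deficiency.
β-values are clipped to [1e-6, 1−1e-6] before the M = log2(β/(1−β))
transform. Genomic inflation is λ = median(χ²_obs)/0.4549. Meta-analysis is
inverse-variance fixed-effects (the scale MR needs; sample-size weighting
would discard the SEs), with per-unit Cochran's Q across cohorts and a
+/−/? direction string. FDR is BH, computed separately per trait and per
analysis stage (EWAS trait, meQTL scan, eQTM per tissue).

The outcome GWAS defaults to logistic regression of T2D on dosage (age,
sex, three genotype PCs, BMI), so Γ is a log-odds and OR = e^θ is
well-defined. A linear-on-binary option exists with the approximate
conversion logOR ≈ β/(μ(1−μ)); it is labelled approximate and not used by
default. Sample overlap between the exposure and outcome sides is a hard
error (two-sample MR requires disjoint samples).

## Synthetic study generator

The generator's defaults are the study conditions everything else is tested
under:

* **Cohorts**: a population-based cohort (n=879; three recruitment sites;
  T2D prevalence 4.7%; no medicated participants; two methylation time
  points) and a clinic-based cohort contributing an EWAS subset (n=332,
  prevalence 1.8%, single site), a T2D-enriched meQTL subset (n=606,
  prevalence 46.2%, 98% of cases medicated, with a 23% longitudinal
  follow-up subset ≈ 138 samples), a disjoint outcome-GWAS sample (n=4,000,
  prevalence 48.7%) and tissue-expression subsets (blood 77, adipose 49,
  muscle 55). A hepatocyte panel (n=56, West African ancestry fraction
  ~0.83) supplies the second meQTL tissue.
* **Genotypes**: latent-Gaussian LD blocks. Two haplotype draws per person
  share a block-level factor with weight √r and are thresholded at the
  allele frequency, so marginal dosages are exactly Binomial(2, p)
  (Hardy–Weinberg) while within-block dosage correlation rises with r and
  across-block correlation is zero. This gives tunable r² without modelling
  haplotype history; it does not reproduce realistic LD decay with
  distance, which none of the tested procedures depend on.
* **Methylation**: M = intercept + Σγ·dosage + small age/sex/cell/plate
  effects + N(0, 0.8²). The two causal CpGs sit at ~92% and ~74%
  methylation. The blood CpG has three meQTLs (γ = 0.45, 0.35, 0.40) in
  three separate LD blocks inside its cis window — after clumping, exactly
  three independent instruments with per-SNP R² ≈ 0.1 (F ≈ 60 at n=606).
  The hepatocyte CpG has one strong meQTL (γ = 1.0, R² ≈ 0.4), the kind of
  effect detectable at an n=56 panel. The second time point adds per-CpG
  drift on the beta scale (−0.0042 and −0.0095 for the causal CpGs, 0
  elsewhere) plus N(0, 0.01²) noise; drift is specified on the beta scale
  because stability is reported in percent methylation.
* **Phenotypes**: liability as above with θ = log(0.76) and log(1.29);
  the intercept is solved numerically so mean expit(L) hits the target
  prevalence. Fasting glucose is drawn conditional on the Bernoulli case
  label from truncated normals on either side of the 7.0 mmol/l diagnostic
  threshold (affine-in-liability means within each stratum), so the
  glucose-based case definition reproduces the label exactly rather than
  only in expectation. HbA1c tracks glucose (≈5.5 mmol/mol per mmol/l)
  plus direct CpG trait couplings; insulin is log-normal and rises with
  liability. HOMA-S and HOMA-B use the classic formulas
  (HOMA-IR = glucose·insulin[mU/l]/22.5, HOMA-S = 100/IR,
  HOMA-B = 20·insulin/(glucose−3.5)); the published HOMA calculator is a
  non-closed-form computer model, so absolute HOMA levels here are
  order-of-magnitude realistic rather than calibrated. Glucose ≤ 3.5 is
  re-drawn (bounded retries) to keep the HOMA-B denominator positive.
  Follow-up HbA1c adds λ_follow·Σθ_j(M_ij − mean) (λ_follow = 2 mmol/mol
  per liability unit) — a configurable stand-in, as no quantitative model
  links baseline methylation to follow-up HbA1c.
* **Cell proportions**: Dirichlet with mean targets
  (13.7, 21.3, 5.0, 8.3, 8.1, 43.2)% and total concentration 17, matching
  the between-person spread of deconvolution estimates (neutrophil SD
  ≈ 0.12).
* **Expression**: expr = a + b·M + small age term + noise for configured
  CpG→gene couplings; genes are placed at configured TSS offsets (two cis
  muscle genes at +0.3/+0.45 Mb with b = −0.366 and −1.258, one trans blood
  gene at +1.94 Mb with b = −0.045). Per-gene noise SDs (0.4, 4.0, 0.05)
  were chosen once so the three couplings land in their intended evidence
  tiers (strict FDR, exploratory FDR < 0.2, strict) at the subset sizes.
  Background genes are pure noise at random positions.

What the generator does **not** emulate — probe-level technical artefacts,
cross-reactive probes, realistic LD decay, relatedness, population
stratification beyond discrete sites, and cell-type interaction effects —
bounds what green tests demonstrate: the statistical machinery is correct
and calibrated under the assumed causal structure, not that the pipeline is
robust to every failure mode of real array data.

## Numerical and design choices

* Coordinates are 1-based inclusive (VCF convention); "within X Mb" is a
  closed interval on base-pair distance.
* Missing values are "NA" in all text formats; floats are written at full
  repr precision and parsed with round-trip precision so files reproduce
  byte-identically and extreme p-values (1e-300) survive.
* One global seed per run, forked per stage through named seed sequences:
  re-running any stage alone reproduces its outputs.
* Tertiles split at the empirical 1/3 and 2/3 rank cuts; boundary ties all
  go to the lower tertile (deterministic); an all-equal input degenerates
  to a single group with a warning. Kruskal–Wallis uses mid-ranks with the
  standard tie correction. The longitudinal analysis includes untreated
  T2D cases by default (a flag excludes them).
* cis/trans for eQTMs is measured at the annotated TSS (strand-aware);
  the gene-body-overlap alternative is a documented option.
* Zero-variance predictors are skipped with a flag, not an error;
  rank-deficient designs are an error naming the collinear columns.

## Problem sizes

The shipped configuration runs ~60 background probes, ~70 variants in 10 LD
blocks and the cohort sizes above; a full nine-stage run takes a few
seconds, and the simulation studies in the acceptance script (100-replicate
OR medians, 300-replicate type-I error and coverage, a 10,000-probe null
EWAS) complete in well under a minute. These sizes were chosen so the
complete validation loop is cheap enough to run on every change; every
statistical check is formulated scale-free (calibration rates, coverage,
oracle equivalence), so the conclusions do not hinge on the scale.

## Known limitations

* Cumulative F from summed marginal R² ignores residual LD (< 0.1) between
  clump indices and mildly overstates joint strength; the joint-fit mode
  avoids this.
* The Wald/IVW delta SEs ignore uncertainty in γ (standard two-sample
  practice); with weak instruments this understates the SE — mitigated by
  the F > 10 bar.
* Logistic marginalisation means the per-SNP Γ of a liability-mediated
  effect is very slightly attenuated relative to θγ (non-collapsibility);
  at the default effect sizes the bias is below 2% of θ and invisible next
  to sampling error, as the coverage simulations confirm.
* The screen's multiplicity cost (keep rate ≈ 0.74 per clean instrument)
  is inherent to the nominal-p exclusion rule, not a defect; the relaxed
  mode exists for sensitivity analyses.
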