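# Methods

`broodmeth` re-implements, as a tested pipeline, the post-fledging stage
of a cross-foster / brood-size-manipulation experiment in wild great
tits (*Parus major*): the question is whether the nutritional stress of
being raised in an enlarged brood leaves carry-over effects that unfold
*after* independence — on weight, wing development (third-primary
length), exploration behaviour, and erythrocyte DNA methylation — and
whether those methylation effects depend on the time elapsed since
fledging.

## Study design and the statistical model

Broods hatching on the same day are paired; within each cross-foster
(CF) pair about half the nestlings are swapped, and one brood is
enlarged by three nestlings while the other is reduced by three.  Every
bird therefore has a brood of origin (genetics/prenatal) and a brood of
rearing (treatment environment), both nested within the CF pair.
Fledglings are recaptured from four weeks after fledging onward;
recapture probability differs by treatment (30.51% reduced vs 16.43%
enlarged in the study population).

**Methylation.** For each CpG site the methylated read count m out of
coverage n for bird i is modelled binomially with a logit link:

    m_i ~ Binomial(n_i, p_i)
    logit(p_i) = beta_0 + beta_T T_i + beta_D D_i + beta_TD T_i D_i
                 + u_origin(i) + u_rearing(i)

where T is treatment, D days since fledging, and the u's are independent
random intercepts for brood of origin and brood of rearing (one variance
each; nesting in CF pair is encoded by composite `pair:brood` labels).
A site is a *days-dependent differentially methylated site* (DMS) when
the 2-df likelihood-ratio test of the full model against a null model
with treatment only (the added terms being days and the interaction) is
significant after Benjamini–Hochberg correction at q <= 0.05.

**Phenotypes.** Post-fledging weight, Δ weight (post-fledging minus
day-14 weight), P3 length and exploration score are analysed with
Gaussian mixed models (same random structure, maximum-likelihood
estimation), reduced by backward elimination at p < 0.05 (interactions
and squared terms first, treatment never removed), with type-III F
tests, Satterthwaite denominator degrees of freedom, and per-treatment
slopes of days since fledging with Bonferroni correction (m = 2).  The
exploration score is the movement count in a 2-minute novel-environment
test residualised on test date and recentred to the cohort mean.

## Estimation

### Binomial GLMM by Laplace approximation

The marginal likelihood integrates the random intercepts out of the
binomial likelihood.  We maximise its Laplace approximation

    l(beta, sigma) = log f(y | beta, u_hat) - u_hat' D^-1 u_hat / 2
                     - log det D / 2 - log det H / 2,

where u_hat is the joint mode found by a penalised Newton iteration
(warm-started across evaluations), D the prior covariance and
H = Z'WZ + D^-1 the conditional curvature.  The outer optimisation runs
over the fixed effects and log random-effect SDs jointly (L-BFGS-B) with
an **exact analytic gradient**: the direct mode dependence vanishes by
the envelope theorem, and the gradient of the log-determinant term
accounts for the mode's movement via implicit differentiation.  Fixed
effect columns are centred/scaled internally for conditioning; estimates
are reported on the original scale.

Two numerical points matter in this design:

* **Multi-modality.**  Because roughly half the chicks are not moved,
  brood of origin and brood of rearing are nearly collinear groupings,
  and the Laplace surface can hold the shared variance on either factor.
  After the primary fit the swapped configurations (each SD pushed to
  its boundary with the other released) are probed and the best solution
  kept.  Without this, roughly 3% of per-site fits stop in a local
  optimum.
* **Boundaries.** Log-SDs are bounded in [-10, 4]; an SD below 1e-4
  flags the fit singular.  Singular fits are retained; fits that fail to
  converge are omitted from the screen.

The likelihood includes the binomial combinatorial constant, so values
are directly comparable with ordinary logistic regression and with
quadrature.  A 25-node adaptive Gauss–Hermite evaluation (independent
implementation) agrees with the Laplace optimum to < 1e-3 on
high-coverage toys; with the variances pinned at zero the fit reproduces
plain logistic regression coefficients to < 1e-6.

### Gaussian LMM

Maximum likelihood with the fixed effects and residual variance profiled
out; the optimiser runs over log variance ratios, with an explicit
boundary candidate (ratios snapped to zero) because the log-ratio
gradient vanishes exponentially at the boundary.  Small-sample inference
— Satterthwaite df, type-III F tests and slope standard errors — uses
the REML profile of the same model (variance estimates, their
asymptotic covariance from the numerical Hessian of the restricted
likelihood, and GLS fixed effects at those variances).  With ML
curvature the Satterthwaite df on a balanced split-plot would be ≈ g
rather than the exact g − 2; REML curvature restores the classical
values and matches the behaviour of the standard mixed-model t/F
machinery.  Contrast-variance gradients use central differences with
relative step 1e-4.

Satterthwaite df for a contrast c is 2 v² / (g' A g) with v = c'C(φ)c,
g = ∂v/∂φ and A the covariance of the variance parameters φ.  Multi-df
terms combine per-eigencontrast dfs.

### Per-treatment slopes

Slopes of days since fledging are linear contrasts built by
differencing two design rows one unit apart (the estimated-marginal-
trends construction), with delta-method standard errors.  Gaussian fits
use a t reference with Satterthwaite df; binomial fits use the normal
reference, as no finite-sample df theory exists for Laplace GLMMs.

## The screening pipeline

Order: per-site null/full fits → omission of errored sites (singular
fits kept) → overdispersion screen → BH–FDR → post-hoc slopes →
category assignment.  The overdispersion screen computes each site's
Pearson dispersion (chi-square over n − p with p counting fixed effects
only; fitted probabilities include the predicted random effects) and
removes sites outside the 95% highest-density interval — the shortest
window of the sorted dispersions holding 95% of them (ties to the
lowest start).  Under this convention the dispersion of a well-specified
site sits *below* 1 at study scale (≈ 0.78 with 50 birds in ~55 broods)
because the predicted brood effects absorb part of the observation
noise; the screen uses the empirical distribution, so only relative
position matters.  BH is applied to the sites surviving the screen by
default (`fdr_universe="tested"`); `"all_filtered"` computes the
correction over all fitted sites instead.  Post-hoc slope p-values are
BH-corrected jointly across the 2 × n_significant tests (switchable to
per-site).

Significant sites are assigned one of six interaction categories from
the two post-FDR slopes: opposing (both significant, opposite signs;
named after the enlarged-group direction), enlarged-only up/down,
reduced-only up/down.  "Stable" is operationalised as non-significant
after FDR; both-significant-same-sign and both-flat sites are labelled
`unclassified`.

## Null calibration: what holds and what does not

Under the global null the LRT behaves as follows (all measured, see
`scripts/acceptance.py`):

* with no random-effect variance the p-values are uniform
  (KS p ≈ 0.97 on 1000 sites) — the engine itself is calibrated;
* at the study conditions (50 birds, ~30× coverage, brood random
  intercepts of SD 0.3 logit) the statistic is inflated by ~7% in the
  mid-range (mean null p ≈ 0.466), so a KS test on 2000 sites rejects
  uniformity.  This is intrinsic to comparing nested GLMMs with a
  chi-square reference when variance components are estimated from only
  ~30 brood clusters: it persists unchanged at 300× coverage (where the
  Laplace error is negligible), and our per-site statistics agree with
  lme4's to ~5 decimals once both are fully converged.  The *tail* is
  calibrated (fraction of null p < 0.01 is 0.0085; none of ~2000 null
  p-values fall below 1e-3), so BH at q <= 0.05 controls the false
  discovery proportion — the property the screen actually relies on.

A note on interpreting the all-null FDP experiment (20 seeds of null
sites): on fully null data the FDP of a seed is 0 or 1, and for BH under
independence the probability of any rejection equals the FDR level
exactly, so one rejecting seed in 20 is the *expected* outcome under
exact control and batches with two rejecting seeds occur about a quarter
of the time.  The seed-level pass fraction reported by the acceptance
script should be read against that binomial baseline, not as a
point requirement.

## Filtering rules

Applied in fixed order with strict inequalities and a telescoping
report: (1) cells with coverage < 10× or above the sample's own 99.9th
coverage percentile (linear interpolation) become missing — missing,
never zero, so observed zero methylation stays distinguishable; sites
left with no data drop out; (2) sites covered in fewer than 15
individuals in either treatment drop out; (3) sites with mean
methylated fraction across individuals < 0.05 or > 0.95 drop out.  The
percentile is per sample, the common reduced-representation practice.
Coordinates are 1-based inclusive, anchored at the plus-strand C of the
merged CpG; BED output is 0-based half-open over the dinucleotide.

## Annotation

Strand-aware windows per gene: TSS region (300 bp up / 50 bp down of the
transcription start), promoter (2000 up / 200 down), gene body, UTRs,
and 10-kb flanks.  The TSS is the 5' end of the gene span (genes, not
transcripts, are annotated).  Class priority is TSS > promoter >
gene body > 5'UTR > 3'UTR > flank; because UTRs lie inside gene bodies
the literal order makes UTR labels unreachable, so the default keeps the
literal order (consistent with region counts that report no UTRs) and
`utr_above_gene_body=True` ranks them above.  Within the winning class,
characterised genes beat LOC (uncharacterised) genes, then the shortest
edge-to-site distance to the gene body decides; upstream vs downstream
follows the winning gene's strand.

## The synthetic-data generator

The generator emulates the study conditions and is the ground truth for
every benchmark: 16 CF pairs (32 broods) matched on hatch date, base
brood size 9 manipulated by ±3, ~half of each brood cross-fostered,
fledging 19 days after hatching, recapture Bernoulli per treatment
(0.3051 / 0.1643), days since fledging uniform on [28, 110] (the field
season constrains only this range; uniform keeps the interaction
identifiable), test date = fledge date + days.  Methylation coverage is
negative-binomial (mean 30, dispersion 5 — RRBS coverage is
overdispersed, which exercises the high-coverage percentile cut);
baseline methylation comes from a two-component logit-normal mixture
(hypo/hyper modes) so the mean-methylation filter has realistic bite;
planted sites add treatment-specific slopes (logit/day) of six shapes;
brood random intercepts default to SD 0.3 logit on each factor, and an
optional per-observation Gaussian logit noise (default 0.2) creates
overdispersed sites.  Slopes are anchored at the mean recapture day
(`center_days=True`), a pure intercept reparametrisation that keeps the
drawn baseline the mid-trajectory methylation.  One global seed spawns
independent sub-streams for design, phenotypes and methylation.

Phenotype defaults plant the observed study patterns: enlarged-brood
birds lighter at day 14; post-fledging weight rising ~0.03 g/day in both
groups; P3 length (+0.04 mm/day) and exploration (+0.21 score/day)
rising with days only in the enlarged group; a hatch-date² catch-up term
in the enlarged group.  Raw movement counts carry a linear test-date
trend that the exploration date-correction must remove.

What the generator does *not* emulate: read-level artefacts (bisulfite
conversion error, PCR clones, mapping bias), linked methylation of
neighbouring CpGs, condition-dependent survival (recapture is the only
selective process), sex effects, and real genomic site spacing.  Passing
benchmarks therefore demonstrate correctness of the statistical
machinery under the assumed generative model, not robustness to
upstream bioinformatic artefacts.

## Benchmark scenarios and problem sizes

Fixed in `broodmeth.benchmarks` so every reported number is reproducible
from the package alone:

* engine check: 20 toys of 10 observations in 3 balanced groups at
  ~600× coverage (deep coverage makes the intrinsic Laplace–quadrature
  gap far smaller than the 1e-3 comparison level, so implementation
  errors are visible; at 30× the intrinsic gap alone is ~1e-2);
* null calibration: 2,000 null sites on a 50-bird cohort at 30×; FDP
  control: 20 seeds × 100 null sites (on all-null data the FDP is 1
  whenever anything is rejected, so the seed-level pass rate is
  insensitive to the number of sites);
* recovery: 600 planted sites (100 per category, slopes ±0.025
  logit/day) among 1,400 nulls, same cohort, with mid-range baselines
  (modes ±1.2 logit) emulating sites that survive the mean-methylation
  filter;
* phenotype recovery: 100 design seeds, exploration model, planted
  enlarged slope 0.21/day.

## Known limitations

* The binomial GLMM family is binomial only; extra-binomial variation is
  screened out (HDI) rather than modelled (no beta-binomial).
* The mid-range null miscalibration above means per-site p-values near
  0.1–0.5 are slightly optimistic at study scale; discovery decisions at
  q <= 0.05 are unaffected.
* Backward elimination inherits the usual caveats of stepwise selection;
  it is implemented because it is the procedure under study.
* Type-III tests with uncentred polynomial terms (hatch date²) are
  sensitive to the origin of the covariate; `center_hatch=True` is
  available.
* No regional aggregation or smoothing across neighbouring CpGs; sites
  are screened independently.
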