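# Methods

`rejumet` implements a cross-species "metabolic rejuvenation" analysis for
targeted metabolomics (and, with the same machinery, proteomics): it asks
whether a treatment shifts an organism's feature profile *against* the
direction of aging, and how that shift depends on dose. Every stage is
exercised end to end on synthetic studies whose statistical structure matches
the designs the pipeline is built for, so all claims below are testable
without any external data.

## Data model and preprocessing

Concentrations (µM) arrive as a samples × features table with a class
annotation (AA amino acids, AC acylcarnitines, BA biogenic amines, LysoPC
lysophosphatidylcholines, PC phosphatidylcholines, SM sphingomyelins, H
hexoses). Values below the limit of detection are *missing*, never zero, and
every downstream stage tolerates missingness by pairwise/row deletion.

All modelling is on the log2 scale. Sample QC computes per-feature z-scores
across samples (sample SD, n−1), averages them within each sample, and flags
|mean z| > 3; flagged samples are excluded from model fits but retained in
the QC report. Metabolite-class values are sums of member concentrations on
the **natural** scale (summing log-values would be dimensionally
meaningless); class-level models then take log2 of the sums — exposed as a
switch, since the outcome scale for class models is a genuine design choice.

## Differential abundance with empirical-Bayes moderation

Each feature is fitted by OLS against a shared design (intercept, treatment-
coded group indicators, numeric covariates such as body weight or BMI, and —
for longitudinal human data — fixed subject-indicator columns implementing
the ID blocking; a duplicate-correlation random-subject alternative is
deliberately out of scope). Residual variances s²_g with df d_g are shrunk
toward a prior estimated from the whole ensemble by moment-matching
log s²_g to a scaled-F distribution (digamma/trigamma moments; the trigamma
equation is inverted by Newton iteration). The moderated variance

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

gives a moderated t on d0 + d_g df for any contrast. Degenerate ensembles
with no excess variance spread yield d0 = ∞ and s̃² ≡ s0² (logged, not an
error). Two-sided p-values; Benjamini–Hochberg FDR across features;
Fisher's method (−2Σ ln p vs χ²₄) pools evidence across paired comparisons.
The implementation is verified in the test suite against an independently
coded direct-formula oracle (1e-10 relative) and against the reference R
implementation run as a subprocess.

## Signature-reversal scoring

The **aging signature** is a per-feature vector of age effects: log2FC
old-vs-young in mice, or external per-year β-age coefficients in humans
(consumed as an input table; Spearman correlation is scale-free, so no
rescaling of per-year units is applied). A treatment's **reversal score** is
Spearman's ρ between its per-feature effects and the signature over the
name-intersected features; ρ < 0 means the treatment opposes aging. The
two-sided p uses the t-approximation on n−2 df, with an exact-permutation
option for panels of n < 10. Families of scores (several arms against one
signature) are BH-adjusted together.

Per-subject scoring in the longitudinal design subtracts each subject's own
baseline from each follow-up visit (log2 difference per feature) and
correlates that change vector against β-age. A follow-up identical to its
baseline has zero rank variance and is recorded as a missing score with a
reason. Group-level human analysis is offered both as a pooled subject-
blocked contrast and as a mean of per-subject scores, since either reading
of the design is defensible.

**Caveat:** when the aging and treatment effects are estimated from designs
sharing a control arm (old controls, in the mouse design), their estimation
noise is positively correlated, which biases the score toward +ρ and makes
its nominal p anti-conservative under the null. This is inherent to
connectivity-map-style scoring with shared comparator groups. The package's
null-calibration tests therefore score estimated treatment effects against
an *external* (true) signature, where the p-value is exactly calibrated;
scores between two estimated effect vectors should be read as descriptive.

## Dose–response mixed models

Outcomes (per-subject score, log2 class sums, osmolality) are modelled as
`outcome ~ 1 + Dose + Dose² [+ BMI] + (1|subject)` with raw dose in mg
(orthogonal recoding available). Fitting is maximum likelihood via the
profiled likelihood: for a fixed variance ratio λ = σ²_subject/σ²_residual
the GLS fixed effects and σ² have closed forms, so a bounded 1-D search over
log λ suffices; λ = 0 is an admissible boundary at which the fit reduces
exactly to OLS (and is taken directly when every subject contributes one
observation, where the profile is flat). Wald tests use the normal
reference — no Satterthwaite/Kenward–Roger correction, by design. ML (not
REML) is used throughout because polynomial orders are compared across
fixed-effect structures.

Polynomial order selection fits orders 1–3 on identical observations and
reports deviance, AIC and BIC per order. Because ML deviance is
non-increasing in nested order, raw deviance cannot select a parsimonious
order; selection therefore uses an information criterion — BIC by default,
as the consistent criterion for order selection — with AIC and raw deviance
available. Orders exceeding (distinct doses − 1) are excluded with a
warning.

The mouse class-level model `class ~ 1 + Age + BW + Genotype*Treatment +
(1|ID)` uses the same machinery; with one serum sample per mouse the random
intercept is degenerate and the boundary handling makes the fit OLS.
Single-level factors drop their columns (and interactions) with a warning.

## Integration, survival, clinical and enrichment stages

The condition network computes all-pairs Spearman correlations of effect
vectors, BH-adjusts across pairs, marks edges with q < 0.05 significant, and
lays nodes out by classical MDS of the signed distance 1 − ρ (anticorrelated
conditions sit far apart; the signed choice preserves the aging-vs-treatment
opposition the figure is meant to show). Conditions with constant effect
vectors get undefined edges rather than silent drops.

The effect PCA divides each condition's vector by its own SD *without
centering* (equalising per-year β and log2FC scales while preserving the
origin) and decomposes by SVD; variance fractions are normalised squared
singular values, and component signs are fixed deterministically.

Survival uses the product-limit estimator with ties handled by simultaneous
events and censoring processed after events at equal times; the k-group
log-rank statistic uses hypergeometric variances on k−1 df (asymptotic p,
matching the conventional implementations; no exact small-sample option).
Calculated serum osmolality is the standard clinical 2·Na + glucose/18 +
BUN/2.8 (mg/dL inputs) — the formula is a convention choice, stated here
prominently because the quantity's definition varies across clinics.

Preranked enrichment uses the weighted KS running sum (weight exponent 1 by
default, ranking by moderated t by default — the statistic is switchable
since either t or log2FC is defensible), with gene-label permutation nulls
(the appropriate null for a preranked vector), two-sided p with floor
1/(1+n_perm), NES = ES / mean|ES_null|, and BH across sets. Ranking ties
break lexicographically for determinism.

## Synthetic-study generators

The generators are first-class, tested code and define the package's study
conditions.

**Mouse (cross-sectional):** arms young WT (n=7), old WT ± losartan
(10/14), old AT1KO ± losartan (8/5), old AT2KO ± losartan (7/6); 120
quantifiable features in the default class mix (PC-dominated, approximating
the 180-analyte panel). Log2 values are class baseline + per-feature offset
+ a shared per-sample class factor (SD 0.15, giving class-structured
covariance) + design effects + N(0, 0.3) noise, exponentiated to
concentrations; the lowest 2% of each feature's values are censored to
missing. Aging subtracts on average 0.6 log2 units (SD 0.3) from 60% of
features; losartan reverses half of the affected features at half strength,
multiplied by a receptor-dependence factor (WT ×1.0, AT1KO ×0.5, AT2KO ×0 —
a qualitative pattern, not a measured claim). Effect magnitudes were chosen
by variance algebra so the emulated design yields treatment-vs-aging scores
on the scale such designs report (ρ in the −0.3 to −0.5 band at these arm
sizes; the realised mean over 100 seeds is ≈ −0.49, somewhat stronger than
the hand calculation anticipated, and deliberately left as chosen).

**Human (longitudinal dose escalation):** 9 placebo + 7 treated subjects by
default, visits at 0/25/50/100 mg every 8 weeks, 160 features. Per-year
β-age effects are N(0.02, 0.015) — broadly positive, opposite in direction
to the mouse. Each visit at dose d injects −r(d)·β per feature with
r(d) = 0.4·d − 0.004·d² (a U-shape peaking at 50 mg with ≈10 year-
equivalents of reversal); subject random intercepts (SD 0.3) induce
within-subject correlation; noise SD 0.35. This gives expected per-subject
scores of ≈ −0.22 at 25 mg and ≈ −0.28 at 50 mg. The external-coefficient
generator returns the true β plus N(0, error_sd) estimation noise.

**Survival:** exponential event times with administrative censoring at
follow-up; the demo uses 19 treated vs 14 controls over 60 days with
hazards 0.006 vs 0.02/day. **Clinical panel:** physiologic baselines
(Na 140±2 mmol/L, glucose 95±10 mg/dL, BUN 16±4 mg/dL) with a sodium dose
response following a quadratic shape peaking at 50 mg.

What the generators do **not** emulate: cross-species coupling of the aging
signatures (the species' truths are drawn independently, so the
cross-species network edge is near zero rather than negative), batch and
plate effects, heavy-tailed or feature-specific noise, informative
missingness beyond the low-end censoring, drift over visits, and dropout.
Passing tests therefore demonstrate correctness and calibration of the
machinery under a clean, class-correlated log-normal world — not robustness
to every artefact of real acquisition.

## Numerical choices and problem sizes

Profiled-likelihood search runs over log λ ∈ [−15, 15] with 1e-12
tolerance; trigamma inversion iterates Newton to 1e-12 relative; CSV output
uses 15 significant digits so repeated runs are byte-identical; all
randomness flows through explicit integer seeds of numpy Generators.
Simulation-based tests use deliberately modest sizes — 100 seeds for
detection rates, 1000 for null calibration, 100 replicates of 100-subject
trials for order-selection recovery, 200 cohorts for log-rank calibration —
chosen to keep the full suite in the low minutes while leaving comfortable
margins on the assertions.

## Known limitations

- Fixed-effect subject blocking (not duplicate-correlation) for the human
  differential model; random slopes and GLMMs are out of scope.
- Wald (normal) inference for mixed-model fixed effects; small-n df
  corrections are not implemented.
- Harmonisation across panels is by exact trimmed name only.
- The shared-control bias of estimated-vs-estimated reversal scores (above)
  is reported, not corrected; an external signature avoids it.
- No imputation or batch correction.
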