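# Methods

This note documents the models and procedures exposomekit implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter.

## Scope and data model

The package analyzes a longitudinal biobank design: women sampled once or
twice (second visit up to 16 years after the first), with reproductive
covariates (number of pregnancies including early terminations, number of
deliveries, age at menarche, BMI, tobacco ever-use, hormone-use history)
and plasma measured by parallel targeted and untargeted LC-HRMS.  Four
in-memory containers carry the state: a `Cohort` (participants + visit
records), a `ConcentrationMatrix` (targeted analytes × samples with
per-cell censoring status), `RawFeatureTable`s (per-ESI-mode peak areas
over samples, procedural blanks and pooled QC, with m/z, RT and MS2 per
feature), and tidy association-result frames.

## Synthetic-data generator

Real individual-level data of this kind are access-restricted, so the
generator is a first-class, tested module whose defaults *are* the study
conditions: 100 women in parity strata of 26/23/27/24 (none, 1–2, 3–4,
>4 pregnancies), second samples from 0/22/21/18 women per stratum (61
repeat donors, 82% of the 74 parous women, 161 samples total), sampling
years 1987–2006, five injection batches with two procedural blanks and a
pooled QC each.  Stratum-level age, BMI, tobacco and hormone-use
parameters default to the published cohort summary statistics and are
overridable.  Parous women get a first visit within two years of their
last pregnancy, mirroring the selection criterion of the emulated design.

Concentrations follow a log-normal law with linear covariate effects on
the log scale — log c = β₀ + Σβₖxₖ + u_subject + ε — which reproduces the
left skew that motivates the downstream square-root transform; exact
√-normality is deliberately not forced.  Detection is deterministic so
tests stay exact: concentrations below MLOQ/3 are non-detects, values in
[MLOQ/3, MLOQ) are detected-but-below-MLOQ.  The untargeted tables carry
planted structure with generation-time validation against the pipeline's
own tolerances: cross-mode duplicate pairs ([M+H]⁺/[M−H]⁻ of one neutral
mass, within 0.002 Da and 0.2 min), co-eluting in-source fragment pairs
(r > 0.95, RT within 0.1 min), blank-dominated contaminants, a sporadic
(low detection frequency) fraction, and batch-correlated multiplicative
drift shared between features and the 34 isotope-labeled internal
standards so the normalization has real signal to remove.

All randomness flows from one master seed through numpy `SeedSequence`
child streams (`SeedSequence([seed, k])` with a fixed counter k per
artefact), so each artefact regenerates independently and bit-identically.

What the generator does *not* emulate: raw spectra, chromatographic peak
shapes, RT drift between batches, adducts beyond the single
protonation/deprotonation pair, matrix effects, or disease outcomes.
Consequently, passing tests demonstrate that the *procedures* are
implemented correctly and are calibrated on data obeying their
assumptions — not that the assumptions hold in any particular real
cohort.  The fraction of pregnancies ending in delivery (0.85) and the
timing of second visits (uniform 1–16 years) are free parameters with no
claimed fidelity.

## Targeted quantification

Calibration lines are ordinary least squares of response ratio
(analyte area / internal-standard area) on nominal concentration, nine
levels spanning 0.01–100 ng/mL; the three replicate injections per batch
are averaged into one per-batch calibration (drift handling beyond
averaging is not modelled).  Quantification inverts the line; a cell
above the upper calibration bound keeps its extrapolated value and is
flagged.  Censoring substitution replaces below-MLOQ values by MLOQ/2 and
non-detects by MLOQ/4, idempotently.  Isomer totals sum linear + branched
values, substituted values included; the combined status takes the "most
detected" member status, so a total of two substituted cells remains
flagged substituted.  Reference standardization of steroid hormones is
simplified to multiplicative scaling by the pooled-QC/reference ratio.

Boundary conventions (all inclusive, least-surprise): detection frequency
exactly at the 60%/70% threshold retains; a value exactly at MLOQ counts
as quantified; a value exactly at the calibration upper bound counts as
in-range.

The targeted detection frequency is, by default, the fraction of samples
*not* requiring substitution (quantified or extrapolated).  The
alternative reading — counting below-MLOQ detections as detected — is
available as `df_mode="detected"`; the two differ only for analytes with
many below-MLOQ cells.

## Untargeted feature treatment

The cascade runs in fixed order, each stage logging removals to a
provenance list: (1) blank-ratio filter, keep max(sample)/mean(blank) > 5,
zero blank mean retains any detected feature; (2) ESI merge on neutral
mass m/z ∓ 1.007276 Da (proton mass; the constant is fixed here because
exports rarely state it) within 0.002 Da and 0.2 min, discarding the
lower-average-intensity twin; (3) IS-PCA normalization; (4) per-cell blank
treatment: ratio against blank mean + 0.1 pseudo-count, below 5× → 0,
else subtract the blank mean, then floor areas below 90,000 to 0; blank
columns are zeroed afterwards, which makes the stage idempotent;
(5) correlation dedup: features processed in descending average-area
order (ties broken by feature id so the survivor set is deterministic),
a remaining feature within 0.1 min whose Pearson r over co-detected
(shared nonzero) samples exceeds 0.95 at p < 0.001 (t-distribution,
n − 2 df) is discarded; pairs with < 3 co-detected samples are skipped;
(6) detection frequency = fraction of sample columns with area > 0,
computed after dedup; features below 70% are dropped.

The visual peak-shape inspection step that usually accompanies dedup is
replaced by the quantitative r/p/RT gates alone — peak profiles are not
present in alignment exports.

**IS-PCA normalization.**  The log internal-standard matrix (standards ×
samples) is transposed, column-centered, and decomposed by SVD; the
per-sample drift is the mean over standards of the rank-k reconstruction
(k = 2 by default), recentred to zero mean so the geometric mean of the
correction is one and the overall intensity scale is preserved.  Areas in
study-sample columns are divided by exp(drift); zeros stay zero; an
occasional missing standard is imputed at its mean log intensity, and a
sample with no IS signal at all is rejected by name.  A planted twofold
batch drift is removed to well under 5% residual.  A simple per-sample
median-IS scaling is available as `method="median"`.  Note that unlike
the pure filter stages, this stage is only approximately idempotent: a
second pass removes the next principal components of what remains.

## Annotation

Spectra are binned at 0.01 Da and square-root intensity weighted (common
practice to de-emphasize dominant peaks; switchable off).  The dot score
is 1000 × cosine over the union of bins; the reverse-dot score restricts
the query to the reference's bins before the cosine, so extra query peaks
(noise, co-elution) do not penalize it — reference peaks missing from the
query penalize both.  The total identification score is the mean of dot
and reverse dot; the blend used by vendor software is proprietary, and
the mean is documented here as an approximation that preserves the
printed thresholds: Level 2 requires total > 700 and dot or reverse dot
> 600 (strict), Level 1 additionally a library RT within 0.2 min
(tolerance chosen as the merge RT tolerance; no published value exists).
Only the best-total entry per feature is considered, after a 0.01 Da
precursor pre-filter.  Class (environmental / endogenous / ambiguous on
conflict) and subclass come from library metadata; counts over the three
classes always sum to the number of annotated features.

## Association models

Levels are square-root transformed (order-preserving, defined at zero,
tames the left skew).  Spearman correlations screen raw values against
risk factors; Pearson correlations among transformed values inform the
PFAS co-exposure groups, which default to the three predeclared lists
(PFDA/PFNA/PFUnDA; FOSA/FOSAA/NEtFOSAA; PFOS/PFHpS/PFOA/PFHxS) with an
optional average-linkage |r| ≥ 0.6 clustering for new datasets.

Each chemical is modelled separately by a linear mixed model with a
subject random intercept, fitted by REML via statsmodels `MixedLM` on
complete-case rows.  Adjustment sets are exposure-specific: age models
adjust for BMI, pregnancies, sample year, age at menarche and tobacco;
parity models for age, birth year, age at menarche and tobacco; menarche
models for age, BMI and birth year.  Tobacco combines smoking and snuff
into ever/never.  For numerical conditioning the outcome is standardized
and covariates centered internally; the reported coefficient and SE are
rescaled back exactly, so results are invariant to this device.  With
fewer than two subjects contributing repeats the model falls back to OLS
with a warning; a rank-deficient design is flagged non-converged and
excluded from multiplicity counts.

P-values are Wald tests on the normal reference by default.  A
t-reference on residual degrees of freedom (n − p − #subjects-with-
repeats) is available as a more conservative small-sample option;
Satterthwaite/Kenward-Roger degrees of freedom are not implemented in the
underlying fitter, and at this design size (161 observations, ~100
groups) simulation shows the normal reference is already calibrated:
over replicate cohorts at the default scale, 95% Wald intervals cover at
≈ 0.96 and the type-I error at α = 0.05 is ≈ 0.05.

The age × pregnancies interaction is tested by adding the product term to
a model containing both main effects.  The parous-only sensitivity
analysis re-fits on subjects with ≥ 1 pregnancy by default (≥ 1 delivery
via config); the two definitions differ only for women whose pregnancies
all ended early.  Multiplicity for untargeted scans is flagged at three
nested tiers — α = 0.05, the 0.005 literature threshold, and Bonferroni
α/n_tests with n_tests counting converged models only; targeted analyses
use the nominal α tier.

## Problem sizes and numerical choices

Default desk-scale runs use 120 + 90 untargeted features, a 40-entry
library, and cap the untargeted model scan at 60 outcomes; the
simulation-calibration suite uses 500 replicate cohorts for coefficient
recovery and coverage and 1,000 for type-I error, all at the full cohort
scale of 100 subjects / 161 samples.  These sizes were chosen so the
whole calibration is routinely re-runnable on a single CPU while keeping
Monte-Carlo error well below the decision bands.

Degenerate inputs are handled explicitly: empty cohorts and empty feature
tables flow through the entire pipeline producing empty outputs; a
detection-frequency threshold above 1 empties the association stage
without error; constant outcomes, constant correlation columns and
all-equal calibration concentrations are rejected or flagged rather than
silently fitted.

## Known limitations

- The generator's areas are log-normal with a shared batch drift; real
  instrument drift is smoother within batches and partly RT-dependent.
- The total identification score is a stand-in for the proprietary blend;
  absolute score values are comparable only within this package.
- Reference standardization is reduced to a single multiplicative QC
  scaling.
- `MixedLM` fits one variance component; crossed or nested designs
  (e.g. batch random effects) are out of scope.
- Untargeted intensities are comparable within a feature across samples,
  never between features.
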