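# Methods

## The inference problem

Every subject in an autopsy cohort contributes exactly one molecular
snapshot, time-stamped by the date and local clock time of death.
Because deaths spread over the full year and the full day, the cohort is
a cross-sectional sampling design for two fixed-period cycles: 24 h and
365 d.  `pmrhythm` fits both cycles jointly per molecular feature and
builds all inference on permutation nulls that shuffle the death times
(or dates) across subjects, which preserves every other property of the
cohort — covariate structure included — while destroying only the
time-expression association under test.

## Time reference

Clock times are converted to three diurnal angles (2&pi; = 24 h):
zeitgeber time (0 = sunrise on the date of death, reflecting natural
light exposure), local clock time (0 = midnight, reflecting social/
artificial-light schedules), and time relative to the dark-period
midpoint (which is invariant across seasons).  Sunrise and sunset come
from the NOAA low-accuracy solar equations (fractional year, equation of
time, declination; zenith 90.833°, i.e. refraction plus solar radius),
accurate to ±3 min — far below the precision of recorded death times.
Dates map to a seasonal angle with 2&pi; = 365 d and 0 at January 1
00:00; February 29 folds onto February 28 so leap years do not distort
the circle.  Polar dates without sunrise raise an error rather than
guessing.  The recorded UTC offset is taken as given; no timezone
database is consulted.

## Cosinor model

Per feature, `y = mu + A_d cos(theta - phi_d) + A_s cos(psi - phi_s) +
sum_k gamma_k x_k + eps`, linearized to OLS on
`[1, cos theta, sin theta, cos psi, sin psi, covariates]` with
`A = sqrt(a^2 + b^2)` and `phi = atan2(b, a)` wrapped to `[0, 2pi)`.
Degenerate fits (`a = b = 0` to machine precision, or zero residual
variance) are flagged and excluded from downstream clustering.  Periods
are never estimated: with one observation per subject the data carry no
information about period.  Covariate sets are modality-specific (RIN for
RNA, cross-correlation for H3K9Ac, batch for all; age, sex, post-mortem
interval, depressive symptoms and AD pathology burden throughout).
Rhythmicity per period uses the nested F test
`F = ((RSS_reduced - RSS_full)/2) / (RSS_full/(n - p))` with
`(2, n - p)` degrees of freedom.  Two edge conventions: a perfect full
fit with rhythm signal reports `F = +inf, p = 0`; a perfect fit whose
reduced model is equally perfect (constant y) reports `F = 0, p = 1`.

Fitting is vectorized: all complete features share one design matrix and
are solved in a single least-squares call, which is what makes
thousands of permutation replicates affordable.  Missing values fall
back to per-feature listwise deletion; features with fewer than 10
usable samples are flagged out.

## Permutation engine

Replicate b draws its generator from `SeedSequence([master_seed, b])`,
so results are bit-identical regardless of evaluation order.  Exceedance
counting is inclusive (`null >= observed`), the conservative tie
convention; zero exceedances are reported as "<1/B" rather than 0.
Shuffling is implemented at two levels: label-level (move the raw clock
time or date to another subject and re-derive angles against the
recipient's own date/site sun events — preserving the marginal time
distribution exactly) and angle-level (permute the angle columns
directly).  For a single-site cohort they differ only through
day-to-day sunrise drift; angle-level is the default for speed.  The
default replicate count is B = 1,000 for desk use; tests and the
pipeline default use B = 200 and state so in their outputs.

## Acrophase clustering

Acrophase densities on both circles are bimodal (morning ~ZT0 vs evening
~ZT12; spring vs fall), so classification reduces to cutting a circular
density into two arcs.  A one-dimensional self-organizing map on a ring
(24 nodes, 10 batch epochs, Gaussian ring neighborhood decaying 6 → 1,
inputs as unit vectors) quantizes the density; the ring is cut at the
two largest circular gaps between occupied nodes (empty nodes carry no
data density and never separate clusters).  The downstream object is
only this two-way cut, which is insensitive to the SOM hyperparameters;
they are nevertheless exposed as arguments.  Labels: the diurnal cluster
whose density-weighted mean is nearer angle 0 is "morning"; the seasonal
cluster whose mean falls in the Jul–Dec half-year is "fall", with a
deterministic tie-break.

For DNA methylation the temporal semantics follow the *nadir* (trough),
because hypomethylation associates with transcription.  Nadirs are
acrophases rotated by exactly &pi;, so nadir-based clustering is
implemented as acrophase clustering plus relabeling — the identical
feature partition, bit for bit.  Two further numerical choices make
"acrophase vs nadir equivalence" exact rather than approximate: the
Mardia–Watson–Wheeler statistic computes circular ranks relative to a
canonical origin (the first observation), making W numerically invariant
under joint rotation, and all chi-square statistics accumulate their
cell terms with an exactly rounded sum (`math.fsum`), making them
invariant under row/column relabeling.

## Circular statistics

MWW uniform-scores test: combined circular midranks (stable, exact
half-integers), scores `beta_i = 2 pi r_i / N`,
`W = 2 sum_g (C_g^2 + S_g^2)/n_g`.  An exact enumeration mode covers
small samples.  Circular correlation is the Jammalamadaka–SenGupta
coefficient (rotation-invariant, symmetric).  Set enrichment against
external gene lists is a plain 1-df Pearson chi-square on the 2x2
membership table.

## Genomic context

Coordinates are 0-based half-open throughout (BED convention).  Distance
from a feature interval to a TSS is the edge gap (0 if the TSS falls
inside); "within 2,000 bp" is inclusive.  TSS-proximity uses only active
TSSs (transcript detected in >90% of samples).  Epigenomic features near
TSSs of both a morning- and an evening-class transcript are ambiguous:
excluded and counted, keeping the compared groups disjoint.  Proximity
partitions depend only on coordinates, never on sample metadata — they
are fixed across permutation replicates by construction.

## TF-site association

A feature is locally associated with a TF when its anchor (TSS point,
peak interval, or CpG position) lies within 2,000 bp of an annotated
binding site.  One *joint* logistic regression of temporal class on all
TF indicators estimates each TF's association adjusted for all others;
indicators are standardized for a small ridge penalty (1e-4 by default,
guarding against separation from sparse columns) and coefficients mapped
back to the indicator scale.  A `--marginal`-style one-at-a-time fit is
available through calling `fit_tf_logistic` per column.  Permutation
inference re-runs the whole fit → cluster → regress chain per replicate;
per-TF p-values compare |beta| with that TF's own null betas, and the
analysis-wide FDR at threshold t is the replicate-averaged count of null
|beta| ≥ t (pooled over TFs) divided by the observed count, evaluated at
each observed |beta| and monotonized (step-up).

## AD differential rhythms

The design gains (AD, age, sex) x (cos, sin) interaction columns for
both periods, plus the modifier main effects.  Group parameters are
evaluated at AD ∈ {0, 1} with age and sex at cohort means, so the group
contrast isolates the AD coefficient while age and sex effects on the
rhythm parameters are adjusted for.  "Relative amplitude" is amplitude
divided by the group's model-predicted mean level (all covariates at
cohort means) — a standard cosinor normalization chosen because the
quantity is otherwise underdetermined; raw amplitudes are returned
alongside.  Per-feature AD-minus-nonAD acrophase differences are wrapped
to (−12, 12] h and (−182.5, 182.5] d; cohort summaries are medians, with
two-sided permutation p-values (times shuffled for diurnal metrics,
dates for seasonal).  AD labels are never shuffled: the null keeps the
AD-covariate structure and destroys only the time association.

## Synthetic cohorts

The generator inverts the analysis model exactly: at zero noise the
cosinor fit recovers planted amplitudes and phases to machine precision,
which anchors the whole test pyramid.  Defaults encode the emulated
study conditions: deaths uniform over year and day at a single Chicago
site; age median 88.7 (s.d. 6), 63% female, 61% with depressive
symptoms, post-mortem interval log-normal with median 5.7 h, 59%
pathological AD; 20% of features rhythmic with diurnal acrophases from a
von Mises mixture at ZT0/ZT12 (kappa = 8), seasonal acrophases at
mid-April/mid-October, and morning↔fall coupling 0.9; AD advances
diurnal acrophases by 1.5 h, delays seasonal acrophases by 15 d, and
attenuates amplitudes by 20%.  Per-feature amplitudes are log-normal
with median 0.1 (log2 units) — real effect sizes are not publicly
tabulated, so this is chosen small relative to unit noise; power studies
override it with a fixed amplitude.  Covariate effects are drawn at a
small scale (0.05 per standardized covariate) since no reference values
exist.  Methylation mode squashes the linear predictor through a
logistic link so beta values stay in (0, 1); the analysis still models
them linearly.

What the generator does *not* emulate: read-level noise, isoform/gene
hierarchies, spatially correlated batch effects, cross-feature
co-expression beyond the shared rhythm structure, or multi-site cohorts
(available but off by default).  Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
stated generative model, not robustness to every artefact of real
tissue data.

## Problem sizes and power

Test and demonstration runs use cohorts of 150–500 subjects and
300–2,000 features with B = 100–500 permutations — sizes at which each
analysis completes in seconds to a few minutes while keeping planted
effects comfortably detectable.  One planted effect sits at the design's
statistical floor and is worth recording: detection of a median seasonal
acrophase shift by permutation.  Under the shuffled-date null the
per-feature seasonal phase differences are nearly uniform on
(−182.5, 182.5], so the null median over m features has an irreducible
spread of about 365/(2 sqrt(m)) days (~8 d at m = 500); a +15 d planted
delay is therefore only a ~1.8-sigma effect at that feature count, and
its two-sided permutation p hovers near 0.06–0.13.  The diurnal analogue
(−1.5 h on the 24-h circle, ~2.8 sigma) is reliably detected.  A second
structural effect: when many features share one strong amplitude, their
rhythm signals project onto the same two shuffled design vectors under
permutation, correlating the null across features; the AD power studies
therefore use a moderate amplitude (0.25 at unit noise) at which
per-feature phase noise stays small while this shared leakage is
negligible.

## Known limitations

- Single-harmonic cosinor only; non-sinusoidal waveforms alias into
  reduced amplitude.
- One sample per subject: no within-subject dynamics, no period
  estimation, and phase estimates conflate inter-individual phase
  dispersion with measurement noise.
- The TF analysis treats binding-site annotations as fixed and binary;
  cell-type specificity of binding is out of scope.
- PCA sample QC is a single pass (no iterative re-fitting after outlier
  removal).
- The SOM two-cluster cut assumes bimodality; genuinely unimodal or
  multimodal acrophase densities will still be forced into two arcs
  (the degenerate-input case is detected, intermediate cases are not).
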