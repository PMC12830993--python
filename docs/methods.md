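# Methods

This note documents the models, numerical choices and limitations behind
`pirlms`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

A tissue specimen (a xenograft growth) is probed by laser ablation with
on-line time-of-flight mass spectrometry at one spectrum per second. A
~10-second *sampling event* yields a lipid-range molecular fingerprint
(negative-ion, 100–1000 Da). The task is binary: is the growth a true
solid-tumour PDX or a lymphoproliferative imposter? Two properties shape
the whole design:

* **Repeated, correlated measurements.** Several sampling events are taken
  per specimen (spatial heterogeneity); events from one specimen share a
  specimen-level effect and must never be split across train/test.
* **Abstention is a first-class outcome.** A screening tool that guesses on
  ambiguous spectra is worse than one that declines; the classifier carries
  an explicit rejection region, and all accounting distinguishes
  *bad data* (failed QC), *unclassifiable* (rejected by the model) and
  classified points.

## Preprocessing

**Event recognition.** A state machine over the 1 Hz scan stream: an event
opens at the first scan whose TIC exceeds the trigger (default 10⁴),
accumulates up to 13 qualifying scans and closes on count or after a 13 s
timeout. Scans are never shared between events. When the stream already
carries event identifiers (synthetic or pre-segmented data),
`events_from_table` groups directly.

**QC.** Three bad-data criteria, checked in a fixed order so the first
failure names the status: (a) no peak within ±0.25 Da of the lock-mass
m/z 717.5070; (b) signal duration ≤ 3 s (i.e. < 4 scans at 1 Hz — "more
than 3 seconds" is strict); (c) combined-spectrum TIC ≤ 10³. The 10³
threshold is applied to the *event's* combined spectrum; per-scan TIC is
used only by the 10⁴ recognition trigger. These are two deliberately
distinct thresholds.

**Lock-mass correction.** The observed lock-mass is the most intense peak
within the search window; the correction is a single uniform *additive*
shift (reference − observed) applied to the whole combined spectrum, after
which the identified peak is pinned to the reference exactly (avoiding a
1-ulp float residue). Additive rather than ppm rescaling is the simplest
model consistent with a single internal standard; with one reference ion
the two are indistinguishable anyway. Correction precedes binning —
correctness forces that order.

**Binning and normalisation.** Half-open bins [edge, edge+0.1) from
100.0 Da; a peak with 100 ≤ m/z < 1000 contributes its full intensity to
bin ⌊(m/z − 100)/0.1⌋, giving exactly 9,000 features. A guard of 10⁻⁶ of a
bin width is added before the floor so that a peak sitting numerically on
a bin edge (e.g. 500.0, whose float quotient is 3999.9999…) lands in its
own bin. Rows are divided by their sum (each good row sums to 1 within
10⁻⁹); rows with no in-range signal are flagged, never divided. The 1 Da
rebin sums blocks of 10 consecutive bins (900 features) and conserves row
sums exactly.

## The rejection classifier

PCA (exact SVD, deterministic given row order) retains the smallest number
of leading components whose cumulative explained-variance ratio reaches
the configured fraction (default 0.95), optionally capped (the fixed-cap
mode of projection-based commercial modelling software, e.g. 262
components); LDA then projects the retained scores onto k−1 = 1
discriminant axis. Each class c is summarised in LDA space by its centre
μ_c and covariance Σ_c, estimated with ddof = 0 and shrunk toward the
pooled within-class covariance:

    Σ_c ← (1 − λ) Σ_c + λ Σ_pooled,   λ = 0.1.

Per-class (rather than pooled) covariance lets the rejection radius follow
each cluster's own spread; shrinkage protects small classes from
degenerate estimates. Population covariance plus the scale-invariance of
Mahalanobis distance along a single axis makes the fitted distances exactly
invariant to duplicating the training set.

A query is scored by d_c = √((x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c)) — in 1-D simply
|x−μ_c|/σ_c, the number of standard deviations from the cluster centre.
Decision rule:

* min_c d_c > 4 (the SD threshold) → **unclassifiable**, no probabilities;
* otherwise the label is argmin_c d_c with p_c ∝ exp(−d_c²/2), the
  Gaussian-likelihood softmax, normalised over classes. Exact ties resolve
  to the first class in sorted order ("lymphoma" precedes "pdx") for
  determinism.

The distance space is the LDA score space (the space the "cluster centres"
of a scores plot live in); the exact probability formula of the commercial
implementation is not public, so only the decision rule — not
probability-level equivalence — is guaranteed.

Specimen-level calls are the majority label over the specimen's classified
events; *spatial concordance* is the fraction agreeing with the majority.
A vote tie or a specimen with no classified events is *indeterminate*.

## Validation

**Folds.** StratifiedGroupKFold with specimens as groups and classes as
strata: every event of a specimen is in exactly one fold, each class
appears in every fold when counts permit, and train/test specimen sets are
disjoint in every fold (asserted programmatically in the tests).

**Two accuracy denominators.** Per-classifiable = correct/(correct +
misclassified) × 100 (rejected spectra carry no decision); per-all =
correct/total × 100. The duty cycle is classifiable/attempts × 100, with
both QC failures and rejections counting against it. `CvReport` also emits
the fold-averaged per-classifiable accuracy, since published
permuted-model numbers average across folds (at these sizes pooled and
fold-averaged agree to ~2 decimals).

**Permutation null.** Whole specimens are reassigned: each true class's
specimens are split (near-)evenly between two pseudo-groups, so both
groups mix both classes at near-equal specimen counts and the group
structure survives for full-group CV. Under this null, per-classifiable
accuracy sits in a band around 50%. Two subtleties the acceptance test
accounts for: (i) the effective sample size is the number of *specimens*
(events within a specimen share a random effect), so the 95% binomial band
uses n = specimens, not events; (ii) grouped leave-out with balanced
pseudo-groups carries a mild, well-known below-chance bias, and a single
permutation draw has ~5-percentage-point specimen-level noise — the test
therefore averages three permutation draws as its estimate of the null
mean.

**SMOTE.** Implemented in-package (no oversampling dependency is
available): minority-class points are augmented up to the majority count
by x_new = x_i + u·(x_nn − x_i), u ~ U(0,1), with x_nn one of the k = 5
nearest minority neighbours (k reduced with a warning for tiny classes).
Augmentation happens in PCA-score space, inside each training fold, before
the LDA step; test folds are never augmented and are bit-identical to
plain CV's.

**ROC.** Standard threshold sweep over the lymphoma softmax probability
(or a signed LDA score); AUC is cross-checked in the tests against the
Mann–Whitney U identity AUC = U/(n₁n₂).

**Blind evaluation.** Labels travel in a `SealedGroundTruth` that exposes
only specimen identity to the classification path and is unsealed once, at
scoring. Sensitivity and specificity use each class in turn as positive,
over classified events only. Probability and spatial-concordance summaries
are reported as mean ± *half* a sample SD — the reporting convention of
the source cohorts — with `sd_scale` restoring a conventional ±1 SD.

## Diagnostics

UMAP (Euclidean, 25 neighbours, 2 components, 200 epochs, seed 123) is
visualisation-only; module boundaries keep its output away from any
classification decision. The configured "iterations = 250" is carried as
metadata since the embedding algorithm exposes a single epoch parameter.

Correlation maps are 900×900 Pearson matrices over the 1 Da features
across an event subset (≥3 events; with 2, every coefficient is ±1).
Zero-variance features give undefined coefficients and are masked, not
imputed. Map similarity is the Pearson correlation of the two upper
triangles over jointly defined entries — a scalar stand-in for the visual
comparison of a query specimen's map against per-class control maps built
by pooling specimens whose events all classified correctly.

The jitter view exports per-event 1-D LDA scores plus an overlap
statistic: the fraction of events falling inside the intersection of the
two classes' score ranges (≈0 when separated, ≈1 when the distributions
coincide).

## The synthetic world

No raw data is deposited, so the generator emulates the statistical
structure the analysis assumes. Stated-world defaults:

| parameter | default | rationale |
|---|---|---|
| specimens per class | (20, 90) | modelling-cohort shape |
| events per specimen | U{10..14} | ~12 events/specimen, ~1,300 events |
| scans per event | 13 | recognition parameter |
| class panels | 7 peaks each, 600–900 Da | lipid-range fingerprints |
| shared peaks | 5 peaks | chemistry common to both classes |
| lock-mass | 717.5070 Da, log-intensity 10 | internal standard |
| specimen effect SD | 0.3 (log) | between-specimen heterogeneity |
| scan noise SD | 0.4 (log) | shot-to-shot variability |
| panel covariation SD | 0.5 (log) | per-event co-regulation of the class panel |
| mass drift SD | 0.02 Da/event | uniform shift, well inside ±0.25 window |
| baseline noise | 40 peaks/scan, log-mean 6 | chemical background |
| bad-event rates | (11, 23, 0)/2079 | blind-set bad-data accounting |

Intensities are log-normal, exp(mean + specimen effect + panel activity +
scan noise): strictly positive and heavy-tailed like real peaks. Mass
drift is one uniform additive shift per event (matching a single lock-mass
correction per event) with the stated standard deviation. The *panel
activity* term — one scalar per event shared by all class-panel peaks —
encodes co-regulation of a lipid panel across sampling spots; without it
every feature fluctuates independently and correlation maps carry no
reproducible class structure at all, contradicting the physical premise of
the map diagnostic. Injected bad events violate exactly their designated
QC criterion (for missing-lock-mass events, baseline peaks are kept out of
the search window so the violation is guaranteed).

What the generator does **not** emulate — and hence what a green test does
not establish: isotope envelopes and adducts, profile-mode peak shapes,
intensity-dependent mass error (drift is mass-independent), murine stromal
admixture, instrument drift across acquisition days, and any real lipid
identities. The ~10 effective PCA dimensions of the synthetic world are far
below the ~262 of real spectra; tests demonstrate correctness of the
machinery, not field performance.

## Degenerate inputs and tie-breaks

Single-class fits, folds with single-class training sets, empty panels,
fewer specimens than folds, <3-event correlation subsets and singular
covariances (before regularisation) all raise. Component counts are capped
at the feasible rank when samples are scarce. Classification ties break by
class order; specimen-vote ties are indeterminate rather than broken.

## Known limitations

* The additive lock-mass model cannot represent mass-dependent calibration
  error; with a single reference ion no data could distinguish the two.
* The probability map p ∝ exp(−d²/2) assumes Gaussian clusters in LDA
  space; probabilities are decision weights, not calibrated posteriors.
* mzML input is not supported in this build; the CSV long format is the
  interchange representation.
* The permutation null is estimated from a small number of draws in the
  acceptance path; a production significance test would use hundreds.
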