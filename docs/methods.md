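# Methods

## Scope and model

The package implements the statistical core of a multi-proteome AD biomarker
pipeline: label-free spectral-count quantification of WT-vs-5xFAD contrasts
in three proteomes (hippocampus, cortex, plasma EV) at two ages, directional
pathway-activation scoring, human plasma-EV biomarker classing by MMSE stage,
and sequential panel selection with a cross-validated SVM. Wet-lab stages
(database search, FDR control, EV isolation, densitometry image analysis) are
upstream of the interface: the pipeline starts at protein-level PSM count
tables and Ponceau-normalized band intensities.

## Spectral-count quantification

Technical replicates are pooled by summation into a cumulative count c per
protein per group — the replicate-level variance is deliberately not modeled,
so p-values quantify counting (technical) confidence, not biological
replication; this caveat applies to every downstream significance call.
The normalized PSM index is i = s·c/T (default scale s = 10⁴, exposed), T
being the group total. The G statistic is the likelihood-ratio test of a
common proportion across the two groups, G = 2Σ c_j ln(c_j/e_j) with
e_j = (c_A+c_B)·T_j/(T_A+T_B) and 0·ln 0 = 0, referred to χ² with 1 df. A
Williams small-sample correction is available but off by default, since the
plain statistic is the conventional choice for spectral counts.

Numerical conventions, each chosen once and exposed as a parameter:

* pseudocount q = 0.5 **index units**, applied only inside the fold-change
  ratio so one-sided detections keep a finite fold; the G-test always runs on
  raw counts. Consequence: for proteins whose indices are of order 1 (low
  abundance at moderate depth) the fold estimate is shrunk toward zero —
  conservative exactly where counts are scarce. Significance is unaffected.
* strict inequality for p thresholds (p < 0.05), inclusive for fold
  thresholds (|log₂fold| ≥ 5), matching the common phrasing of such filters.
* deterministic output order: p ascending, |log₂fold| descending, protein id.
* proteins with zero counts in both groups are ND: excluded from testing and
  from altered-set membership, never imputed as zero-fold.

## Pathway activation

The enrichment p is the hypergeometric upper tail (one-sided Fisher exact
test) of the overlap between pathway members and the significant set, with
the quantified proteins of the contrast as universe. The activation score is
the unweighted directional consistency z = Σ s_k/√N over significant members
(s_k = fold sign × expected direction); |z| ≤ √N with equality iff fully
consistent. Calls require both z ≥ 0.5 in magnitude and −log₁₀ p > 1.3
(i.e. p < 0.05); base 10 is the only base under which a 1.3 cutoff
corresponds to a conventional significance level. Commercial knowledge-base
content, edge weights, and literature-bias corrections are out of scope —
pathway definitions with per-member expected directions are user data (GMT
with a +/− direction string). Across strata, a pathway is summarized
activated/deactivated only if every stratum that calls it agrees; both
directions make it mixed; never-called pathways leave the denominator.

## Human panel statistics and classing

Stages follow the MMSE partition late < 16 ≤ early ≤ 23 < 24 ≤ healthy,
a total partition of [0, 30]. Per protein: one-way ANOVA across the three
groups, then the three pairwise two-sample t-tests (pooled variance; Welch by
flag) at α/3 — Bonferroni over the within-protein family of three
comparisons, not across proteins, mirroring the per-panel post-hoc
convention. Flags are up/down by the sign of the mean difference when
adjusted-significant, else ns. With only two groups present the same
machinery runs a single unadjusted two-tailed t-test.

Class assignment is a first-match rule table over the flag triple
(healthy-vs-early, healthy-vs-late, early-vs-late), replaceable as data:

| pattern | class |
|---|---|
| he = ns | unclassified |
| he = up, hl = up | class 3 |
| he = up, hl = ns, el = ns | class 2 |
| he = up, hl = ns, el ≠ ns | class 1 |
| he = up, hl = down | class 1 |
| he = down | class 2 |

The class-1/class-2 boundary is genuinely underdetermined by stage-wise
significance: both are "significant in early". The default uses the
early-vs-late comparison to distinguish a demonstrated late return (class 1)
from an indeterminate late level (class 2), and routes down-going early
changes to class 2; both choices are isolated in the rule table.

## Panel selection and cross-validation

The feature universe is the intersection of per-group marker availability
(markers measured in every subject of every group), sorted lexicographically.
Within each training fold, features are ranked by two-sample t-test
(ascending p, ties by descending |t| then name; degenerate zero-variance
features rank first when perfectly separated, last otherwise), and for every
panel size k a StandardScaler + linear SVC (C = 1) pipeline — the
`SequentialPanelClassifier` estimator — is trained on the top k and scored on
the held-out fold. Ranking inside the fold avoids selection bias;
standardization statistics come from training data only. Cross-validation is
10 repeats of stratified 10-fold with repeat seeds seed+0..seed+9; accuracy,
sensitivity (positive-class recall; the later disease stage is positive) and
specificity are means over all 100 held-out evaluations. The best panel size
is the argmax of mean accuracy with ties to the smaller panel; the reported
best panel is the top-best_k ranking on the full data. Held-out decision
scores at best_k are pooled per repeat for per-repeat AUCs (their mean is
reported) and pooled across all repeats for the reported ROC curve, whose
trapezoidal area is the reported AUC — so the stored curve and AUC are
mutually consistent. Three one-vs-one binary contrasts are fitted, never a
multiclass model. Kernel, C, folds, repeats and seeds are all configuration.

The argmax over panel size is a noisy statistic when the accuracy curve is
nearly flat (differences of ~1% between adjacent k at n = 40/group); the
recovery test therefore checks the median best_k over five independently
generated cohorts rather than a single draw, while per-feature mean ranks —
a stable statistic — are asserted per cohort.

## Synthetic data: what it emulates and what it does not

The generator provides planted ground truth for every stage; its
distributions are stand-ins (recorded as such in the truth JSON), because no
noise or depth characteristics of the emulated MS runs are available.

* **PSM counts**: Poisson around abundance × depth-factor means; per-sample
  depth factors lognormal (σ = 0.1), per-protein abundances log-uniform over
  two orders of magnitude, shared across tissues. Planted proteins carry a
  5xFAD/WT generating-mean ratio of 2^effect (default 2³) in every stratum.
  Poisson sampling is the simplest model under which the G-test's
  conditional-binomial assumptions approximately hold, so the calibration
  test (null false-positive fraction ≈ 5%) is meaningful. Real spectral
  counts are overdispersed between biological replicates; because replicates
  here are technical and pooled, that axis is intentionally absent, and
  passing calibration says nothing about biological-replicate variance.
* **Human intensities**: lognormal (σ = 0.4 on the log scale) around
  class-specific geometric means; the standardized shift d moves the log-mean
  by d·σ (default d = 3, n = 40/group, within the 39–47/group design).
  MMSE is uniform over each group's admissible integers — no empirical MMSE
  distribution is claimed.
* **Class-2 planted pattern**: the late mean sits midway between healthy and
  early. At the default effect size this midway elevation (d/2 = 1.5σ) is
  itself detected with power ≈ 1 at n = 40, so planted class-2 proteins are
  *expected* to surface as class 3; the truth record carries this implied
  assignment (`human_expected_class`) alongside the planted label, and the
  round-trip test asserts the implied one. A weaker effect or smaller cohort
  leaves the midway elevation undetected and class 2 is recovered as itself.
* **Pathways**: coherent pathways draw members from planted differential
  proteins with matching expected directions; random pathways draw uniformly
  with random directions; coherence is recorded in truth. Random streams are
  split per table so adding pathways never perturbs counts.

What passing these tests shows: the statistics are implemented correctly,
calibrated under their own assumptions, and recover planted effects at
realistic sizes. What they do not show: performance under biological
variance, batch effects, missingness patterns of real densitometry, or the
actual human cohort's class structure — the study's human accuracies
(78.5%/79.6%/70.5%) and AUCs (0.84/0.85/0.75) are context, not reproduction
targets, since the underlying data are not deposited.

## Problem sizes in the shipped checks

Calibration uses 2,500 proteins at depth 10⁵ (≥ 2,000 quantified tests);
recovery plants 20 of 2,000 proteins at 2³ with depth 10⁵; the
truth-consistency check uses depth 10⁶ with 25 replicates so Poisson noise
is small against the 5% band; pathway agreement uses 40 pathways over 2,000
proteins; CV suites use 40 subjects per group with 5–9 features. These sizes
make the suite fast while keeping every statistical band comfortably
non-marginal.

## Orchestration

`evpanel run` executes the stages in dependency order from one YAML
configuration, skipping human-panel stages when no panel is present, and
writes a manifest with the package version, seed, per-stage parameters and
SHA-256 hashes of every output — two runs of the same configuration produce
identical manifests. Per-stage CLIs (`simulate`, `quant`, `compare`,
`pathways`, `biomarkers`, `ml`) remain independently usable.

## Known limitations

* No biological-replicate variance model: significance reflects counting
  statistics of pooled technical replicates.
* Fold shrinkage by the index-unit pseudocount for low-abundance proteins
  (see above); use a smaller pseudocount if unbiased folds matter more than
  finite one-sided folds.
* The class-1/class-2 rule and the down-going-early routing are documented
  interpretations, replaceable via the rule table.
* The G-test's χ²₁ reference is asymptotic; at very low depth (expected
  counts ≪ 5) it becomes conservative. The Williams correction option
  mitigates but does not remove this.
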