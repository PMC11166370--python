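# evpanel

Spectral-count differential abundance, directional pathway activation, and
plasma extracellular-vesicle (EV) biomarker-panel selection — a tested,
reusable implementation of a multi-proteome analysis pipeline for
Alzheimer's-disease (AD) biomarker discovery in the 5xFAD mouse model and
human plasma-EV validation cohorts.

## Who this is for

Proteomics groups doing label-free spectral-count quantification (hippocampal,
cortical, and plasma-EV proteomes; WT-vs-5xFAD contrasts at 3 and 6 months)
and translational groups validating candidate panels on human plasma-EV
densitometry with MMSE-staged cohorts. Since raw LC-MS/MS and densitometry
data of the emulated study design are not publicly deposited, a synthetic-data
generator with planted ground truth makes every stage testable end to end.

## The statistics at the core

**Spectral-count quantification.** Per protein, technical replicates are
pooled into a cumulative PSM count c per group; the normalized PSM index is
i = 10⁴ · c / T with T the group's total PSM yield. Fold change is
log₂((i_B + q)/(i_A + q)) with pseudocount q = 0.5 index units (applied only
inside the ratio). Confidence comes from the likelihood-ratio G-test on the
raw counts,

    G = 2 Σ_j c_j ln(c_j / e_j),   e_j = (c_A + c_B) · T_j / (T_A + T_B),

referred to χ²₁; proteins undetected in both groups are ND, not imputed.

**Directional pathway activation.** Against a gene set whose members carry
expected directions δ_k ∈ {+1, −1}, significant members contribute
s_k = sign(log₂fold_k) · δ_k and z = Σ s_k / √N. A pathway is *activated*
when z ≥ 0.5 and −log₁₀ p > 1.3 (hypergeometric enrichment p), *deactivated*
symmetrically; across proteomes a pathway showing both directions is *mixed*.

**Biomarker classing.** Human subjects are staged by MMSE (late < 16,
16 ≤ early ≤ 23, healthy ≥ 24). Per protein: one-way ANOVA then the three
pairwise t-tests at Bonferroni-adjusted α (0.05/3) flag up/down/ns; the flag
triple maps to class 1 (early-only elevation), class 2 (early change, late
indeterminate), class 3 (sustained elevation), or unclassified, through a
replaceable rule table.

**Panel selection.** Features common to all diagnostic groups are ranked by
two-sample t-test inside each training fold; a soft-margin linear SVM on the
top-k features is evaluated by 10 × 10-fold stratified cross-validation for
every panel size k; the best panel maximizes mean accuracy, and held-out
decision scores give the ROC curve and trapezoidal AUC (equal to the
Mann-Whitney statistic).

## Worked example

```python
import evpanel as ep

g, p = ep.g_test(20, 5, 46000, 45200)
print(f"G = {g:.3f}, p = {p:.4f}")

cfg = ep.SimConfig(n_proteins=2000, n_de=20, effect_log2=3.0,
                   mean_depth=1e5, seed=1)
exp, truth = ep.generate_psm_experiment(cfg, tissues=("hippocampus",), ages=(3,))
diff = ep.differential_analysis(exp, "hippocampus", 3)
hits = ep.filter_significant(diff, p_max=0.01, lfc_min=2.0)
print(f"{len(hits)} of {len(diff)} proteins significant; "
      f"planted recovered: {len(set(truth.de_proteins) & set(hits['protein_id']))}/20")

panel, ptruth = ep.generate_human_ev_panel(cfg)
print(ep.assign_classes(panel)["assigned_class"].value_counts().to_string())

universe = ep.common_intersection(
    {grp: list(ptruth.human_class_truth) for grp in ("healthy", "early", "late")})
perf = ep.accumulate_cv(panel, "healthy_vs_early", universe, seed=1)
print(f"best_k = {perf.best_k}, accuracy = {perf.per_k['accuracy'].max():.3f}, "
      f"AUC = {perf.auc:.3f}")
```

prints

```
G = 9.376, p = 0.0022
17 of 2000 proteins significant; planted recovered: 17/20
assigned_class
class1          6
class3          6
unclassified    2
best_k = 6, accuracy = 1.000, AUC = 1.000
```

Reading the output: a 20-vs-5 count split across ~4.6 × 10⁴-PSM groups is a
significant fourfold change (G ≈ 9.4, p ≈ 0.002). In the synthetic
experiment all 20 planted eightfold proteins reach p < 0.01, but three
low-abundance ones fall below the fold filter because the pseudocount shrinks
fold estimates when the normalized index is of order 1 — the fold estimate is
conservative exactly where counts are scarce. On the human panel, planted
class-1 and null proteins are recovered as-is; planted class-2 proteins
surface as class 3 because their "intermediate" late elevation (half the
early shift) is itself detectable at this effect size and cohort size (see
`docs/methods.md`). The strongly separated synthetic groups then give a
perfect cross-validated panel.

A full run (simulation → quantification → comparison → pathways →
biomarkers → panel CV, with a manifest of output hashes) is one command:

```sh
evpanel run --config run.yaml --outdir out/
```

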