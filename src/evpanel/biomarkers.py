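"""Human plasma-EV biomarker staging, group statistics, and class patterns.

Subjects are staged by mini-mental state examination (MMSE) score — late-stage
AD below 16, early stage 16-23, healthy 24 and above.  For each candidate
protein the three groups are compared by one-way ANOVA followed by the three
pairwise comparisons at Bonferroni-adjusted alpha (0.05/3), each flagged up /
down / ns from the sign of the mean difference.  The flag triple (healthy vs
early, healthy vs late, early vs late) is then mapped to an expression-pattern
class:

* class 1 — elevated in early-stage disease, back at healthy level late
  (he=up, hl=ns, with the early-vs-late comparison confirming the return);
* class 2 — changed in early-stage disease, late behavior indeterminate;
* class 3 — elevated in both early- and late-stage disease (he=up, hl=up);
* unclassified — no early-stage change.

The class-1/class-2 boundary is not uniquely determined by stage-wise
significance alone; the mapping lives in a replaceable rule table
(`DEFAULT_RULES`) whose default uses the early-vs-late comparison to separate
a demonstrated late return (class 1) from an indeterminate one (class 2), and
routes a *down*-going early change to class 2.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "stage_from_mmse",
    "select_candidates",
    "group_compare",
    "classify_pattern",
    "assign_classes",
    "ponceau_normalize",
    "read_panel",
    "load_table1",
    "load_flags_fixture",
    "DEFAULT_RULES",
]

STAGES = ("healthy", "early", "late")

#: Ordered (pattern, label) rules; the first pattern matching the (he, hl, el)
#: flag triple wins.  Omitted keys are wildcards.  This table is data: pass a
#: replacement to `classify_pattern` to change the class boundaries.
DEFAULT_RULES = (
    ({"he": "ns"}, "unclassified"),
    ({"he": "up", "hl": "up"}, "class3"),
    ({"he": "up", "hl": "ns", "el": "ns"}, "class2"),
    ({"he": "up", "hl": "ns"}, "class1"),  # el != ns: late demonstrably returns
    ({"he": "up", "hl": "down"}, "class1"),
    ({"he": "down"}, "class2"),
)


def stage_from_mmse(score: int) -> str:
    """Diagnostic stage from an MMSE score: late < 16, 16 <= early <= 23,
    healthy >= 24."""
    if not 0 <= score <= 30:
        raise ValueError(f"MMSE score {score} outside [0, 30]")
    if score < 16:
        return "late"
    if score <= 23:
        return "early"
    return "healthy"


def select_candidates(
    ev_tables: dict[str, pd.DataFrame], p_max: float = 0.05
) -> pd.DataFrame:
    """Biomarker candidates: proteins significant in at least one plasma-EV
    contrast.

    ``ev_tables`` maps age labels (e.g. ``"3mo"``, ``"6mo"``) to EV
    differential tables.  Returns one row per candidate with each age's
    log2 fold and p-value, ordered by the minimum p over ages (ties by id).
    """
    if len(ev_tables) < 1:
        raise ValueError("at least one EV differential table required")
    frames = []
    for age, table in ev_tables.items():
        quantified = table[table["status"] == "quantified"]
        frames.append(
            quantified[["protein_id", "log2_fold", "p_value"]]
            .rename(columns={"log2_fold": f"log2_fold_{age}", "p_value": f"p_{age}"})
            .set_index("protein_id")
        )
    joined = pd.concat(frames, axis=1)
    p_cols = [c for c in joined.columns if c.startswith("p_")]
    keep = (joined[p_cols] < p_max).any(axis=1)
    out = joined[keep].copy()
    out["min_p"] = out[p_cols].min(axis=1)
    out.index.name = "protein_id"
    out = out.reset_index().sort_values(["min_p", "protein_id"]).reset_index(drop=True)
    return out


def _pair_flag(a: np.ndarray, b: np.ndarray, alpha_adj: float, equal_var: bool) -> str:
    """up/down/ns for group b versus group a at the adjusted alpha."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return "ns"  # identical values everywhere: no evidence of change
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    if np.isnan(p) or p >= alpha_adj:
        return "ns"
    return "up" if np.mean(b) > np.mean(a) else "down"


def group_compare(
    panel: pd.DataFrame,
    protein: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict:
    """Three-group comparison of one protein: ANOVA plus Bonferroni pairwise
    flags.

    Returns ``{"anova_p": p, "he": ..., "hl": ..., "el": ...}`` where the
    pairwise flags (healthy-vs-early, healthy-vs-late, early-vs-late) are
    two-sample t-tests (pooled variance by default, Welch with
    ``equal_var=False``) at alpha adjusted for the family of pairwise
    comparisons; direction is the sign of (second group mean - first group
    mean).  With only two groups present the single comparison runs
    unadjusted.
    """
    groups = {g: panel.loc[panel["group"] == g, protein].to_numpy(dtype=float)
              for g in STAGES if g in set(panel["group"])}
    if len(groups) < 2:
        raise ValueError("need at least two diagnostic groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")

    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        anova_p = 1.0
    elif len(groups) == 2:
        anova_p = float(stats.ttest_ind(*groups.values(), equal_var=equal_var).pvalue)
    else:
        anova_p = float(stats.f_oneway(*groups.values()).pvalue)

    pairs = [("he", "healthy", "early"), ("hl", "healthy", "late"),
             ("el", "early", "late")]
    pairs = [(k, a, b) for k, a, b in pairs if a in groups and b in groups]
    alpha_adj = alpha / len(pairs)
    out = {"anova_p": anova_p}
    for key, a, b in pairs:
        out[key] = _pair_flag(groups[a], groups[b], alpha_adj, equal_var)
    return out


def classify_pattern(flags: dict, rules=DEFAULT_RULES) -> str:
    """Expression-pattern class from the (he, hl, el) flag triple.

    The first rule whose pattern matches wins; the default table implements
    the class definitions in the module docstring.
    """
    for key in ("he", "hl", "el"):
        if flags.get(key) not in ("up", "down", "ns"):
            raise ValueError(f"incomplete or invalid flags: missing/invalid {key!r}")
    for pattern, label in rules:
        if all(flags[k] == v for k, v in pattern.items()):
            return label
    return "unclassified"


def assign_classes(
    panel: pd.DataFrame,
    proteins: list[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    rules=DEFAULT_RULES,
) -> pd.DataFrame:
    """Flags and class per protein over a human panel table.

    Returns columns protein_id, anova_p, he, hl, el, assigned_class.
    """
    if proteins is None:
        proteins = [c for c in panel.columns if c not in ("subject_id", "group", "mmse")]
    rows = []
    for prot in proteins:
        flags = group_compare(panel, prot, alpha=alpha, equal_var=equal_var)
        rows.append(
            {
                "protein_id": prot,
                "anova_p": flags["anova_p"],
                "he": flags["he"],
                "hl": flags["hl"],
                "el": flags["el"],
                "assigned_class": classify_pattern(flags, rules=rules),
            }
        )
    return pd.DataFrame(rows)


def ponceau_normalize(raw_density: float, loading_density: float) -> float:
    """Band density normalized to the lane's Ponceau S total-protein stain."""
    if loading_density <= 0 or raw_density <= 0:
        raise ValueError("densities must be positive")
    return raw_density / loading_density


def read_panel(path, validate_stage: bool = True) -> pd.DataFrame:
    """Load a human panel TSV (subject_id, group, mmse, then protein columns)
    and validate MMSE range, group/stage consistency, and positive
    intensities."""
    panel = pd.read_csv(path, sep="\t")
    return validate_panel(panel, validate_stage=validate_stage)


def validate_panel(panel: pd.DataFrame, validate_stage: bool = True) -> pd.DataFrame:
    for col in ("subject_id", "group", "mmse"):
        if col not in panel.columns:
            raise ValueError(f"panel missing required column {col!r}")
    if not panel["mmse"].between(0, 30).all():
        raise ValueError("MMSE scores outside [0, 30]")
    if validate_stage:
        derived = panel["mmse"].map(stage_from_mmse)
        bad = panel.loc[derived != panel["group"], "subject_id"].tolist()
        if bad:
            raise ValueError(f"group label inconsistent with MMSE stage: {bad}")
    protein_cols = [c for c in panel.columns if c not in ("subject_id", "group", "mmse")]
    if protein_cols and (panel[protein_cols] <= 0).any().any():
        raise ValueError("intensities must be positive")
    return panel


def _fixture(name: str):
    return resources.files("evpanel.fixtures").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The packaged 21-candidate mouse differential table (log2 fold and p for
    the EV, hippocampal and cortical contrasts at both ages), as transcribed;
    undetected cells are NaN with the paired status column 'ND'."""
    df = pd.read_csv(_fixture("table1.tsv"), sep="\t", na_values=["ND"])
    return df


def table1_ev_tables() -> dict[str, pd.DataFrame]:
    """The packaged candidate table reshaped into per-age EV differential
    tables suitable for `select_candidates`."""
    df = load_table1()
    out = {}
    for age, prefix in (("3mo", "ev3"), ("6mo", "ev6")):
        sub = pd.DataFrame(
            {
                "protein_id": df["gene_id"],
                "log2_fold": df[f"{prefix}_lfc"],
                "p_value": df[f"{prefix}_p"],
            }
        )
        sub["status"] = np.where(sub["p_value"].notna(), "quantified", "ND")
        out[age] = sub
    return out


def load_flags_fixture() -> pd.DataFrame:
    """The packaged 14-candidate pairwise-outcome table (he/hl/el flags) for
    the human plasma-EV validation panel."""
    return pd.read_csv(_fixture("flags.tsv"), sep="\t")
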