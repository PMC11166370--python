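"""Spectral-count quantification: cumulative PSM indices, fold changes, G-test.

Label-free quantification by spectral counting compares, for each protein, the
number of peptide-spectrum matches (PSMs) accumulated across technical
replicates between two experimental groups.  Counts are normalized to each
group's total PSM yield (the *normalized PSM index*, per 10^4 PSM by default),
fold changes are taken on the normalized indices, and statistical confidence
comes from a likelihood-ratio G-test on the raw cumulative counts, referred to
a chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PsmExperiment",
    "accumulate_psm",
    "normalize_psm_index",
    "g_test",
    "differential_analysis",
    "filter_significant",
    "read_psm_tables",
]

#: Default normalization scale: indices are reported per 10^4 total PSM.
DEFAULT_SCALE = 1e4
#: Default pseudocount, in normalized-index units, applied only inside the
#: fold-change ratio (never to the counts entering the G-test) so that
#: proteins undetected in one group still get a finite log2 fold.
DEFAULT_PSEUDOCOUNT = 0.5

META_COLUMNS = ("tissue", "age_months", "genotype", "replicate_id")


@dataclass
class PsmExperiment:
    """Protein x sample PSM count matrix with per-sample design metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, indexed by unique protein id, one column
        per sample.
    meta : pandas.DataFrame
        Indexed by sample id; must carry ``tissue``, ``age_months``,
        ``genotype`` and ``replicate_id`` for every sample in ``counts``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("protein ids must be unique")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("PSM counts must be integers")
            self.counts = self.counts.round().astype(int)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("PSM counts must be non-negative")
        if (arr.sum(axis=0) <= 0).any():
            bad = self.counts.columns[arr.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total PSM: {bad}")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
            if self.meta.loc[list(self.counts.columns), col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing values")

    def select(self, **criteria) -> list[str]:
        """Sample ids whose metadata match every ``column=value`` criterion."""
        mask = pd.Series(True, index=self.meta.index)
        for col, value in criteria.items():
            if col not in self.meta.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            mask &= self.meta[col] == value
        ids = [s for s in self.counts.columns if mask.get(s, False)]
        return ids


def accumulate_psm(exp: PsmExperiment, **criteria) -> tuple[pd.Series, int]:
    """Cumulative PSM count per protein over the selected samples.

    Sums counts across every sample matching the metadata ``criteria``
    (e.g. ``tissue="hippocampus", age_months=3, genotype="WT"``) — the pooled
    count over technical replicates — and returns it together with the group
    total (the sum over all proteins).
    """
    samples = exp.select(**criteria)
    if not samples:
        raise ValueError(f"no samples match selector {criteria!r}")
    c = exp.counts[samples].sum(axis=1)
    return c, int(c.sum())


def normalize_psm_index(c, T, scale: float = DEFAULT_SCALE):
    """Normalized PSM index: ``scale * c / T`` (default per 10^4 total PSM)."""
    if np.any(np.asarray(T) <= 0):
        raise ValueError("group total T must be positive")
    return scale * np.asarray(c, dtype=float) / np.asarray(T, dtype=float)


def _xlogy(x, y):
    # 0 * ln(0) == 0 convention for empty cells
    return np.where(x > 0, x * np.log(np.where(x > 0, y, 1.0)), 0.0)


def g_test(c_a, c_b, t_a, t_b, williams: bool = False):
    """Likelihood-ratio G-test for a count split against group totals.

    Tests whether the two cumulative counts ``c_a``, ``c_b`` are consistent
    with a common underlying proportion of the group totals ``t_a``, ``t_b``:

        G = 2 * sum_j c_j * ln(c_j / e_j),   e_j = (c_a + c_b) * t_j / (t_a + t_b)

    with the convention ``0 * ln 0 = 0``.  The p-value is the upper tail of
    chi-square with 1 degree of freedom.  ``williams=True`` applies the
    Williams small-sample correction ``G / (1 + 1/(2*(c_a+c_b)))`` (off by
    default).

    Accepts scalars or equal-length arrays; returns ``(G, p)``.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if np.any(t_a <= 0) or np.any(t_b <= 0):
        raise ValueError("group totals must be positive")
    if np.any(c_a > t_a) or np.any(c_b > t_b):
        raise ValueError("cumulative count exceeds its group total")
    if np.any(c_a + c_b <= 0):
        raise ValueError("c_a + c_b must be positive (undetected proteins are ND)")
    rate = (c_a + c_b) / (t_a + t_b)
    e_a = rate * t_a
    e_b = rate * t_b
    g = 2.0 * (_xlogy(c_a, c_a / e_a) + _xlogy(c_b, c_b / e_b))
    g = np.maximum(g, 0.0)  # clip -0.0 / rounding at the boundary
    if williams:
        g = g / (1.0 + 1.0 / (2.0 * (c_a + c_b)))
    p = stats.chi2.sf(g, df=1)
    if g.ndim == 0:
        return float(g), float(p)
    return g, p


def differential_analysis(
    exp: PsmExperiment,
    tissue: str,
    age_months: int,
    *,
    group_a: str = "WT",
    group_b: str = "5xFAD",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale: float = DEFAULT_SCALE,
    williams: bool = False,
) -> pd.DataFrame:
    """Per-protein WT-vs-5xFAD contrast within one tissue x age stratum.

    For each protein: technical replicates are pooled by summation into
    cumulative counts, indices are normalized per group, the log2 fold is
    ``log2((i_B + q) / (i_A + q))`` with pseudocount ``q`` applied only to the
    normalized indices, and the G-test runs on the raw cumulative counts.
    Proteins undetected in both groups get ``status == "ND"`` and NaN
    statistics.  Rows are ordered by p ascending, then \\|log2 fold\\|
    descending, then protein id.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    c_a, t_a = accumulate_psm(exp, tissue=tissue, age_months=age_months, genotype=group_a)
    c_b, t_b = accumulate_psm(exp, tissue=tissue, age_months=age_months, genotype=group_b)

    i_a = normalize_psm_index(c_a, t_a, scale)
    i_b = normalize_psm_index(c_b, t_b, scale)
    log2_fold = np.log2((i_b + pseudocount) / (i_a + pseudocount))

    detected = (c_a + c_b) > 0
    g = np.full(len(c_a), np.nan)
    p = np.full(len(c_a), np.nan)
    if detected.any():
        g_det, p_det = g_test(
            c_a[detected], c_b[detected], t_a, t_b, williams=williams
        )
        g[detected.to_numpy()] = g_det
        p[detected.to_numpy()] = p_det

    out = pd.DataFrame(
        {
            "protein_id": c_a.index,
            f"c_{group_a}": c_a.to_numpy(),
            f"c_{group_b}": c_b.to_numpy(),
            f"i_{group_a}": i_a,
            f"i_{group_b}": i_b,
            "log2_fold": np.where(detected, log2_fold, np.nan),
            "G": g,
            "p_value": p,
            "status": np.where(detected, "quantified", "ND"),
        }
    )
    out = out.sort_values(
        by=["p_value", "log2_fold", "protein_id"],
        key=lambda s: -s.abs() if s.name == "log2_fold" else s,
        na_position="last",
    ).reset_index(drop=True)
    out.attrs["totals"] = {group_a: t_a, group_b: t_b}
    return out


def filter_significant(
    records: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.0,
    direction: str = "any",
) -> pd.DataFrame:
    """Quantified records with ``p < p_max`` (strict) and ``|log2 fold| >= lfc_min``.

    ``direction`` restricts the fold-change sign: ``"up"`` keeps positive
    folds, ``"down"`` negative, ``"any"`` both.  Input order is preserved.
    """
    if direction not in ("up", "down", "any"):
        raise ValueError("direction must be 'up', 'down' or 'any'")
    quantified = records[records["status"] == "quantified"]
    keep = (quantified["p_value"] < p_max) & (quantified["log2_fold"].abs() >= lfc_min)
    if direction == "up":
        keep &= quantified["log2_fold"] > 0
    elif direction == "down":
        keep &= quantified["log2_fold"] < 0
    return quantified[keep]


def read_psm_tables(counts_path, meta_path) -> PsmExperiment:
    """Load a PSM experiment from a counts TSV (first column = protein id)
    and a metadata TSV (columns: sample_id, tissue, age_months, genotype,
    replicate_id)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return PsmExperiment(counts=counts, meta=meta)
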