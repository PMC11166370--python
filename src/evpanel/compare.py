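"""Cross-proteome comparison: altered protein sets, recapitulation, age trends.

The three proteomes (hippocampus, cortex, plasma EV) at two ages yield one
differential table per stratum.  Proteins passing the significance filter
(p < 0.05 and |log2 fold| >= 5 by default) form each stratum's altered set;
proteins shared between two strata's altered sets are *recapitulated*.
Proteins with status ND in a stratum are absent from that stratum's set.
"""

from __future__ import annotations

import pandas as pd

from .quant import filter_significant

__all__ = [
    "altered_protein_sets",
    "recapitulation",
    "age_contrast",
    "load_altered_sets_fixture",
]


def load_altered_sets_fixture() -> dict[str, pd.DataFrame]:
    """The packaged per-stratum altered-protein lists.

    Only the cross-stratum intersection members (the recapitulated proteins)
    are real; the per-stratum filler proteins and all fold values are
    synthetic stand-ins, since full per-stratum membership is not available —
    so only set algebra on the intersections is meaningful.
    """
    from importlib import resources

    path = resources.files("evpanel.fixtures").joinpath("altered_sets_synthetic.tsv")
    df = pd.read_csv(path, sep="\t")
    return {s: sub[["protein_id", "log2_fold"]].reset_index(drop=True)
            for s, sub in df.groupby("stratum")}


def altered_protein_sets(
    tables: dict[str, pd.DataFrame], p_max: float = 0.05, lfc_min: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Per-stratum altered sets: quantified proteins with p < p_max and
    |log2 fold| >= lfc_min, either direction.

    ``tables`` maps stratum labels (e.g. ``"hippocampus_3mo"``) to
    differential tables; returns the same mapping onto two-column frames
    (protein_id, log2_fold).
    """
    if not tables:
        raise ValueError("at least one differential table required")
    out = {}
    for stratum, table in tables.items():
        kept = filter_significant(table, p_max=p_max, lfc_min=lfc_min, direction="any")
        out[stratum] = kept[["protein_id", "log2_fold"]].reset_index(drop=True)
    return out


def recapitulation(set_1: pd.DataFrame, set_2: pd.DataFrame) -> pd.DataFrame:
    """Proteins present in both altered sets, with each set's log2 fold.

    Returns columns (protein_id, log2_fold_1, log2_fold_2), ordered
    lexicographically by protein id.  An empty intersection is a valid
    result, not an error.
    """
    merged = pd.merge(
        set_1[["protein_id", "log2_fold"]],
        set_2[["protein_id", "log2_fold"]],
        on="protein_id",
        suffixes=("_1", "_2"),
    )
    return merged.sort_values("protein_id").reset_index(drop=True)


def age_contrast(
    table_3mo: pd.DataFrame,
    table_6mo: pd.DataFrame,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Join 3- and 6-month differential tables of one tissue on protein id.

    Reports both ages' log2 folds and p-values plus a concordance flag:
    ``concordant`` (same fold sign at both ages), ``discordant`` (opposite),
    or ``single_age`` (quantified at only one age).  If both tables carry a
    ``tissue`` attribute (set by the pipeline) they must agree.
    """
    t3 = table_3mo.attrs.get("tissue")
    t6 = table_6mo.attrs.get("tissue")
    if t3 is not None and t6 is not None and t3 != t6:
        raise ValueError(f"tissue mismatch: {t3!r} vs {t6!r}")

    cols = ["protein_id", "log2_fold", "p_value", "status"]
    merged = pd.merge(
        table_3mo[cols], table_6mo[cols], on="protein_id",
        how="outer", suffixes=("_3mo", "_6mo"),
    )

    def flag(row):
        q3 = row["status_3mo"] == "quantified"
        q6 = row["status_6mo"] == "quantified"
        if q3 and q6:
            if row["log2_fold_3mo"] * row["log2_fold_6mo"] > 0:
                return "concordant"
            if row["log2_fold_3mo"] * row["log2_fold_6mo"] < 0:
                return "discordant"
            return "concordant"  # a zero fold at either age cannot disagree
        return "single_age"

    merged["concordance"] = merged.apply(flag, axis=1)
    return merged.sort_values("protein_id").reset_index(drop=True)
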