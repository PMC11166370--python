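"""Directional pathway activation scoring over differential-abundance results.

Each pathway is a user-supplied gene set in which every member carries an
expected direction of change under pathway activation (+1 or -1).  Two
statistics are computed against a differential table:

* an enrichment p-value — the hypergeometric upper tail for the overlap
  between the pathway and the significant protein set (a one-sided Fisher
  exact test), and
* an activation z-score — the directional consistency of the significant
  members, ``z = (sum_k s_k) / sqrt(N)`` where ``s_k = sign(log2 fold_k) *
  expected_direction_k``, so a fully consistent pathway of N members scores
  ``sqrt(N)``.

A pathway is called *activated* when ``z >= z_cut`` and ``-log10 p > logp_cut``
(defaults 0.5 and 1.3, i.e. p < 0.05), *deactivated* symmetrically, otherwise
*no_call*.  Across strata (tissue x age proteomes) a pathway whose non-no_call
labels all agree is summarized as activated or deactivated; one showing both
directions is *mixed*; pathways never called anywhere are excluded from the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayDefinition",
    "enrichment_p",
    "activation_z",
    "classify_pathway",
    "score_pathways",
    "cross_summary",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """Named gene set with a per-member expected activation direction."""

    name: str
    members: tuple[str, ...]
    directions: tuple[int, ...]  # +1 / -1 per member

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(f"pathway {self.name!r} needs >= 2 members")
        if len(self.directions) != len(self.members):
            raise ValueError(f"pathway {self.name!r}: one direction per member required")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError(f"pathway {self.name!r}: directions must be +1 or -1")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pathway {self.name!r}: duplicate members")

    @property
    def direction_of(self) -> dict[str, int]:
        return dict(zip(self.members, self.directions))


def enrichment_p(overlap: int, set_size: int, n_sig: int, universe: int) -> float:
    """Hypergeometric upper-tail P(X >= overlap) for the pathway/significant
    overlap, X ~ Hypergeom(universe, n_sig, set_size)."""
    if not (0 <= overlap <= min(set_size, n_sig) and max(set_size, n_sig) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, set_size={set_size}, "
            f"n_sig={n_sig}, universe={universe}"
        )
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, n_sig, set_size))


def activation_z(
    diff: pd.DataFrame, pathway: PathwayDefinition, p_max: float = 0.05
) -> tuple[int, float]:
    """Overlap size N and directional z over significant pathway members.

    Members with a quantified record at ``p < p_max`` and a non-zero fold
    contribute ``s_k = sign(log2 fold) * expected_direction``; z is their sum
    over sqrt(N).  Returns ``(0, nan)`` when no member is significant.
    """
    quantified = diff[diff["status"] == "quantified"]
    sig = quantified[quantified["p_value"] < p_max].set_index("protein_id")
    s = []
    for member, direction in zip(pathway.members, pathway.directions):
        if member in sig.index:
            fold = sig.at[member, "log2_fold"]
            if fold != 0:
                s.append(np.sign(fold) * direction)
    n = len(s)
    if n == 0:
        return 0, float("nan")
    return n, float(np.sum(s) / np.sqrt(n))


def classify_pathway(
    z: float, p: float, z_cut: float = 0.5, logp_cut: float = 1.3
) -> str:
    """Call label from the activation z and enrichment p."""
    if np.isnan(z) or -np.log10(p) <= logp_cut:
        return "no_call"
    if z >= z_cut:
        return "activated"
    if z <= -z_cut:
        return "deactivated"
    return "no_call"


def score_pathways(
    diff: pd.DataFrame,
    pathways: list[PathwayDefinition],
    p_max: float = 0.05,
    z_cut: float = 0.5,
    logp_cut: float = 1.3,
) -> pd.DataFrame:
    """Activation calls for every pathway against one differential table.

    The enrichment universe is the quantified protein set of the table; the
    significant set is its ``p < p_max`` subset.  Returns one row per pathway:
    name, N, z, enrichment_p, label.
    """
    quantified = diff[diff["status"] == "quantified"]
    universe_ids = set(quantified["protein_id"])
    sig_ids = set(quantified.loc[quantified["p_value"] < p_max, "protein_id"])
    rows = []
    for pw in pathways:
        members_in = [m for m in pw.members if m in universe_ids]
        overlap = sum(1 for m in members_in if m in sig_ids)
        p_enr = enrichment_p(overlap, len(members_in), len(sig_ids), len(universe_ids))
        n, z = activation_z(diff, pw, p_max=p_max)
        label = classify_pathway(z, p_enr, z_cut=z_cut, logp_cut=logp_cut)
        rows.append(
            {"pathway": pw.name, "N": n, "z": z, "enrichment_p": p_enr, "label": label}
        )
    return pd.DataFrame(rows)


def cross_summary(labels: pd.DataFrame) -> dict:
    """Activated / deactivated / mixed accounting across strata.

    ``labels`` is pathways x strata of call labels.  Per pathway: *activated*
    if at least one stratum calls it and every call agrees on activation;
    *deactivated* symmetrically; *mixed* if both directions occur; pathways
    with only no_call are excluded from the denominator.  Percentages are
    reported to one decimal.
    """
    if labels.empty:
        raise ValueError("empty label table")
    counts = {"activated": 0, "deactivated": 0, "mixed": 0}
    for _, row in labels.iterrows():
        calls = {v for v in row if v in ("activated", "deactivated")}
        if not calls:
            continue
        if calls == {"activated"}:
            counts["activated"] += 1
        elif calls == {"deactivated"}:
            counts["deactivated"] += 1
        else:
            counts["mixed"] += 1
    denom = sum(counts.values())
    percentages = {
        k: round(100.0 * v / denom, 1) if denom else float("nan")
        for k, v in counts.items()
    }
    return {"counts": counts, "n_pathways": denom, "percentages": percentages}


def read_gmt(path) -> list[PathwayDefinition]:
    """Read pathways from GMT: name, direction string of '+'/'-' per member,
    then member ids."""
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *members = line.split("\t")
            signs = desc.strip()
            if len(signs) != len(members) or any(c not in "+-" for c in signs):
                raise ValueError(
                    f"pathway {name!r}: description must be a '+'/'-' string, "
                    "one sign per member"
                )
            directions = tuple(1 if c == "+" else -1 for c in signs)
            pathways.append(PathwayDefinition(name, tuple(members), directions))
    return pathways


def write_gmt(pathways: list[PathwayDefinition], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            signs = "".join("+" if d > 0 else "-" for d in pw.directions)
            fh.write("\t".join([pw.name, signs, *pw.members]) + "\n")
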