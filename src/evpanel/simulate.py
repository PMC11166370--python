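"""Synthetic data with planted truth for every pipeline stage.

No raw mass-spectrometry or densitometry data accompany the study design this
package implements, so the generator emulates its structure: multi-tissue PSM
count experiments with planted differentially abundant proteins, directional
pathway definitions (coherent or random), and a three-group human plasma-EV
panel with planted class-1/2/3 expression patterns and MMSE scores.

Sampling models are deliberately simple stand-ins, labelled as such in the
truth record:

* PSM counts are Poisson with a per-sample depth factor (lognormal, sigma
  0.1 on the log scale) and per-protein abundances drawn log-uniformly over
  two orders of magnitude — the simplest model under which the G-test's
  multinomial assumptions approximately hold, so calibration is testable.
* Human band intensities are lognormal (sigma 0.4 on the log scale) around
  class-specific geometric means; the planted standardized shift d moves the
  log-mean by d * sigma.  Class 2's late mean sits midway between the healthy
  and early means.
* MMSE scores are uniform over each group's admissible integer interval
  (healthy 24-30, early 16-23, late 0-15).

Random streams are split per table (counts / human panel / pathways), so
adding pathways never perturbs count generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pathways import PathwayDefinition
from .quant import PsmExperiment

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "generate_psm_experiment",
    "generate_human_ev_panel",
    "generate_pathway_sets",
    "write_experiment",
    "HUMAN_PANEL_CLASSES",
]

TISSUES = ("hippocampus", "cortex", "plasma_EV")
AGES = (3, 6)
GENOTYPES = ("WT", "5xFAD")

#: Default human panel: the 14 validated candidates with their planted
#: expression-pattern classes (class 1 early-only elevation; class 2 early
#: change, late indeterminate; class 3 sustained elevation; null no change).
HUMAN_PANEL_CLASSES = {
    "A2M": "class1", "CKM": "class1", "FLNA": "class1", "ITGA2B": "class1",
    "ORM2": "class1", "PLTP": "class1",
    "HP": "class2", "QSOX1": "class2", "TGM2": "class2",
    "FLNC": "class3", "HSP70": "class3", "MAN2B1": "class3",
    "PF4": "null", "TLN1": "null",
}

MMSE_RANGES = {"healthy": (24, 30), "early": (16, 23), "late": (0, 15)}


@dataclass
class SimConfig:
    """Generator settings; identical seeds give byte-identical tables."""

    n_proteins: int = 2000
    n_tech_replicates: int = 3
    mean_depth: float = 1e5
    n_de: int = 20
    effect_log2: float = 3.0
    human_n_per_group: int = 40
    human_effect_d: float = 3.0
    human_sigma: float = 0.4
    depth_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0 or self.n_tech_replicates <= 0:
            raise ValueError("protein and replicate counts must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.n_de <= self.n_proteins:
            raise ValueError("n_de must lie in [0, n_proteins]")
        if self.human_n_per_group < 3:
            raise ValueError(
                "human_n_per_group < 3: pairwise group tests are undefined"
            )


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying each generated table."""

    de_proteins: dict[str, float] = field(default_factory=dict)  # id -> log2 fold
    human_class_truth: dict[str, str] = field(default_factory=dict)
    human_expected_class: dict[str, str] = field(default_factory=dict)
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_coherence: dict[str, str] = field(default_factory=dict)
    notes: str = (
        "sampling distributions are synthetic stand-ins; no noise or depth "
        "characteristics of the emulated MS runs are available"
    )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _streams(seed: int):
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_psm_experiment(
    config: SimConfig,
    tissues: tuple[str, ...] = TISSUES,
    ages: tuple[int, ...] = AGES,
) -> tuple[PsmExperiment, SimulationTruth]:
    """PSM count experiment over tissues x ages x genotypes x replicates.

    The first ``n_de`` proteins are planted with a 5xFAD/WT generating-mean
    ratio of ``2**effect_log2`` in every stratum; all other proteins have
    ratio 1.  Counts are Poisson around abundance x depth-factor means.
    """
    rng, _, _ = _streams(config.seed)
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    # long-tailed relative abundances, fixed across tissues
    abundance = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=n))
    fold = np.ones(n)
    fold[: config.n_de] = 2.0 ** config.effect_log2

    truth = SimulationTruth(
        de_proteins={ids[i]: config.effect_log2 for i in range(config.n_de)}
    )

    columns, data, meta_rows = [], [], []
    base_share = abundance / abundance.sum()
    for tissue in tissues:
        for age in ages:
            for genotype in GENOTYPES:
                mean = base_share * (fold if genotype == "5xFAD" else 1.0)
                for rep in range(1, config.n_tech_replicates + 1):
                    depth = config.mean_depth * rng.lognormal(0.0, config.depth_sigma)
                    lam = mean * depth
                    data.append(rng.poisson(lam))
                    sample = f"{tissue}_{age}mo_{genotype}_r{rep}"
                    columns.append(sample)
                    meta_rows.append(
                        {
                            "sample_id": sample,
                            "tissue": tissue,
                            "age_months": age,
                            "genotype": genotype,
                            "replicate_id": rep,
                        }
                    )
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(ids, name="protein_id"), columns=columns
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return PsmExperiment(counts=counts, meta=meta), truth


def generate_human_ev_panel(
    config: SimConfig,
    protein_classes: dict[str, str] = HUMAN_PANEL_CLASSES,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Three-group human panel with planted class-1/2/3 expression patterns.

    Per protein, the log-scale group means follow its planted class with
    shift ``delta = human_effect_d * human_sigma``: class 1 is elevated early
    only; class 2 elevated early with the late mean midway back; class 3
    elevated in both early and late; null proteins share one mean.  MMSE is
    uniform over each group's admissible integers; intensities are lognormal.
    """
    _, rng, _ = _streams(config.seed)
    delta = config.human_effect_d * config.human_sigma
    shift = {
        "class1": {"healthy": 0.0, "early": delta, "late": 0.0},
        "class2": {"healthy": 0.0, "early": delta, "late": delta / 2.0},
        "class3": {"healthy": 0.0, "early": delta, "late": delta},
        "null": {"healthy": 0.0, "early": 0.0, "late": 0.0},
    }
    truth = SimulationTruth(human_class_truth=dict(protein_classes))
    # Expected downstream assignment at full power: a pairwise flag is
    # up/down whenever the generating means differ.  Note the planted
    # class-2 pattern (late mean midway) is itself a real late elevation,
    # so with d large enough to detect delta/2 it maps to class 3.
    from .biomarkers import classify_pattern

    for protein, cls in protein_classes.items():
        mu = shift[cls]
        if config.human_effect_d == 0:
            truth.human_expected_class[protein] = "unclassified"
            continue

        def _flag(a, b):
            return "ns" if mu[a] == mu[b] else ("up" if mu[b] > mu[a] else "down")

        flags = {"he": _flag("healthy", "early"), "hl": _flag("healthy", "late"),
                 "el": _flag("early", "late")}
        truth.human_expected_class[protein] = classify_pattern(flags)

    rows = []
    for group in ("healthy", "early", "late"):
        lo, hi = MMSE_RANGES[group]
        for i in range(config.human_n_per_group):
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "mmse": int(rng.integers(lo, hi + 1)),
                }
            )
    panel = pd.DataFrame(rows)
    for protein, cls in protein_classes.items():
        mu = {g: shift[cls][g] for g in MMSE_RANGES}
        truth.group_means[protein] = {g: float(np.exp(m)) for g, m in mu.items()}
        log_means = panel["group"].map(mu).to_numpy(dtype=float)
        panel[protein] = np.exp(
            rng.normal(log_means, config.human_sigma, size=len(panel))
        )
    return panel, truth


def generate_pathway_sets(
    n_pathways: int,
    size_range: tuple[int, int],
    truth: SimulationTruth,
    seed: int,
    protein_ids: list[str] | None = None,
    coherent_fraction: float = 0.5,
) -> list[PathwayDefinition]:
    """Directional pathway definitions, some coherent with the planted truth.

    Coherent pathways draw their members from the planted differential
    proteins with expected directions matching the planted fold signs; random
    pathways draw members uniformly with random directions.  Coherence labels
    are recorded in ``truth.pathway_coherence``.
    """
    lo, hi = size_range
    if lo > hi or lo < 2:
        raise ValueError("size_range must be a non-empty interval within [2, n]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    de_ids = sorted(truth.de_proteins)
    if protein_ids is None:
        protein_ids = de_ids
    n_coherent = int(round(coherent_fraction * n_pathways)) if de_ids else 0
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        coherent = i < n_coherent and size <= len(de_ids)
        if coherent:
            members = list(rng.choice(de_ids, size=size, replace=False))
            directions = tuple(
                1 if truth.de_proteins[m] >= 0 else -1 for m in members
            )
            kind = "coherent"
        else:
            members = list(rng.choice(protein_ids, size=size, replace=False))
            directions = tuple(rng.choice([-1, 1], size=size))
            kind = "random"
        name = f"PW_{kind}_{i:03d}"
        pathways.append(PathwayDefinition(name, tuple(members), directions))
        truth.pathway_coherence[name] = kind
    return pathways


def write_experiment(exp: PsmExperiment, outdir, prefix: str = "psm") -> None:
    """Write counts and metadata as tab-separated tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.counts.to_csv(outdir / f"{prefix}_counts.tsv", sep="\t")
    exp.meta.to_csv(outdir / f"{prefix}_meta.tsv", sep="\t", index_label="sample_id")
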