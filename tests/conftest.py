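import numpy as np
import pandas as pd
import pytest

from evpanel.quant import PsmExperiment
from evpanel.simulate import SimConfig, generate_human_ev_panel, generate_psm_experiment


def make_experiment(counts: dict, meta_rows: list[dict]) -> PsmExperiment:
    """Hand-built experiment: counts maps sample id -> list of per-protein counts."""
    n = len(next(iter(counts.values())))
    ids = [f"prot{i}" for i in range(n)]
    frame = pd.DataFrame(counts, index=pd.Index(ids, name="protein_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return PsmExperiment(counts=frame, meta=meta)


@pytest.fixture(scope="session")
def small_experiment():
    """One hippocampus/3mo stratum, two genotypes x two replicates, 4 proteins."""
    meta = [
        {"sample_id": s, "tissue": "hippocampus", "age_months": 3,
         "genotype": g, "replicate_id": r}
        for s, g, r in [("wt1", "WT", 1), ("wt2", "WT", 2),
                        ("tg1", "5xFAD", 1), ("tg2", "5xFAD", 2)]
    ]
    counts = {
        "wt1": [3, 20, 0, 0],
        "wt2": [7, 20, 0, 0],
        "tg1": [2, 5, 6, 0],
        "tg2": [3, 5, 6, 0],
    }
    return make_experiment(counts, meta)


@pytest.fixture(scope="session")
def sim_experiment():
    """Moderate synthetic experiment with planted differential proteins."""
    cfg = SimConfig(n_proteins=400, n_de=8, effect_log2=3.0, mean_depth=5e4,
                    n_tech_replicates=3, seed=11)
    exp, truth = generate_psm_experiment(cfg, tissues=("hippocampus",), ages=(3,))
    return cfg, exp, truth


@pytest.fixture(scope="session")
def sim_panel():
    """Synthetic human panel at the default planted conditions (d=3, n=40)."""
    cfg = SimConfig(seed=7)
    panel, truth = generate_human_ev_panel(cfg)
    return cfg, panel, truth


def planted_panel(informative, noise, d=1.5, n_per_group=40, seed=0) -> pd.DataFrame:
    """Healthy-vs-early cohort with planted informative and pure-noise features."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, mmse_rng in (("healthy", (24, 30)), ("early", (16, 23))):
        for i in range(n_per_group):
            rows.append({"subject_id": f"{group}_{i}", "group": group,
                         "mmse": int(rng.integers(*mmse_rng))})
    panel = pd.DataFrame(rows)
    shift = np.where(panel["group"] == "early", d, 0.0)
    for name in informative:
        panel[name] = rng.normal(0, 1, len(panel)) + shift
    for name in noise:
        panel[name] = rng.normal(0, 1, len(panel))
    return panel


def separable_panel(n_per_group=40, d=6.0, n_features=5, seed=0) -> pd.DataFrame:
    """Two well-separated Gaussian groups posing as healthy vs early."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, mmse_rng, shift in (("healthy", (24, 30), 0.0),
                                   ("early", (16, 23), d)):
        for i in range(n_per_group):
            rows.append({"subject_id": f"{group}_{i}", "group": group,
                         "mmse": int(rng.integers(*mmse_rng))})
    panel = pd.DataFrame(rows)
    for j in range(n_features):
        base = rng.normal(0, 1, size=len(panel))
        panel[f"f{j}"] = base + np.where(panel["group"] == "early", d, 0.0)
    return panel
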