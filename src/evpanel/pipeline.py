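"""End-to-end orchestration: simulate -> quant -> compare -> pathways ->
biomarkers -> ml, from a single configuration mapping.

Each stage writes its outputs under the run directory and registers them in a
manifest (JSON) holding the package version, global seed, per-stage
parameters, and a SHA-256 hash of every output file — so two runs of the same
configuration can be compared byte-for-byte.  Stages whose inputs are absent
(e.g. the human-panel stages on a mouse-only run) are skipped and recorded as
such.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarkers import assign_classes, select_candidates, validate_panel
from .compare import altered_protein_sets, recapitulation
from .ml import CONTRASTS, accumulate_cv, common_intersection
from .pathways import cross_summary, read_gmt, score_pathways, write_gmt
from .quant import differential_analysis, read_psm_tables
from .simulate import (
    SimConfig,
    generate_human_ev_panel,
    generate_pathway_sets,
    generate_psm_experiment,
    write_experiment,
)

log = logging.getLogger("evpanel")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(manifest: dict, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest["stages"][stage] = {
        "parameters": params,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    ``config`` carries an optional ``simulate`` block (SimConfig fields plus
    ``n_pathways`` / ``pathway_size``) or an ``inputs`` block with paths
    (``counts``, ``meta``, ``gmt``, ``panel``), plus optional per-stage
    parameter blocks ``quant``, ``compare``, ``pathways``, ``biomarkers``,
    ``ml``.  The manifest (also written to ``manifest.json``) lists seeds,
    parameters and output hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"package": "evpanel", "version": __version__, "seed": seed,
                "stages": {}}

    exp = truth = pathway_defs = panel = None
    try:
        if "simulate" in config:
            sim_block = dict(config["simulate"])
            n_pathways = sim_block.pop("n_pathways", 0)
            size_range = tuple(sim_block.pop("pathway_size", (5, 15)))
            sim_cfg = SimConfig(seed=seed, **sim_block)
            log.info("simulate: %s", sim_cfg)
            exp, truth = generate_psm_experiment(sim_cfg)
            panel, human_truth = generate_human_ev_panel(sim_cfg)
            truth.human_class_truth = human_truth.human_class_truth
            truth.group_means = human_truth.group_means
            write_experiment(exp, outdir)
            panel.to_csv(outdir / "human_panel.tsv", sep="\t", index=False)
            outputs = [outdir / "psm_counts.tsv", outdir / "psm_meta.tsv",
                       outdir / "human_panel.tsv"]
            if n_pathways:
                pathway_defs = generate_pathway_sets(
                    n_pathways, size_range, truth, seed,
                    protein_ids=list(exp.counts.index),
                )
                write_gmt(pathway_defs, outdir / "pathways.gmt")
                outputs.append(outdir / "pathways.gmt")
            truth.to_json(outdir / "truth.json")
            outputs.append(outdir / "truth.json")
            _register(manifest, "simulate",
                      {**asdict(sim_cfg), "n_pathways": n_pathways,
                       "pathway_size": list(size_range)}, outputs)
        elif "inputs" in config:
            paths = config["inputs"]
            if "counts" in paths:
                exp = read_psm_tables(paths["counts"], paths["meta"])
            if "gmt" in paths:
                pathway_defs = read_gmt(paths["gmt"])
            if "panel" in paths:
                panel = validate_panel(pd.read_csv(paths["panel"], sep="\t"))
            _register(manifest, "inputs", {k: str(v) for k, v in paths.items()}, [])
        else:
            raise ValueError("config needs a 'simulate' or 'inputs' block")

        diff_tables = {}
        if exp is not None:
            qp = config.get("quant", {})
            for tissue in exp.meta["tissue"].unique():
                for age in sorted(exp.meta["age_months"].unique()):
                    table = differential_analysis(
                        exp, tissue, age,
                        pseudocount=qp.get("pseudocount", 0.5),
                        scale=qp.get("scale", 1e4),
                    )
                    table.attrs["tissue"] = tissue
                    stratum = f"{tissue}_{age}mo"
                    path = outdir / f"diff_{stratum}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    diff_tables[stratum] = table
            _register(manifest, "quant", dict(qp),
                      [outdir / f"diff_{s}.tsv" for s in diff_tables])

        if diff_tables:
            cp = config.get("compare", {})
            sets = altered_protein_sets(
                diff_tables, p_max=cp.get("p_max", 0.05),
                lfc_min=cp.get("lfc_min", 5.0),
            )
            long = pd.concat(
                [s.assign(stratum=name) for name, s in sets.items()],
                ignore_index=True,
            )[["stratum", "protein_id", "log2_fold"]]
            long.to_csv(outdir / "altered_sets.tsv", sep="\t", index=False)
            inter = {}
            names = sorted(sets)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    inter[f"{a}|{b}"] = recapitulation(sets[a], sets[b])[
                        "protein_id"].tolist()
            with open(outdir / "intersections.json", "w") as fh:
                json.dump(inter, fh, indent=2, sort_keys=True)
            _register(manifest, "compare", dict(cp),
                      [outdir / "altered_sets.tsv", outdir / "intersections.json"])

        if diff_tables and pathway_defs:
            pp = config.get("pathways", {})
            labels = {}
            calls_frames = []
            for stratum, table in diff_tables.items():
                calls = score_pathways(
                    table, pathway_defs,
                    p_max=pp.get("p_max", 0.05),
                    z_cut=pp.get("z_cut", 0.5),
                    logp_cut=pp.get("logp_cut", 1.3),
                )
                labels[stratum] = calls.set_index("pathway")["label"]
                calls_frames.append(calls.assign(stratum=stratum))
            pd.concat(calls_frames, ignore_index=True).to_csv(
                outdir / "pathway_calls.tsv", sep="\t", index=False)
            summary = cross_summary(pd.DataFrame(labels))
            with open(outdir / "pathway_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            _register(manifest, "pathways", dict(pp),
                      [outdir / "pathway_calls.tsv", outdir / "pathway_summary.json"])

        if diff_tables:
            ev = {s.split("_")[-1]: t for s, t in diff_tables.items()
                  if s.startswith("plasma_EV")}
            if ev:
                bp = config.get("biomarkers", {})
                cands = select_candidates(ev, p_max=bp.get("p_max", 0.05))
                cands.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
                _register(manifest, "candidates", dict(config.get("biomarkers", {})),
                          [outdir / "candidates.tsv"])

        classes = None
        if panel is not None:
            bp = config.get("biomarkers", {})
            classes = assign_classes(panel, alpha=bp.get("alpha", 0.05))
            classes.to_csv(outdir / "panel_classes.tsv", sep="\t", index=False)
            _register(manifest, "biomarkers", dict(bp),
                      [outdir / "panel_classes.tsv"])
        else:
            manifest["stages"]["biomarkers"] = {"skipped": "no human panel input"}

        if panel is not None:
            mp = config.get("ml", {})
            proteins = [c for c in panel.columns
                        if c not in ("subject_id", "group", "mmse")]
            universe = common_intersection({g: proteins for g in
                                            panel["group"].unique()})
            outputs = []
            report = {}
            for contrast in mp.get("contrasts", sorted(CONTRASTS)):
                perf = accumulate_cv(
                    panel, contrast, universe,
                    folds=mp.get("folds", 10), repeats=mp.get("repeats", 10),
                    seed=seed, C=mp.get("C", 1.0),
                    kernel=mp.get("kernel", "linear"),
                )
                perf.per_k.to_csv(outdir / f"ml_{contrast}_per_k.tsv",
                                  sep="\t", index=False)
                perf.roc.to_csv(outdir / f"ml_{contrast}_roc.tsv",
                                sep="\t", index=False)
                outputs += [outdir / f"ml_{contrast}_per_k.tsv",
                            outdir / f"ml_{contrast}_roc.tsv"]
                report[contrast] = {
                    "best_k": perf.best_k, "best_panel": perf.best_panel,
                    "accuracy": float(perf.per_k["accuracy"].max()),
                    "auc": perf.auc, "auc_mean": perf.auc_mean,
                }
            with open(outdir / "ml_report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            outputs.append(outdir / "ml_report.json")
            _register(manifest, "ml", dict(mp), outputs)
        else:
            manifest["stages"]["ml"] = {"skipped": "no human panel input"}

    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
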