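"""End-to-end run: filter -> normalize -> contamination QC -> differential ->
pathway GSEA -> correlation screens -> metabolite associations.

A run is a pure function of (input files, config, seed).  Every stage writes a
TSV (or JSON) artifact into the run directory and the run ends with a manifest
recording the stage sequence, row counts, package versions, seed, and a hash
of the resolved configuration, so two runs with the same config and seed are
byte-for-byte identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contamination import score_samples, scores_table
from .correlation import correlation_ranked_gsea, correlation_table, spearman_screen
from .differential import DesignSpec, differential_table, fit_protein_models, ranking_for_gsea
from .errors import PipelineError, ValidationError
from .gsea import gsea_preranked, results_table
from .io_formats import (
    read_gmt,
    read_metabolites,
    read_metadata,
    read_protein_table,
    write_results,
)
from .metabolites import metabolite_logistic, metabolite_table
from .preprocess import filter_proteins, normalize, zeros_to_missing

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "STAGES"]

STAGES = ["filter", "normalize", "qc_score", "differential", "pathway_gsea",
          "correlation", "metabolites"]

_DEFAULT_PARAMS = {
    "seed": 0,
    "min_unique_peptides": 2,
    "zero_mode": "cell",
    "qc": {"cutoff": -0.75, "n_perm": 1000, "min_present": 50},
    "gsea": {"n_perm": 10000, "min_size": 5, "max_size": 500, "weight_exponent": 1.0},
    "differential": {"min_n": 10, "orientation": "obesity"},
    "correlation": {"min_n": 10, "variables": None, "strata": ["all"], "min_proteins": 50},
    "metabolites": {"adjust": ["age"], "fdr_threshold": 0.05, "zero_policy": "error"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValidationError(f"{path}: config must be a mapping with an 'inputs' section")
    cfg["params"] = _merge(_DEFAULT_PARAMS, cfg.get("params") or {})
    return cfg


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> Path:
    """Execute all stages in order and return the run directory.

    ``config`` is a YAML path or an equivalent dict with ``inputs`` (paths to
    the protein table, metadata, adipose/blood GMTs, pathway GMT, metabolite
    table), ``params`` (per-stage settings, all optional), and ``outdir``.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(config)
        cfg["params"] = _merge(_DEFAULT_PARAMS, cfg.get("params") or {})
    params = cfg["params"]
    inputs = cfg["inputs"]
    outdir = Path(outdir or cfg.get("outdir", "run"))

    required = ["protein_table", "metadata", "adipose_gmt", "blood_gmt",
                "pathway_gmt", "metabolites"]
    missing_keys = [k for k in required if k not in inputs]
    if missing_keys:
        raise ValidationError(f"config inputs missing: {missing_keys}")
    missing_files = [str(inputs[k]) for k in required if not Path(inputs[k]).exists()]
    if missing_files:
        raise ValidationError(f"input files not found: {missing_files}")

    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(params["seed"])
    manifest_stages = []

    def record(stage: str, **info) -> None:
        manifest_stages.append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    # ---- load inputs ----------------------------------------------------
    try:
        matrix = read_protein_table(inputs["protein_table"])
        meta = read_metadata(inputs["metadata"])
        adipose = read_gmt(inputs["adipose_gmt"])[0]
        blood = read_gmt(inputs["blood_gmt"])[0]
        pathways = read_gmt(inputs["pathway_gmt"])
        metabolites = read_metabolites(inputs["metabolites"])
    except Exception as exc:
        raise PipelineError("load_inputs", str(exc)) from exc

    # ---- 1. filter ------------------------------------------------------
    try:
        matrix, report = filter_proteins(matrix, params["min_unique_peptides"])
        (outdir / "filter_report.json").write_text(
            json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        record("filter", **report.as_dict())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # ---- 2. normalize ---------------------------------------------------
    try:
        matrix = zeros_to_missing(matrix, mode=params["zero_mode"])
        matrix = normalize(matrix)
        norm_out = matrix.values.reset_index()
        write_results(outdir / "normalized_matrix.tsv", norm_out)
        record("normalize", n_proteins=matrix.n_proteins, n_samples=len(matrix.samples))
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    # ---- 3. contamination QC -------------------------------------------
    try:
        qc = params["qc"]
        scores = score_samples(
            matrix, adipose, blood, cutoff=qc["cutoff"], n_perm=qc["n_perm"],
            seed=seed, min_present=qc["min_present"],
        )
        write_results(outdir / "qc_scores.tsv", scores_table(scores))
        excluded = [s.sample_id for s in scores if not s.keep]
        (outdir / "excluded_samples.txt").write_text("".join(f"{s}\n" for s in excluded))
        matrix = matrix.drop_samples(excluded)
        meta = [m for m in meta if m.sample_id not in set(excluded)]
        record("qc_score", n_excluded=len(excluded), excluded=sorted(excluded))
    except Exception as exc:
        raise PipelineError("qc_score", str(exc)) from exc

    # ---- 4. differential ------------------------------------------------
    try:
        dpar = params["differential"]
        diff = fit_protein_models(matrix, meta, DesignSpec(), min_n=dpar["min_n"])
        write_results(outdir / "differential.tsv", differential_table(diff))
        n_sig = int((differential_table(diff)["fdr"] < 0.05).sum())
        record("differential", n_tested=sum(r.status == "ok" for r in diff),
               n_significant_fdr05=n_sig)
    except Exception as exc:
        raise PipelineError("differential", str(exc)) from exc

    # ---- 5. pathway GSEA on the differential ranking --------------------
    try:
        gpar = params["gsea"]
        ranking = ranking_for_gsea(diff, orientation=dpar["orientation"])
        gres = gsea_preranked(
            ranking, pathways, n_perm=gpar["n_perm"], min_size=gpar["min_size"],
            max_size=gpar["max_size"], weight_exponent=gpar["weight_exponent"],
            seed=seed + 1,
        )
        write_results(outdir / "gsea_differential.tsv", results_table(gres))
        record("pathway_gsea", n_sets=len(gres),
               n_tested=sum(r.status == "ok" for r in gres))
    except Exception as exc:
        raise PipelineError("pathway_gsea", str(exc)) from exc

    # ---- 6. correlation screens ----------------------------------------
    try:
        cpar = params["correlation"]
        variables = cpar["variables"] or list(metabolites.values.columns[:3])
        var_df = metabolites.values[variables]
        all_corr, all_gsea = [], []
        for stratum in cpar["strata"]:
            corr = spearman_screen(matrix, var_df, min_n=cpar["min_n"],
                                   meta=meta, stratum=stratum)
            all_corr.extend(corr)
            for var in variables:
                sub = [c for c in corr if c.variable == var]
                usable = [c for c in sub if c.status == "ok"]
                if len(usable) < cpar["min_proteins"]:
                    continue
                gres_c = correlation_ranked_gsea(
                    sub, pathways, n_perm=gpar["n_perm"], min_size=gpar["min_size"],
                    max_size=gpar["max_size"], seed=seed + 2,
                )
                tbl = results_table(gres_c)
                tbl.insert(0, "variable", var)
                tbl.insert(1, "stratum", stratum)
                all_gsea.append(tbl)
        write_results(outdir / "correlations.tsv", correlation_table(all_corr))
        if all_gsea:
            write_results(outdir / "gsea_correlation.tsv",
                          pd.concat(all_gsea, ignore_index=True))
        record("correlation", n_pairs=len(all_corr), n_variables=len(variables))
    except Exception as exc:
        raise PipelineError("correlation", str(exc)) from exc

    # ---- 7. metabolite associations -------------------------------------
    try:
        mpar = params["metabolites"]
        mres = metabolite_logistic(
            metabolites, meta, adjust_for=tuple(mpar["adjust"]),
            fdr_threshold=mpar["fdr_threshold"], zero_policy=mpar["zero_policy"],
        )
        write_results(outdir / "metabolite_associations.tsv", metabolite_table(mres))
        n_down = sum(r.direction == "down" for r in mres)
        n_up = sum(r.direction == "up" for r in mres)
        record("metabolites", n_measures=len(mres), n_down=n_down, n_up=n_up)
    except Exception as exc:
        raise PipelineError("metabolites", str(exc)) from exc

    # ---- manifest --------------------------------------------------------
    cfg_serial = json.dumps({"inputs": {k: str(v) for k, v in inputs.items()},
                             "params": params}, sort_keys=True, default=str)
    manifest = {
        "pipeline_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_serial.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": manifest_stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
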