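"""One-shot orchestration: simulate -> normalize -> de -> skew -> cluster -> qpcr.

A flat YAML config drives a full run; every output is a TSV under the
configured output directory and a JSON manifest records the config
snapshot, seed, package version, per-stage output digests and timings.
Outputs are pure functions of config + seed, so re-running an identical
config reproduces byte-identical TSVs (manifests differ only in timings).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Union

import yaml

from . import __version__
from .data_io import (ConfigError, DataError, read_count_table, read_ct_table,
                      read_gene_set, write_count_table, write_ct_table,
                      write_gene_set, write_results)
from .cluster_view import cluster_extreme_de
from .de_analysis import de_table, sort_de_table
from .geneset_skew import skew_report
from .normalize_filter import normalize_counts, write_normalized_table
from .qpcr_concordance import ddct_fold_change, sign_concordance
from .synthetic_data import SynthConfig, generate_counts, generate_ct_table

log = logging.getLogger("mitoskew")

DEFAULTS: dict[str, Any] = {
    "simulate": True,
    "counts": None, "design": None, "geneset": None, "ct": None,
    "threshold": 10.0, "pseudocount": 1.0, "filter_rule": "both-groups-below",
    "alpha": 0.05, "fc_threshold": 1.3, "welch": False, "fdr": "none",
    "epsilon": 0.0,
    "cluster_k": 20, "linkage": "ward", "distance": "euclidean",
    "stages": ["normalize", "de", "skew", "cluster", "qpcr"],
    "outdir": "mitoskew_run",
    "seed": None,
}
_VALID_STAGES = ("normalize", "de", "skew", "cluster", "qpcr")


def load_config(path: Union[str, Path]) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat mapping")
    return raw


def _validate(config: dict) -> dict:
    unknown = set(config) - set(DEFAULTS) - set(SynthConfig().to_dict())
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {**DEFAULTS, **config}
    for stage in cfg["stages"]:
        if stage not in _VALID_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
    if cfg["simulate"]:
        if cfg["seed"] is None:
            raise ConfigError("a seed is required for a simulated run")
    else:
        if not cfg["counts"] or not cfg["design"]:
            raise ConfigError("counts and design paths are required when simulate: false")
        if "skew" in cfg["stages"] and not cfg["geneset"]:
            raise ConfigError("skew stage enabled but no gene-set path given")
        if "qpcr" in cfg["stages"] and not cfg["ct"]:
            raise ConfigError("qpcr stage enabled but no Ct table path given")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Union[dict, str, Path]) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages_done: list[dict] = []

    def record(name: str, started: float, outputs: list[Path]) -> None:
        stages_done.append({
            "stage": name,
            "seconds": round(time.perf_counter() - started, 4),
            "outputs": {p.name: _digest(p) for p in outputs},
        })

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    truth = gene_set = ct = None
    if cfg["simulate"]:
        synth_keys = set(SynthConfig().to_dict())
        synth = SynthConfig(**{k: cfg[k] for k in synth_keys if k in cfg})
        table, truth, gene_set = generate_counts(synth)
        outs = [outdir / "counts.tsv", outdir / "design.tsv",
                outdir / "truth.tsv", outdir / "geneset.txt"]
        write_count_table(table, outs[0], outs[1])
        write_results(truth, outs[2])
        write_gene_set(gene_set, outs[3])
        if "qpcr" in cfg["stages"]:
            ct = generate_ct_table(truth, synth)
            outs.append(outdir / "ct.tsv")
            write_ct_table(ct, outs[-1])
        record("simulate", t0, outs)
    else:
        table = read_count_table(cfg["counts"], cfg["design"])
        if "skew" in cfg["stages"]:
            gene_set = read_gene_set(cfg["geneset"])
        if "qpcr" in cfg["stages"]:
            ct = read_ct_table(cfg["ct"], cfg["design"])
        record("load", t0, [])

    # --- stages -----------------------------------------------------------
    norm = records = None
    for stage in cfg["stages"]:
        t0 = time.perf_counter()
        try:
            if stage == "normalize":
                norm, n_removed = normalize_counts(
                    table, cfg["threshold"], cfg["pseudocount"], cfg["filter_rule"])
                out = outdir / "normalized.tsv"
                write_normalized_table(norm, out)
                record(stage, t0, [out])
                stages_done[-1]["genes_removed"] = n_removed
                stages_done[-1]["genes_retained"] = len(norm.gene_ids)
            elif stage == "de":
                records = de_table(norm, cfg["alpha"], cfg["fc_threshold"],
                                   cfg["welch"], cfg["fdr"])
                out = outdir / "de.tsv"
                write_results(sort_de_table(records), out)
                record(stage, t0, [out])
                stages_done[-1]["n_de"] = int(records["is_de"].sum())
            elif stage == "skew":
                result, ma_table = skew_report(gene_set, norm, cfg["epsilon"])
                outs = [outdir / "skew.tsv", outdir / "skew_genes.tsv"]
                write_results(result, outs[0])
                write_results(ma_table, outs[1])
                record(stage, t0, outs)
                stages_done[-1]["p_two_sided"] = result.p_two_sided
            elif stage == "cluster":
                cres = cluster_extreme_de(norm, records, cfg["cluster_k"],
                                          cfg["linkage"], cfg["distance"])
                out = outdir / "cluster.tsv"
                write_results(cres, out)
                record(stage, t0, [out])
                stages_done[-1]["purity"] = cres.purity
            elif stage == "qpcr":
                folds = ddct_fold_change(ct)
                outs = [outdir / "qpcr_folds.tsv"]
                if records is not None:
                    rnaseq = records.set_index("gene_id")["fold_linear"]
                    shared = [g for g in folds["gene_id"] if g in rnaseq.index]
                    pairs = folds.set_index("gene_id").loc[shared]
                    pairs = pairs.assign(rnaseq_fold=rnaseq.loc[shared]) \
                                 .rename(columns={"fold": "qpcr_fold"}) \
                                 .reset_index()
                    if len(pairs):
                        n_con, n_dis, flagged = sign_concordance(
                            pairs[["gene_id", "rnaseq_fold", "qpcr_fold"]])
                        outs.append(outdir / "qpcr_concordance.tsv")
                        write_results(flagged, outs[-1])
                        write_results(folds, outs[0])
                        record(stage, t0, outs)
                        stages_done[-1]["n_concordant"] = n_con
                        stages_done[-1]["n_discordant"] = n_dis
                        continue
                write_results(folds, outs[0])
                record(stage, t0, outs)
        except DataError as err:
            raise DataError(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "package": "mitoskew",
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: cfg[k] for k in sorted(cfg)},
        "stages": stages_done,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
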