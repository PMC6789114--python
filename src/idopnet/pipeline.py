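"""End-to-end orchestration: EI -> allometry -> clustering -> fit -> test -> networks.

A run is described by a flat, versioned YAML config; all randomness
derives from one root seed via per-stage spawned seeds, so re-running an
identical config reproduces identical numeric outputs.  Each stage writes
its outputs under the configured directory and the run finishes with a
JSON manifest recording config, stage status, outputs, seeds and timings.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .allometry import screen_power_fit
from .clustering import CurveMixture, aggregate_modules
from .expression import compute_expression_index, load_expression, load_metadata, reorder_by_ei
from .networks import build_network_at, network_to_edge_table, write_graphml
from .qdode import QdODE
from .significance import permutation_test

log = logging.getLogger("idopnet")

CONFIG_VERSION = 1

#: recognised config keys with defaults (None = required)
CONFIG_SCHEMA: dict[str, object] = {
    "config_version": CONFIG_VERSION,
    "expr": None,
    "meta": "",
    "outdir": None,
    "format": "tsv",
    "seed": 0,
    "log_level": "INFO",
    # clustering
    "cluster_enabled": True,
    "cluster_kmin": 1,
    "cluster_kmax": 5,
    "cluster_n_init": 3,
    "cluster_aggregate": "mean",
    "recompute_ei_after_aggregation": True,
    # qdODE fit
    "degree": 3,
    "n_interior": 0,
    "n_interior_dep": 0,
    "n_lambda": 10,
    "criterion": "bic",
    "adaptive": False,
    "cov": "independent",
    # significance test
    "test_enabled": True,
    "n_perm": 100,
    # networks
    "network_at": "median",  # "median", "samples", or a number
    "allometry_r2_min": 0.0,
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    cfg = dict(CONFIG_SCHEMA)
    cfg.update(raw)
    missing = [k for k, v in cfg.items() if v is None]
    if missing:
        raise ConfigError(f"missing required config key(s): {missing}")
    if int(cfg["config_version"]) != CONFIG_VERSION:
        raise ConfigError(
            f"config_version {cfg['config_version']} unsupported (expected {CONFIG_VERSION})"
        )
    return cfg


def _stage_seeds(root_seed: int, names: list[str]) -> dict[str, int]:
    states = np.random.SeedSequence(root_seed).generate_state(len(names)) % (2**31)
    return {n: int(s) for n, s in zip(names, states)}


def run_pipeline(cfg: dict) -> dict:
    """Run every stage; returns (and writes) the manifest dict."""
    cfg = validate_config(dict(cfg))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["log_level"])
    seeds = _stage_seeds(int(cfg["seed"]), ["cluster", "fit", "test"])
    manifest = {
        "idopnet_version": __version__,
        "config": cfg,
        "stage_seeds": seeds,
        "stages": [],
    }

    def record(name, t0, **outputs):
        manifest["stages"].append({
            "name": name, "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3), "outputs": outputs,
        })
        log.info("stage %s complete", name)

    try:
        t0 = time.perf_counter()
        meta = load_metadata(cfg["meta"]) if cfg["meta"] else None
        x = load_expression(cfg["expr"], format=cfg["format"], metadata=meta)
        record("load", t0, n_genes=x.n_genes, n_samples=x.n_samples)

        t0 = time.perf_counter()
        ei = compute_expression_index(x)
        xs = reorder_by_ei(x, ei)
        ei_path = str(outdir / "ei.tsv")
        ei.to_frame(x.sample_ids).to_csv(ei_path, sep="\t", index=False)
        record("ei", t0, ei_table=ei_path)

        t0 = time.perf_counter()
        fits = screen_power_fit(x, ei, r2_min=float(cfg["allometry_r2_min"]))
        allo_path = str(outdir / "allometry.tsv")
        fits.to_csv(allo_path, sep="\t")
        record("allometry", t0, table=allo_path)

        t0 = time.perf_counter()
        if cfg["cluster_enabled"]:
            mix = CurveMixture(x, ei).fit_select(
                range(int(cfg["cluster_kmin"]), int(cfg["cluster_kmax"]) + 1),
                seed=seeds["cluster"], n_init=int(cfg["cluster_n_init"]),
            )
            assign_path = str(outdir / "modules.tsv")
            mix.assignment_frame().to_csv(assign_path, sep="\t")
            mix.aic_trace.to_csv(outdir / "aic_trace.tsv", sep="\t", index=False)
            mx = aggregate_modules(x, mix, how=cfg["cluster_aggregate"])
            mx.write(outdir / "module_expression.tsv")
            net_input = mx
            net_ei = compute_expression_index(mx) if cfg["recompute_ei_after_aggregation"] else ei
            record("cluster", t0, n_modules=mix.n_modules, assignment=assign_path)
        else:
            net_input, net_ei = xs, ei
            record("cluster", t0, skipped=True)

        t0 = time.perf_counter()
        engine = QdODE(
            net_input, ei=net_ei, degree=int(cfg["degree"]),
            n_interior=cfg["n_interior"], n_interior_dep=int(cfg["n_interior_dep"]),
        )
        results = engine.fit(
            n_lambda=int(cfg["n_lambda"]), criterion=cfg["criterion"],
            adaptive=bool(cfg["adaptive"]), cov=cfg["cov"],
        )
        model_path = str(outdir / "model.json")
        results.to_json(model_path)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        record("fit", t0, model=model_path, loglik=results.loglik)

        t0 = time.perf_counter()
        if cfg["test_enabled"]:
            test = permutation_test(
                net_input, ei=None if cfg["recompute_ei_after_aggregation"] else net_ei,
                n_perm=int(cfg["n_perm"]), seed=seeds["test"],
                qdode_kwargs={
                    "degree": int(cfg["degree"]), "n_interior": cfg["n_interior"],
                    "n_interior_dep": int(cfg["n_interior_dep"]),
                },
                fit_kwargs={"n_lambda": int(cfg["n_lambda"])},
            )
            test_path = str(outdir / "network_test.json")
            test.to_json(test_path)
            np.savetxt(outdir / "null_lrs.tsv", test.null_lrs, header="lr", comments="")
            record("test", t0, report=test_path, significant=bool(test.significant))
        else:
            record("test", t0, skipped=True)

        t0 = time.perf_counter()
        at = cfg["network_at"]
        if at == "median":
            ei_values = [float(np.median(engine.e))]
        elif at == "samples":
            ei_values = [float(v) for v in engine.e]
        else:
            ei_values = [float(at)]
        tables = []
        for v in ei_values:
            g = build_network_at(results, v)
            tables.append(network_to_edge_table(g))
        import pandas as pd

        edge_path = str(outdir / "networks.tsv")
        pd.concat(tables).to_csv(edge_path, sep="\t", index=False)
        write_graphml(build_network_at(results, ei_values[0]), outdir / "network.graphml")
        record("networks", t0, edges=edge_path)
    except Exception as exc:  # record partial completion, then re-raise
        manifest["stages"].append({"name": "failed", "status": "error", "error": str(exc)})
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def run_from_file(path) -> dict:
    return run_pipeline(load_config(path))


def write_template(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v for k, v in CONFIG_SCHEMA.items()}, fh, sort_keys=False)
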