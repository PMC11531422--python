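"""Config-driven orchestration of the full exposure × outcome analysis grid.

A run config (YAML on disk, dict in memory) names exposure and outcome
summary-statistic files, the methods to run, the filters to apply, an
optional correlated cis block and optional power specifications.  For each
exposure–outcome pair the pipeline harmonizes, filters, runs the estimator
battery, computes heterogeneity, and exports funnel/scatter plot data; it
writes a results TSV (one row per exposure × outcome × method), a filter
log, and a machine-readable manifest with the config, seed and content
hashes of every output.  Identical config + inputs + seed reproduce every
output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cis import LDMatrix, correlated_ivw, cis_wald_table
from .diagnostics import (cochran_q, confounder_filter, export_plot_data,
                          steiger_filter, steiger_frame)
from .estimators import (METHODS, EstimatorConfig, MRConfigError, results_frame,
                         run_battery)
from .metapower import PowerSpec, detectable_or, power_binary
from .sumstats import (ProxyMap, harmonize, harmonized_frame, read_sumstats,
                       select_instruments, usable_frame, write_harmonized)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


DEFAULTS = {
    "methods": list(METHODS),
    "estimator": {
        "re_mode": "multiplicative_random",
        "bootstrap_reps": 1000,
        "mode_bandwidth_factor": 1.0,
        "presso_sims": 1000,
        "presso_outlier_alpha": 0.05,
        "lasso_heterogeneity_quantile": 0.95,
        "raps_overdispersion": True,
    },
    "selection": {"p_max": 5e-8, "maf_min": 0.001, "info_min": None},
    "harmonize": {"palindrome_window": 0.08},
    "filters": {"steiger": False, "confounder": False, "n_tests": None},
    "log_level": "INFO",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg, base_dir=Path(path).parent)


def validate_config(cfg: dict, base_dir: Path | None = None) -> dict:
    """Merge defaults, check required keys and file existence."""
    merged = json.loads(json.dumps(DEFAULTS))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    if "seed" not in merged or merged["seed"] is None:
        raise PipelineError("config must set an integer seed")
    for side in ("exposures", "outcomes"):
        if not merged.get(side):
            raise PipelineError(f"config must list at least one entry in {side!r}")
        for entry in merged[side]:
            if "name" not in entry or "file" not in entry:
                raise PipelineError(f"every {side} entry needs name and file")
            p = Path(entry["file"])
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
                entry["file"] = str(p)
            if not p.exists():
                raise PipelineError(f"{side} file not found: {p}")
    for entry in merged["outcomes"]:
        entry.setdefault("scale", "lnor")
    unknown = [m for m in merged["methods"] if m not in METHODS]
    if unknown:
        raise MRConfigError(f"unknown methods in config: {unknown}")
    return merged


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the analysis grid; returns the manifest dict.

    A fatal error in one exposure–outcome pair is recorded in the manifest
    and the remaining pairs continue.
    """
    cfg = validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    est_cfg = EstimatorConfig(seed=seed, **cfg["estimator"])
    manifest = {"config": cfg, "config_hash": _hash_config(cfg), "seed": seed,
                "version": __version__, "outputs": {}, "errors": {},
                "filter_log": {}}

    proxies = None
    if cfg.get("proxy_file"):
        proxies = ProxyMap.read(cfg["proxy_file"])

    confounder_assoc = None
    if cfg["filters"].get("confounder") and cfg.get("confounder_file"):
        confounder_assoc = pd.read_csv(cfg["confounder_file"], sep="\t")

    all_results = []
    for exp_entry in cfg["exposures"]:
        exposure = read_sumstats(exp_entry["file"], trait_name=exp_entry["name"],
                                 trait_scale=exp_entry.get("scale", "sd"))
        exposure = select_instruments(exposure, **{
            k: v for k, v in cfg["selection"].items() if v is not None})
        for out_entry in cfg["outcomes"]:
            pair = f"{exp_entry['name']}__{out_entry['name']}"
            try:
                pair_results, logs = _run_pair(
                    exposure, exp_entry, out_entry, proxies, confounder_assoc,
                    cfg, est_cfg, out_dir, pair)
                all_results.extend(pair_results)
                manifest["filter_log"][pair] = logs
            except Exception as e:  # pair-level isolation
                logger.error("pair %s failed: %s", pair, e)
                manifest["errors"][pair] = f"{type(e).__name__}: {e}"

    results_df = pd.DataFrame(all_results)
    results_path = out_dir / "results.tsv"
    results_df.to_csv(results_path, sep="\t", index=False)

    if cfg.get("cis"):
        try:
            _run_cis(cfg, est_cfg, out_dir, manifest)
        except Exception as e:
            manifest["errors"]["cis"] = f"{type(e).__name__}: {e}"

    if cfg.get("power"):
        power_rows = []
        for p in cfg["power"]:
            spec = PowerSpec(n_total=int(p["n_total"]), n_cases=int(p["n_cases"]),
                             r2=float(p["r2"]), alpha=float(p.get("alpha", 0.05)))
            row = {"NAME": p.get("name", ""), "N": spec.n_total,
                   "CASES": spec.n_cases, "R2": spec.r2}
            if p.get("or_alt"):
                row["POWER"] = power_binary(spec, float(p["or_alt"]))
            if p.get("target_power"):
                row["DETECTABLE_OR"] = detectable_or(
                    spec, float(p["target_power"]),
                    p.get("direction", "protective"))
                row["TARGET_POWER"] = float(p["target_power"])
            power_rows.append(row)
        power_path = out_dir / "power.tsv"
        pd.DataFrame(power_rows).to_csv(power_path, sep="\t", index=False)

    for f in sorted(out_dir.glob("*.tsv")):
        manifest["outputs"][f.name] = _hash_file(f)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    return manifest


def _run_pair(exposure, exp_entry, out_entry, proxies, confounder_assoc,
              cfg, est_cfg, out_dir, pair):
    outcome = read_sumstats(out_entry["file"], trait_name=out_entry["name"],
                            trait_scale=out_entry.get("scale", "lnor"))
    rows = harmonize(exposure, outcome, proxies=proxies,
                     palindrome_window=cfg["harmonize"]["palindrome_window"])
    write_harmonized(rows, out_dir / f"{pair}.harmonized.tsv")
    table = usable_frame(rows)
    logs = {"n_instruments": len(exposure), "n_harmonized": len(table)}

    if cfg["filters"].get("confounder") and confounder_assoc is not None:
        n_tests = cfg["filters"].get("n_tests") or len(table)
        table, excl = confounder_filter(table, confounder_assoc, int(n_tests))
        logs["confounder_excluded"] = excl["SNP"].astype(str).tolist() \
            if len(excl) else []
    if cfg["filters"].get("steiger"):
        n_cases = out_entry.get("n_cases")
        n_total = out_entry.get("n_total")
        binary = out_entry.get("scale", "lnor") == "lnor"
        table, st = steiger_filter(
            table, n_exp=exp_entry.get("n_total", 1e5),
            n_out_cases=n_cases,
            n_out_controls=(n_total - n_cases) if (n_cases and n_total) else None,
            n_out_total=n_total, binary_outcome=binary)
        steiger_frame(st).to_csv(out_dir / f"{pair}.steiger.tsv",
                                 sep="\t", index=False)
        logs["steiger_dropped"] = int(sum(not r.keep for r in st))

    pair_cfg = EstimatorConfig(**{**est_cfg.__dict__,
                                  "outcome_scale": out_entry.get("scale", "lnor")})
    results = run_battery(table, pair_cfg, cfg["methods"])
    het = cochran_q(table) if len(table) >= 2 else None
    funnel, scatter = export_plot_data(table, results)
    funnel.to_csv(out_dir / f"{pair}.funnel.tsv", sep="\t", index=False)
    scatter.to_csv(out_dir / f"{pair}.scatter.tsv", sep="\t", index=False)
    scatter.attrs["lines"].to_csv(out_dir / f"{pair}.scatter_lines.tsv",
                                  sep="\t", index=False)

    rows_out = []
    for r in results:
        row = {"EXPOSURE": exp_entry["name"], "OUTCOME": out_entry["name"]}
        row.update(r.to_row())
        if het is not None and row.get("Q") is None:
            row["Q"], row["I2"] = het.Q, het.i2
        rows_out.append(row)
    return rows_out, logs


def _run_cis(cfg, est_cfg, out_dir, manifest):
    cis_cfg = cfg["cis"]
    rows = pd.read_csv(cis_cfg["harmonized_file"], sep="\t")
    ld = LDMatrix.read(cis_cfg["ld_file"])
    scale = cis_cfg.get("scale", "lnor")
    wald = cis_wald_table(rows, outcome_scale=scale)
    combined = correlated_ivw(rows, ld, outcome_scale=scale)
    results_frame(wald + [combined]).to_csv(
        out_dir / "cis_results.tsv", sep="\t", index=False)
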