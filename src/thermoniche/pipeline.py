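"""End-to-end orchestration: growth rates -> thermal curves -> comparative
analysis -> trait/environment regressions, with auditable defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phylo_comparative as pc
from .errors import ConsistencyError, DataError, ThermonicheError
from .growth_kinetics import growth_rate_table, read_f0_csv
from .synthetic_data import SEASONS
from .thermal_response import (
    GrowthTemperatureProfile,
    correlate_and_regress,
    fit_thermal_curve,
    performance_range,
)

__all__ = ["RunConfig", "sst_summary", "run_all", "load_config"]

log = logging.getLogger("thermoniche")


@dataclass
class RunConfig:
    """Effective configuration for a full pipeline run.

    Every numeric default is overridable (CLI flags or YAML config) and is
    echoed verbatim in the report.
    """

    f0_csv: str = ""
    tree_nwk: str = ""
    strains_csv: str = ""
    alignment_fasta: str = ""     # optional; enables the Mantel stage
    out_dir: str = "out"
    window: object = "default"    # "default" | "auto" | [start, end]
    weighted: bool = False
    include_zero_growth: bool = True
    fraction: float = 0.8
    smoothing: float = 0.1
    n_perm: int = 999
    seed: int = 0


def load_config(path) -> RunConfig:
    """Read a YAML file whose keys mirror RunConfig field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def sst_summary(seasonal) -> dict:
    """Mean and sample SD of exactly four seasonal SST values."""
    vals = [float(v) for v in seasonal]
    if len(vals) != 4 or not all(math.isfinite(v) for v in vals):
        raise DataError(f"need exactly 4 finite seasonal values, got {seasonal}")
    arr = np.array(vals)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _stage(name, config, **info):
    log.info("stage=%s seed=%s %s", name, config.seed,
             " ".join(f"{k}={v}" for k, v in info.items()))


def _check_labels(name_a, labels_a, name_b, labels_b):
    a, b = set(labels_a), set(labels_b)
    only_a, only_b = sorted(a - b), sorted(b - a)
    if only_a or only_b:
        raise ConsistencyError(
            f"strain_id mismatch between {name_a} and {name_b}: "
            f"only in {name_a}: {only_a}; only in {name_b}: {only_b}"
        )


def _maybe_regress(x, y) -> dict:
    try:
        return correlate_and_regress(x, y).as_dict()
    except DataError as e:
        return {"error": str(e)}


def run_all(config: RunConfig) -> dict:
    """Run every pipeline stage and return (and write) the report bundle.

    Stages: growth-rate estimation, thermal-curve fitting and niche
    bounds, phylogenetic signal on the fitted optima, an optional Mantel
    test, and the trait/environment regressions.  Any stage error aborts
    with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {},
        "notes": [
            "regressions are reported without multiplicity correction",
        ],
    }

    # ---- growth_kinetics ---------------------------------------------------
    stage = "growth_rates"
    try:
        series = read_f0_csv(config.f0_csv)
        rates = growth_rate_table(series, window=_window_arg(config.window))
        report["inputs"]["f0_csv"] = {"sha256": _file_digest(config.f0_csv),
                                      "n_series": len(series)}
        _stage(stage, config, n_series=len(series), n_rows=len(rates))
    except ThermonicheError as e:
        raise ThermonicheError(f"[stage {stage}] {e}") from e
    rates_path = out_dir / "rates.csv"
    rates.to_csv(rates_path, index=False)

    # ---- thermal_response --------------------------------------------------
    stage = "thermal_curves"
    fits = []
    try:
        for sid, grp in rates.groupby("strain_id", sort=True):
            grp = grp.sort_values("temperature_c")
            if config.include_zero_growth:
                keep = grp
            else:
                keep = grp[grp["mean_rate"] > 0]
            profile = GrowthTemperatureProfile(
                strain_id=str(sid),
                temperatures=tuple(keep["temperature_c"]),
                mean_rates=tuple(keep["mean_rate"]),
                se_rates=tuple(keep["se_rate"]),
            )
            params = fit_thermal_curve(profile, weighted=config.weighted)
            niche = performance_range(params, config.fraction)
            fits.append(dict(
                strain_id=str(sid),
                mu_max=params.mu_max, se_mu_max=params.se_mu_max,
                t_opt=params.t_opt, se_t_opt=params.se_t_opt,
                t_max=params.t_max, se_t_max=params.se_t_max,
                beta=params.beta, se_beta=params.se_beta,
                rss=params.rss, converged=params.converged,
                t_low80=niche.t_low, t_high80=niche.t_high, width80=niche.width,
                mu_obs_max=float(grp["mean_rate"].max()),
                t_at_mu_obs_max=float(
                    grp.loc[grp["mean_rate"].idxmax(), "temperature_c"]
                ),
            ))
        _stage(stage, config, n_strains=len(fits))
    except ThermonicheError as e:
        raise ThermonicheError(f"[stage {stage}] {e}") from e
    tpc = pd.DataFrame(fits)
    tpc_path = out_dir / "tpc_fits.csv"
    tpc.to_csv(tpc_path, index=False)

    # ---- phylo_comparative -------------------------------------------------
    stage = "phylo_signal"
    try:
        tree = pc.read_tree(config.tree_nwk)
        _check_labels("tree", pc.tip_labels(tree), "f0_csv", tpc["strain_id"])
        if not pc.is_ultrametric(tree):
            tree = pc.ultrametricize_pl(tree, smoothing=config.smoothing)
        trait = dict(zip(tpc["strain_id"], tpc["t_opt"]))
        lam = pc.fit_pagels_lambda(tree, trait)
        kest = pc.blombergs_k(tree, trait)
        k_p = pc.k_permutation_test(tree, trait, n_perm=config.n_perm, seed=config.seed)
        report["phylosignal"] = {
            "lambda": lam.statistic, "sigma2": lam.sigma2,
            "root_state": lam.root_state, "logL": lam.log_likelihood,
            "p_lr": lam.p_value, "K": kest.statistic, "p_perm": k_p,
        }
        report["inputs"]["tree_nwk"] = {"sha256": _file_digest(config.tree_nwk),
                                        "n_tips": len(pc.tip_labels(tree))}
        _stage(stage, config, n_tips=len(pc.tip_labels(tree)))
    except ThermonicheError as e:
        raise ThermonicheError(f"[stage {stage}] {e}") from e

    # ---- metadata + regressions -------------------------------------------
    stage = "regressions"
    try:
        strains = pd.read_csv(config.strains_csv)
        _check_labels("strains_csv", strains["strain_id"], "f0_csv", tpc["strain_id"])
        df = tpc.merge(strains, on="strain_id", validate="one_to_one")
        regressions = {
            "mu_max_pred_vs_t_opt": _maybe_regress(df["t_opt"], df["mu_max"]),
            "mu_max_obs_vs_t_obs": _maybe_regress(df["t_at_mu_obs_max"], df["mu_obs_max"]),
            "t_opt_vs_sst_mean": _maybe_regress(df["sst_mean"], df["t_opt"]),
            "t_opt_vs_sst_seasonal": {
                s: _maybe_regress(df[f"sst_{s}"], df["t_opt"])
                for s in SEASONS if f"sst_{s}" in df.columns
            },
            "width_vs_t_opt": _maybe_regress(df["t_opt"], df["width80"]),
            "width_vs_sst_sd": _maybe_regress(df["sst_sd"], df["width80"]),
            "width_vs_mu_max": _maybe_regress(df["mu_max"], df["width80"]),
        }
        report["regressions"] = regressions
        report["inputs"]["strains_csv"] = {"sha256": _file_digest(config.strains_csv),
                                           "n_strains": len(strains)}
        _stage(stage, config, n_regressions=len(regressions))
    except ThermonicheError as e:
        raise ThermonicheError(f"[stage {stage}] {e}") from e

    # ---- mantel (optional) -------------------------------------------------
    if config.alignment_fasta:
        stage = "mantel"
        try:
            from Bio import SeqIO

            seqs = {rec.id: str(rec.seq)
                    for rec in SeqIO.parse(config.alignment_fasta, "fasta")}
            _check_labels("alignment", seqs, "strains_csv", strains["strain_id"])
            order = sorted(seqs)
            gen = pc.p_distance_matrix({k: seqs[k] for k in order})
            coords = {r.strain_id: (r.lat_dd, r.lon_dd)
                      for r in strains.itertuples()}
            geo = pc.geographic_distance_matrix({k: coords[k] for k in order})
            report["mantel"] = pc.mantel_test(
                gen, geo, n_perm=config.n_perm, seed=config.seed
            )
            gen.to_dataframe().to_csv(out_dir / "p_distances.csv")
            geo.to_dataframe().to_csv(out_dir / "geo_distances.csv")
            _stage(stage, config, n=len(order))
        except ThermonicheError as e:
            raise ThermonicheError(f"[stage {stage}] {e}") from e

    report["outputs"] = {"rates_csv": str(rates_path), "tpc_fits_csv": str(tpc_path)}
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["outputs"]["report_json"] = str(report_path)
    return report


def _window_arg(window):
    if isinstance(window, (list, tuple)):
        return (float(window[0]), float(window[1]))
    return window
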