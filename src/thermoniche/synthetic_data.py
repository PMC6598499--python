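"""Seeded generators for trees, phylogenetically structured thermal traits,
and noisy multi-temperature growth experiments.

The panel generator encodes the statistical structure the downstream
analysis assumes: a thermal optimum evolving with strong phylogenetic
signal, maximum growth rate increasing with the optimum ("hotter is
better"), niche width increasing with the optimum, and a site temperature
covariate linearly coupled to the optimum — all with known, recoverable
coefficients written to a truth record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError, SpecError, TreeError
from .growth_kinetics import FluorescenceSeries
from .phylo_comparative import lambda_transform, phylo_vcv, write_tree
from .thermal_response import ThermalCurveParams, blanchard_rate, performance_range

__all__ = [
    "PanelSpec",
    "StrainPanel",
    "simulate_tree",
    "simulate_trait",
    "generate_strain_panel",
    "simulate_growth_experiment",
    "simulate_panel_f0",
    "write_panel",
]

#: bump when generator output changes for identical seeds
GENERATOR_VERSION = "1.0"

SEASONS = ("winter", "spring", "summer", "autumn")


@dataclass(frozen=True)
class PanelSpec:
    """Knobs for the synthetic strain panel.

    Default slopes and ranges follow the empirical relationships the
    pipeline is meant to recover: optima spanning 9-27 C, ~0.05
    divisions/day of extra maximum growth and ~0.26 C of extra 80%-niche
    width per degree of thermal optimum, and a 0.6 C shift in optimum per
    degree of site temperature.
    """

    n_strains: int = 24
    temperatures: tuple = (0.5, 5.0, 10.0, 15.0, 20.0, 25.0, 33.0)
    n_replicates: int = 4
    trait_lambda: float = 0.94
    topt_range: tuple = (9.0, 27.0)
    hotter_slope: float = 0.05   # divisions/day per degree C of t_opt
    mu_base: float = 0.2         # divisions/day at t_opt = 0 (extrapolated)
    width_slope: float = 0.26    # degrees of 80% width per degree of t_opt
    width_base: float = 4.0      # width at t_opt = 0 (extrapolated)
    tmax_offset: float = 10.0    # t_max - t_opt
    sst_slope: float = 0.6       # degrees of t_opt per degree of SST
    sst_intercept: float = 9.0   # t_opt at SST = 0
    sst_scatter: float = 1.5     # C, Gaussian scatter on synthetic SST
    noise_sigma: float = 0.05    # lognormal sigma on F0
    n_days: int = 5
    f0_start: float = 3000.0     # fluorescence units, ~3000 cells/ml
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 2 or self.n_replicates < 1:
            raise DataError("counts must be positive (n_strains >= 2)")
        if not self.topt_range[0] < self.topt_range[1]:
            raise DataError("topt_range low must be below high")
        if self.noise_sigma < 0:
            raise DataError("noise_sigma must be >= 0")


@dataclass
class StrainPanel:
    """Generated panel: tree, true curve parameters, metadata, truth record."""

    tree: dendropy.Tree
    curve_params: dict          # strain_id -> ThermalCurveParams
    strains: pd.DataFrame       # metadata incl. synthetic SST
    truth: dict
    spec: PanelSpec


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_tree(n_tips: int, seed=None) -> dendropy.Tree:
    """Yule (pure-birth) tree with root-to-tip depth rescaled to 1.

    Tips are labeled ``S01``, ``S02``, ... in the order they were created.
    Bit-reproducible for a fixed seed.
    """
    if n_tips < 2:
        raise DataError(f"need at least 2 tips, got {n_tips}")
    rng = _rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, t))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(), t))
    t_final = t + rng.exponential(1.0 / n_tips)
    width = len(str(n_tips))
    for j, (node, born) in enumerate(active):
        node.edge.length = t_final - born
    for j, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"S{j + 1:0{width}d}")
    # rescale to unit depth (tree is ultrametric by construction)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t_final
    return tree


def simulate_trait(tree, sigma2: float, root_state: float, lam: float = 1.0, seed=None) -> dict:
    """One MVN draw with mean ``root_state`` and covariance sigma2 * C(lambda)."""
    if sigma2 < 0:
        raise DataError("sigma2 must be >= 0")
    if not (0.0 <= lam <= 1.0):
        raise DataError("lambda must be in [0, 1]")
    cov = phylo_vcv(tree, warn_non_ultrametric=False)
    diag = np.diag(cov.matrix)
    if np.ptp(diag) > 1e-6 * max(diag.max(), 1e-300):
        raise TreeError("simulate_trait requires an ultrametric tree")
    labels = cov.labels
    if sigma2 == 0:
        return {l: float(root_state) for l in labels}
    rng = _rng(seed)
    V = sigma2 * lambda_transform(cov.matrix, lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    y = root_state + L @ rng.standard_normal(len(labels))
    return {l: float(v) for l, v in zip(labels, y)}


def _solve_beta_for_width(t_opt, t_max, mu_max, target_width, fraction=0.8):
    """Bisection on beta so the fraction-level niche width hits the target."""

    def width(beta):
        p = ThermalCurveParams(mu_max=mu_max, t_opt=t_opt, t_max=t_max, beta=beta)
        return performance_range(p, fraction).width

    lo, hi = 1e-3, 1e3
    w_lo, w_hi = width(lo), width(hi)
    if not (w_hi <= target_width <= w_lo):
        raise SpecError(
            f"target width {target_width:.2f} C infeasible for t_max offset "
            f"{t_max - t_opt:.1f} C (attainable: [{w_hi:.3f}, {w_lo:.3f}]); "
            "increase tmax_offset"
        )
    return float(optimize.brentq(lambda b: width(b) - target_width, lo, hi, xtol=1e-10))


def generate_strain_panel(spec: PanelSpec) -> StrainPanel:
    """Generate the tree, true thermal curves, and strain metadata.

    The thermal optimum is a lambda-structured Brownian trait rescaled
    affinely into ``spec.topt_range`` (rank order preserved, so the signal
    structure survives the rescaling).  mu_max and the 80%-width follow
    linear functions of the optimum; beta is solved numerically so each
    curve attains its target width given ``t_max = t_opt + tmax_offset``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = simulate_tree(spec.n_strains, rng)
    raw = simulate_trait(tree, sigma2=1.0, root_state=0.0, lam=spec.trait_lambda, seed=rng)
    labels = list(raw)
    vals = np.array([raw[l] for l in labels])
    lo, hi = spec.topt_range
    if np.ptp(vals) == 0:
        topt = np.full(vals.size, (lo + hi) / 2)
    else:
        topt = lo + (vals - vals.min()) / np.ptp(vals) * (hi - lo)

    curve_params = {}
    rows = []
    for sid, t_opt in zip(labels, topt):
        t_opt = float(t_opt)
        mu_max = spec.mu_base + spec.hotter_slope * t_opt
        t_max = t_opt + spec.tmax_offset
        target_width = spec.width_base + spec.width_slope * t_opt
        beta = _solve_beta_for_width(t_opt, t_max, mu_max, target_width)
        params = ThermalCurveParams(
            mu_max=mu_max, t_opt=t_opt, t_max=t_max, beta=beta, strain_id=sid
        )
        curve_params[sid] = params

        sst_mean = (t_opt - spec.sst_intercept) / spec.sst_slope + rng.normal(0, spec.sst_scatter)
        amp = rng.uniform(0.5, 3.0)
        seasonal = sst_mean + amp * np.array([-1.5, -0.5, 0.5, 1.5])
        rng.shuffle(seasonal)
        lat = float(np.clip((1 if rng.random() < 0.5 else -1) * (70.0 - 2.2 * sst_mean)
                            + rng.normal(0, 5.0), -78.0, 78.0))
        lon = float(rng.uniform(-180.0, 180.0))
        zone = "polar" if t_opt < 13 else ("temperate" if t_opt < 22 else "tropical")
        row = dict(
            strain_id=sid,
            lat_dd=lat,
            lon_dd=lon,
            climate_zone=zone,
            sst_mean=float(np.mean(seasonal)),
            sst_sd=float(np.std(seasonal, ddof=1)),
        )
        for s, v in zip(SEASONS, seasonal):
            row[f"sst_{s}"] = float(v)
        rows.append(row)

    strains = pd.DataFrame(rows)
    truth = {
        "generator_version": GENERATOR_VERSION,
        "seed": spec.seed,
        "trait_lambda": spec.trait_lambda,
        "hotter_slope": spec.hotter_slope,
        "mu_base": spec.mu_base,
        "width_slope": spec.width_slope,
        "width_base": spec.width_base,
        "sst_slope": spec.sst_slope,
        "sst_intercept": spec.sst_intercept,
        "tmax_offset": spec.tmax_offset,
        "noise_sigma": spec.noise_sigma,
        "strains": {
            sid: {
                "mu_max": p.mu_max,
                "t_opt": p.t_opt,
                "t_max": p.t_max,
                "beta": p.beta,
                "width80": spec.width_base + spec.width_slope * p.t_opt,
            }
            for sid, p in curve_params.items()
        },
    }
    return StrainPanel(tree=tree, curve_params=curve_params, strains=strains,
                       truth=truth, spec=spec)


def simulate_growth_experiment(params: ThermalCurveParams, spec: PanelSpec, seed=None) -> list:
    """Noisy F0 time series for one strain at every temperature x replicate.

    F0 grows exponentially at the curve's rate and carries multiplicative
    lognormal measurement noise per observation:
    f0(t) = f0(0) * 2**(mu(T) * t) * exp(N(0, noise_sigma^2)).
    """
    rng = _rng(seed)
    times = np.arange(spec.n_days + 1, dtype=float)
    out = []
    for T in spec.temperatures:
        mu = blanchard_rate(T, params.mu_max, params.t_opt, params.t_max, params.beta)
        for rep in range(1, spec.n_replicates + 1):
            clean = spec.f0_start * np.power(2.0, mu * times)
            if spec.noise_sigma > 0:
                noise = np.exp(rng.normal(0.0, spec.noise_sigma, size=times.size))
            else:
                noise = 1.0
            out.append(
                FluorescenceSeries(
                    strain_id=params.strain_id,
                    temperature=float(T),
                    replicate=rep,
                    times=tuple(times),
                    f0=tuple(clean * noise),
                )
            )
    return out


def simulate_panel_f0(panel: StrainPanel) -> list:
    """F0 series for every strain in the panel (seeded from the panel spec)."""
    ss = np.random.SeedSequence(panel.spec.seed)
    children = ss.spawn(len(panel.curve_params) + 1)
    out = []
    for child, sid in zip(children[1:], sorted(panel.curve_params)):
        rng = np.random.default_rng(child)
        out.extend(simulate_growth_experiment(panel.curve_params[sid], panel.spec, rng))
    return out


def write_panel(panel: StrainPanel, outdir) -> dict:
    """Emit f0.csv, tree.nwk, strains.csv and truth.json; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = simulate_panel_f0(panel)
    rows = []
    for s in series:
        for t, v in zip(s.times, s.f0):
            rows.append(dict(strain_id=s.strain_id, temperature_c=s.temperature,
                             replicate=s.replicate, time_days=t, f0=v))
    f0_path = outdir / "f0.csv"
    pd.DataFrame(rows).to_csv(f0_path, index=False)
    tree_path = outdir / "tree.nwk"
    write_tree(panel.tree, tree_path)
    strains_path = outdir / "strains.csv"
    panel.strains.to_csv(strains_path, index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(panel.truth, indent=2, sort_keys=True))
    return {"f0": str(f0_path), "tree": str(tree_path),
            "strains": str(strains_path), "truth": str(truth_path)}
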