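"""End-to-end pipeline: simulate -> covariates -> fit -> evaluate -> density.

The pipeline simulates two wildfire locations from a shared true selection
function, fits per-location and pooled maximum-entropy and weighted-logistic
models, evaluates every model at every location by bootstrapped AUC, and
calibrates pooled-model HSIs against hatched-nest densities with spatial
block-bootstrap CIs.  All outputs are plain CSV/JSON (plus TIFF HSI maps),
every artifact records the seed and a hash of the configuration, and a fixed
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import burnhab
from burnhab import density as dens
from burnhab import evaluate as ev
from burnhab import maxent as mx
from burnhab import wlr
from burnhab.landscape import LandscapeParams, SelectionParams, generate_landscape, simulate_sites
from burnhab.rasters import RasterStack, write_raster, write_sites

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-landscape run."""

    seed: int = 0
    locations: tuple[str, str] = ("locA", "locB")
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    run_maxent: bool = True
    run_wlr: bool = True
    dnbr_threshold: float = 270.0
    canopy_threshold: float = 10.0
    landscape_radius_m: float = 1000.0
    contribution_threshold: float = 5.0
    delta_aicc_threshold: float = 2.0
    maxent_beta: float = 1.0
    n_boot_auc: int = 2000
    n_boot_density: int = 5000
    ci_level: float = 0.95
    hsi_thresholds: tuple[float, float] | None = None  # None -> natural breaks
    outdir: str = "burnhab_out"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded,
        so reruns into different directories are comparable)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "landscape" in raw:
            raw["landscape"] = LandscapeParams(**raw["landscape"])
        if "selection" in raw:
            raw["selection"] = SelectionParams(**raw["selection"])
        for key in ("locations", "hsi_thresholds"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sub_seed(seed: int, *tags: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(("/".join(map(str, tags)) + f"#{seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _covariate_kwargs(cfg: PipelineConfig) -> dict:
    return dict(
        dnbr_threshold=cfg.dnbr_threshold,
        canopy_threshold=cfg.canopy_threshold,
        landscape_radius_m=cfg.landscape_radius_m,
    )


def simulate_locations(cfg: PipelineConfig) -> dict[str, tuple[RasterStack, pd.DataFrame]]:
    out = {}
    for loc in cfg.locations:
        lp = dataclasses.replace(cfg.landscape, seed=_sub_seed(cfg.seed, "landscape", loc))
        sp = dataclasses.replace(cfg.selection, seed=_sub_seed(cfg.seed, "sites", loc))
        landscape = generate_landscape(lp)
        sites = simulate_sites(landscape, sp, location=loc, **_covariate_kwargs(cfg))
        out[loc] = (landscape, sites)
    return out


def _fit_wlr_location(sites: pd.DataFrame, cfg: PipelineConfig,
                      weights: np.ndarray | None = None,
                      candidates: list[str] | None = None) -> wlr.ModelRanking:
    data = sites[sites["role"].isin(["nest", "non-nest"])].copy()
    data["y"] = (data["role"] == "nest").astype(float)
    if weights is None:
        weights = wlr.observation_weights(data["y"].to_numpy())
    if candidates is None:
        candidates = burnhab.ALL_COVARIATES
    n_nests = int(data["y"].sum())
    subsets = wlr.enumerate_candidates(candidates, n_nests=n_nests)
    fits = [wlr.fit_wlr(data, s, weights) for s in subsets]
    return wlr.rank_models(fits)


def _fit_maxent_location(sites: pd.DataFrame, cfg: PipelineConfig) -> mx.MaxentModel:
    pres = sites[sites["role"] == "nest"]
    bg = sites[sites["role"] == "available"]
    fs = mx.FeatureSet.from_background(bg, burnhab.REMOTE_COVARIATES)
    model = mx.fit_maxent(pres, bg, fs, beta=cfg.maxent_beta)
    model.contributions = mx.variable_contribution(model, pres, bg, beta=cfg.maxent_beta)
    return mx.retain_and_refit(model, pres, bg, beta=cfg.maxent_beta,
                               threshold=cfg.contribution_threshold)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``cfg.outdir``.

    Returns the in-memory bundle (models, rankings, AUC matrix, density
    tables) for programmatic use.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log: dict = {"seed": cfg.seed, "config_hash": chash, "version": burnhab.__version__,
                 "stages": {}}
    sims = simulate_locations(cfg)
    all_sites = pd.concat([s for _, s in sims.values()], ignore_index=True)
    all_sites.insert(0, "config_hash", chash)
    write_sites(all_sites, outdir / "sites.csv")
    all_sites = all_sites.drop(columns="config_hash")
    log["stages"]["simulate"] = {
        loc: {r: int((s["role"] == r).sum()) for r in ("nest", "non-nest", "available")}
        for loc, (_, s) in sims.items()
    }

    bundle: dict = {"sites": all_sites, "config": cfg}
    models: dict[tuple[str, str], object] = {}

    if cfg.run_wlr:
        rankings = {}
        for loc, (_, sites) in sims.items():
            rankings[loc] = _fit_wlr_location(sites, cfg)
            models[("wlr", loc)] = rankings[loc].best
        pooled_covs = wlr.pooled_candidate_covariates(
            list(rankings.values()), cfg.delta_aicc_threshold)
        data = all_sites[all_sites["role"].isin(["nest", "non-nest"])].copy()
        data["y"] = (data["role"] == "nest").astype(float)
        base_w = np.concatenate([
            wlr.observation_weights(
                (data.loc[data["location"] == loc, "y"]).to_numpy())
            for loc in cfg.locations
        ])
        pooled_w, scalars = wlr.make_pooled_weights(base_w, data["location"].to_numpy())
        subsets = wlr.enumerate_candidates(
            pooled_covs, n_nests=int(data["y"].sum()))
        fits = [wlr.fit_wlr(data, s, pooled_w) for s in subsets]
        pooled_ranking = wlr.rank_models(fits)
        rankings["pooled"] = pooled_ranking
        models[("wlr", "pooled")] = pooled_ranking.best
        bundle["wlr_rankings"] = rankings
        tables = []
        for name, r in rankings.items():
            t = r.table().head(20)
            t.insert(0, "developed_at", name)
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(outdir / "wlr_ranking.csv", index=False)
        best = pooled_ranking.best
        pd.DataFrame({"parameter": best.params.index, "estimate": best.params.to_numpy(),
                      "se": best.bse.to_numpy()}).to_csv(
            outdir / "wlr_top_model_coefficients.csv", index=False)
        log["stages"]["wlr"] = {
            "pooled_candidates": pooled_covs, "pooled_weight_scalars": scalars,
            "n_excluded_fits": {k: r.n_excluded for k, r in rankings.items()},
        }

    if cfg.run_maxent:
        mx_models = {}
        for loc, (_, sites) in sims.items():
            mx_models[loc] = _fit_maxent_location(sites, cfg)
            models[("maxent", loc)] = mx_models[loc]
        balanced = mx.balance_background(all_sites, seed=_sub_seed(cfg.seed, "balance"))
        mx_models["pooled"] = _fit_maxent_location(balanced, cfg)
        models[("maxent", "pooled")] = mx_models["pooled"]
        bundle["maxent_models"] = mx_models
        for name, m in mx_models.items():
            (outdir / f"maxent_{name}.json").write_text(m.to_json())
        for loc, (landscape, _) in sims.items():
            from burnhab.landscape import pixel_covariates
            cov = pixel_covariates(landscape, **_covariate_kwargs(cfg))
            hsi = mx_models["pooled"].logistic(cov).reshape(landscape.shape)
            write_raster(
                RasterStack({"hsi": hsi}, landscape.pixel_size, landscape.origin,
                            meta={"seed": cfg.seed, "config_hash": chash}),
                outdir / f"hsi_map_{loc}.tif")
        log["stages"]["maxent"] = {
            name: m.contributions for name, m in mx_models.items()
        }

    rows = []
    for (kind, dev), model in models.items():
        ref_role = "non-nest" if kind == "wlr" else "available"
        for loc in cfg.locations:
            res = ev.cross_apply(
                model, sims[loc][1], reference_role=ref_role,
                n_boot=cfg.n_boot_auc, level=cfg.ci_level,
                seed=_sub_seed(cfg.seed, "auc", kind, dev, loc),
                development=(dev == loc),
            )
            rows.append({
                "model": kind, "developed_at": dev, "applied_at": loc,
                "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "transferable": ev.transferable(res), "development": res.development,
            })
    auc_matrix = pd.DataFrame(rows)
    auc_matrix.to_csv(outdir / "auc_matrix.csv", index=False)
    bundle["auc_matrix"] = auc_matrix

    total_area_ha = (
        sims[cfg.locations[0]][0].shape[0] * sims[cfg.locations[0]][0].shape[1]
        * (cfg.landscape.pixel_size / 100.0) ** 2
    )
    density_tables, curves = [], []
    for kind in [k for k, flag in (("wlr", cfg.run_wlr), ("maxent", cfg.run_maxent)) if flag]:
        ref_role = "non-nest" if kind == "wlr" else "available"
        model = models[(kind, "pooled")]
        for loc in cfg.locations:
            sites = sims[loc][1]
            hatched = sites[(sites["role"] == "nest") & (sites["hatched"] == 1.0)]
            ref = sites[sites["role"] == ref_role]
            nest_hsi = model.score(hatched)
            ref_hsi = model.score(ref)
            curve = dens.moving_window_density(nest_hsi, ref_hsi, total_area_ha)
            curves.append(pd.DataFrame({
                "model": kind, "location": loc, "hsi_mid": curve.mids,
                "density": curve.densities,
            }))
            thresholds = cfg.hsi_thresholds or dens.suggest_thresholds(curve)
            classes = dens.block_bootstrap_density(
                nest_hsi, hatched["cell_id"].to_numpy(),
                ref_hsi, ref["cell_id"].to_numpy(),
                thresholds, total_area_ha,
                n_boot=cfg.n_boot_density, level=cfg.ci_level,
                seed=_sub_seed(cfg.seed, "density", kind, loc),
            )
            t = classes.table()
            t.insert(0, "model", kind)
            t.insert(1, "location", loc)
            t.insert(2, "t1", thresholds[0])
            t.insert(3, "t2", thresholds[1])
            density_tables.append(t)
            bundle.setdefault("density", {})[(kind, loc)] = classes
    if density_tables:
        pd.concat(density_tables, ignore_index=True).to_csv(
            outdir / "density_classes.csv", index=False)
        pd.concat(curves, ignore_index=True).to_csv(outdir / "density_curves.csv", index=False)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    bundle["log"] = log
    return bundle
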