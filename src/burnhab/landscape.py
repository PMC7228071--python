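"""Synthetic burned-landscape generator and site sampler.

Generates co-registered raster layers (burn severity dNBR, pre-fire canopy
cover, ponderosa-pine mask, slope, aspect, and 50-m-plot-scale snag/tree
density fields) as marginally transformed Gaussian random fields, then places
nest, non-nest and available sites with the sampling structure the analysis
assumes:

* nests by a weighted draw whose log-weight is a linear predictor on the true
  covariates (log-linear selection), one nest per pixel,
* non-nests uniformly over pixels that are at least ``min_separation`` m from
  every nest and hold at least one medium-or-large (>= 25 cm DBH) snag in
  their 50-m plot,
* available sites uniformly at random over the landscape.

Hatch outcomes are i.i.d. Bernoulli, independent of covariates, and every
site carries the ID of the 600-m grid cell containing it (the spatial
bootstrap unit downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from burnhab.covariates import remote_covariate_stack
from burnhab.rasters import RasterStack

__all__ = ["LandscapeParams", "SelectionParams", "generate_landscape", "simulate_sites"]

#: Layer names of a generated landscape stack.
LANDSCAPE_LAYERS = [
    "dnbr", "canopy", "pine", "slope", "aspect",
    "sng_mid", "sng_lrg", "tree", "pipo_pct",
]

CELL_SIZE_M = 600.0


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the synthetic landscape.

    Marginal defaults emulate burned dry-conifer forest: mean dNBR around the
    moderate/severe boundary so roughly 60% of pixels are burned (> 270),
    canopy cover 0-100% with a point mass at 0 for pre-fire openings, a
    ponderosa-dominance probability near 0.65, slope in percent, aspect in
    degrees, and zero-inflated gamma snag/tree densities per ha measured at
    the 50-m plot scale.  ``corr_range_m`` (per layer, metres) sets the
    spatial correlation length of the underlying Gaussian fields; 0 gives
    white noise.
    """

    shape: tuple[int, int] = (150, 150)
    pixel_size: float = 30.0
    corr_range_m: dict[str, float] = field(default_factory=lambda: {
        "dnbr": 600.0, "canopy": 600.0, "pine": 300.0,
        "slope": 400.0, "aspect": 400.0,
        "sng_mid": 60.0, "sng_lrg": 60.0, "tree": 150.0, "pipo_pct": 150.0,
    })
    dnbr_mean: float = 330.0
    dnbr_sd: float = 230.0
    canopy_zero_prob: float = 0.15
    canopy_beta: tuple[float, float] = (2.0, 2.5)
    pine_prob: float = 0.65
    slope_mean: float = 15.0
    slope_sd: float = 10.0
    slope_max: float = 60.0
    sng_mid_mean: float = 60.0
    sng_mid_sd: float = 45.0
    sng_mid_zero_prob: float = 0.05
    sng_lrg_mean: float = 10.0
    sng_lrg_sd: float = 11.0
    sng_lrg_zero_prob: float = 0.30
    tree_mean: float = 35.0
    tree_sd: float = 55.0
    tree_zero_prob: float = 0.25
    pipo_pct_mean: float = 45.0
    pipo_pct_sd: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name, p in [
            ("canopy_zero_prob", self.canopy_zero_prob),
            ("pine_prob", self.pine_prob),
            ("sng_mid_zero_prob", self.sng_mid_zero_prob),
            ("sng_lrg_zero_prob", self.sng_lrg_zero_prob),
            ("tree_zero_prob", self.tree_zero_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, v in [
            ("sng_mid_mean", self.sng_mid_mean), ("sng_lrg_mean", self.sng_lrg_mean),
            ("tree_mean", self.tree_mean),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SelectionParams:
    """True nest-placement model and sampling design.

    Nest log-weights are ``intercept + coef . (LocBrnOpn, LandBrnOpn,
    TreeDens, PIPO_pct)`` evaluated on the true per-pixel covariates.  The
    default coefficients carry the sign structure of selection for locally
    burned/open sites inside less-burned home ranges with few live trees and
    more ponderosa pine.
    """

    coef: dict[str, float] = field(default_factory=lambda: {
        "LocBrnOpn": 0.015, "LandBrnOpn": -0.037, "TreeDens": -0.009, "PIPO_pct": 0.012,
    })
    intercept: float = 0.0
    hatch_prob: float = 0.94
    n_nest: int = 47
    n_nonnest: int = 176
    n_available: int = 10_000
    min_separation_m: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hatch_prob <= 1.0:
            raise ValueError("hatch_prob must be in [0, 1]")
        for name, n in [("n_nest", self.n_nest), ("n_nonnest", self.n_nonnest),
                        ("n_available", self.n_available)]:
            if n < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_separation_m < 0:
            raise ValueError("min_separation_m must be >= 0")


def _gaussian_field(rng: np.random.Generator, shape, range_m: float, pixel_size: float) -> np.ndarray:
    """Standard-normal random field with correlation length ~range_m.

    Kernel-smoothed white noise (wrap boundary), re-standardised empirically;
    range 0 returns the raw white noise so marginals are exact."""
    z = rng.standard_normal(shape)
    if range_m > 0:
        sigma = range_m / pixel_size / 2.0
        z = ndimage.gaussian_filter(z, sigma, mode="wrap")
        z = (z - z.mean()) / z.std()
    return z


def _zero_inflated_gamma(u: np.ndarray, mean: float, sd: float, zero_prob: float) -> np.ndarray:
    """Quantile transform of uniforms to a zero-inflated gamma marginal."""
    out = np.zeros_like(u)
    pos = u >= zero_prob
    if mean <= 0 or sd <= 0:
        return out
    k = (mean / sd) ** 2
    theta = sd**2 / mean
    out[pos] = stats.gamma.ppf((u[pos] - zero_prob) / (1.0 - zero_prob), a=k, scale=theta)
    return out


def generate_landscape(params: LandscapeParams) -> RasterStack:
    """Generate the raster stack; bit-reproducible given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    z = {name: _gaussian_field(rng, params.shape, params.corr_range_m.get(name, 0.0), px)
         for name in LANDSCAPE_LAYERS}
    u = {name: stats.norm.cdf(zi) for name, zi in z.items()}

    a, b = params.canopy_beta
    canopy = np.where(
        u["canopy"] < params.canopy_zero_prob,
        0.0,
        100.0 * stats.beta.ppf(
            np.clip((u["canopy"] - params.canopy_zero_prob) / (1.0 - params.canopy_zero_prob), 0, 1),
            a, b,
        ),
    )
    slope_k = (params.slope_mean / params.slope_sd) ** 2
    slope_theta = params.slope_sd**2 / params.slope_mean
    slope = np.clip(stats.gamma.ppf(u["slope"], a=slope_k, scale=slope_theta), 0, params.slope_max)

    m, s = params.pipo_pct_mean / 100.0, params.pipo_pct_sd / 100.0
    nu = max(m * (1 - m) / s**2 - 1.0, 0.1)
    pipo_pct = 100.0 * stats.beta.ppf(u["pipo_pct"], m * nu, (1 - m) * nu)

    layers = {
        "dnbr": params.dnbr_mean + params.dnbr_sd * z["dnbr"],
        "canopy": canopy,
        "pine": (u["pine"] < params.pine_prob).astype(float),
        "slope": slope,
        "aspect": 360.0 * u["aspect"],
        "sng_mid": _zero_inflated_gamma(
            u["sng_mid"], params.sng_mid_mean, params.sng_mid_sd, params.sng_mid_zero_prob),
        "sng_lrg": _zero_inflated_gamma(
            u["sng_lrg"], params.sng_lrg_mean, params.sng_lrg_sd, params.sng_lrg_zero_prob),
        "tree": _zero_inflated_gamma(
            u["tree"], params.tree_mean, params.tree_sd, params.tree_zero_prob),
        "pipo_pct": pipo_pct,
    }
    return RasterStack(layers=layers, pixel_size=px, meta={"seed": params.seed})


def cell_ids(x: np.ndarray, y: np.ndarray, cell_size_m: float = CELL_SIZE_M) -> np.ndarray:
    """ID of the 600-m grid cell containing each point (lower-left inclusive),
    anchored at the raster origin."""
    ix = np.floor(np.asarray(x) / cell_size_m).astype(int)
    iy = np.floor(np.asarray(y) / cell_size_m).astype(int)
    return np.char.add(np.char.add(ix.astype(str), "_"), iy.astype(str))


def pixel_covariates(landscape: RasterStack, **covariate_kwargs) -> pd.DataFrame:
    """True covariates of every pixel (row-major flat order)."""
    remote = remote_covariate_stack(landscape, **covariate_kwargs)
    cols = {name: remote[name].ravel() for name in
            ("Slope", "Casp", "LocBrnOpn", "LandBrnOpn", "LandPIPO")}
    cols["SngMidDens"] = landscape["sng_mid"].ravel()
    cols["SngLrgDens"] = landscape["sng_lrg"].ravel()
    cols["TreeDens"] = landscape["tree"].ravel()
    cols["PIPO_pct"] = landscape["pipo_pct"].ravel()
    return pd.DataFrame(cols)


def simulate_sites(
    landscape: RasterStack,
    sel: SelectionParams,
    location: str = "locA",
    year: int = 1,
    **covariate_kwargs,
) -> pd.DataFrame:
    """Sample nest / non-nest / available sites from a landscape.

    Returns a site table with coordinates, role, covariates, hatched flag
    (nests only), and 600-m cell ID.  Raises ``ValueError`` with the shortfall
    when the separation and snag constraints leave too few eligible pixels
    for the requested non-nests.
    """
    rng = np.random.default_rng(sel.seed)
    cov = pixel_covariates(landscape, **covariate_kwargs)
    xs, ys = landscape.pixel_centers()
    n_pix = len(cov)

    eta = np.full(n_pix, sel.intercept)
    for name, b in sel.coef.items():
        eta += b * cov[name].to_numpy()
    w = np.exp(eta - eta.max())
    p = w / w.sum()
    nest_idx = rng.choice(n_pix, size=sel.n_nest, replace=False, p=p)

    eligible = (cov["SngMidDens"].to_numpy() + cov["SngLrgDens"].to_numpy()) > 0
    if sel.n_nest > 0 and sel.min_separation_m > 0:
        tree_nn = cKDTree(np.column_stack([xs[nest_idx], ys[nest_idx]]))
        dist, _ = tree_nn.query(np.column_stack([xs, ys]))
        eligible &= dist >= sel.min_separation_m
    eligible[nest_idx] = False
    n_eligible = int(eligible.sum())
    if n_eligible < sel.n_nonnest:
        raise ValueError(
            f"cannot place {sel.n_nonnest} non-nests: only {n_eligible} eligible pixels "
            f"(shortfall {sel.n_nonnest - n_eligible}) after the "
            f"{sel.min_separation_m} m separation and snag-presence filters"
        )
    nonnest_idx = rng.choice(np.flatnonzero(eligible), size=sel.n_nonnest, replace=False)
    avail_idx = rng.choice(n_pix, size=min(sel.n_available, n_pix), replace=False)

    idx = np.concatenate([nest_idx, nonnest_idx, avail_idx])
    role = np.array(
        ["nest"] * sel.n_nest + ["non-nest"] * sel.n_nonnest + ["available"] * len(avail_idx)
    )
    df = cov.iloc[idx].reset_index(drop=True)
    df.insert(0, "id", [f"{location}-{r}-{i}" for i, r in enumerate(role)])
    df.insert(1, "x", xs[idx])
    df.insert(2, "y", ys[idx])
    df.insert(3, "role", role)
    df.insert(4, "location", location)
    df.insert(5, "year", year)
    df.insert(6, "cell_id", cell_ids(xs[idx], ys[idx]))
    hatched = np.full(len(df), np.nan)
    hatched[: sel.n_nest] = (rng.random(sel.n_nest) < sel.hatch_prob).astype(float)
    df["hatched"] = hatched
    # center-tree species flag drawn from the local pine share
    df["PIPO"] = (rng.random(len(df)) < df["PIPO_pct"].to_numpy() / 100.0).astype(float)
    return df
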