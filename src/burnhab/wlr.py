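"""Weighted logistic regression (use vs. non-use) with AICc subset selection.

Nest sites (y = 1) keep weight 1 and non-nest sites (y = 0) are down-weighted
by w0 = n1/n0, so the weighted prevalence is exactly 0.5 and the fitted
response is a relative habitat suitability index rather than an absolute
probability of use.  Candidate models are all covariate subsets up to a cap
of one covariate per 10 nests (rounded up), compared by small-sample
corrected AIC:

    AICc = -2 logL_w + 2K + 2K(K+1) / (n - K - 1)

with K the parameter count including the intercept and n the number of
observations.  Model fitting is iteratively reweighted least squares via
statsmodels GLM (binomial family, frequency weights); standard errors come
from the weighted Fisher information.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DELTA_AICC_THRESHOLD = 2.0  # inclusive


@dataclass(frozen=True)
class Weights:
    """The nest/non-nest weighting scheme: w1 = 1, w0 = n1/n0."""

    n1: int
    n0: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n0 <= 0:
            raise ValueError("both class counts must be positive")

    @property
    def w1(self) -> float:
        return 1.0

    @property
    def w0(self) -> float:
        return self.n1 / self.n0


def make_weights(n1: int, n0: int) -> Weights:
    return Weights(n1=n1, n0=n0)


def observation_weights(y: np.ndarray, weights: Weights | None = None) -> np.ndarray:
    """Per-observation weight vector for a 0/1 response."""
    y = np.asarray(y)
    if weights is None:
        weights = make_weights(int(y.sum()), int((1 - y).sum()))
    return np.where(y == 1, weights.w1, weights.w0)


def make_pooled_weights(
    base_weights: np.ndarray, locations: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Rescale one location's weights so per-location weight sums are equal.

    All observations of the location with the larger weight sum are multiplied
    by a single scalar (smaller sum / larger sum).  Returns the adjusted
    weights and the per-location scalars applied.
    """
    base_weights = np.asarray(base_weights, dtype=float)
    locations = np.asarray(locations)
    uniq = pd.unique(locations)
    if len(uniq) == 1:
        logger.warning("make_pooled_weights called with a single location; identity")
        return base_weights.copy(), {str(uniq[0]): 1.0}
    if len(uniq) != 2:
        raise ValueError(f"pooled weighting is defined for two locations, got {len(uniq)}")
    sums = {loc: base_weights[locations == loc].sum() for loc in uniq}
    big = max(sums, key=sums.get)
    small = min(sums, key=sums.get)
    scalar = sums[small] / sums[big] if sums[big] > 0 else 1.0
    out = base_weights.copy()
    out[locations == big] *= scalar
    return out, {str(big): scalar, str(small): 1.0}


@dataclass
class WLRFit:
    """One fitted candidate: subset, logit-scale coefficients, AICc."""

    covariates: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    aicc: float
    n_obs: int
    converged: bool = True
    separated: bool = False

    def predict_hsi(self, sites: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(sites))] + [sites[c].to_numpy(dtype=float) for c in self.covariates]
        )
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    score = predict_hsi


def aicc(llf: float, k: int, n_obs: int) -> float:
    """Small-sample corrected AIC."""
    if n_obs <= k + 1:
        raise ValueError(f"AICc undefined for n_obs={n_obs} <= K+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def fit_wlr(
    sites: pd.DataFrame,
    subset,
    weights: np.ndarray | Weights | None = None,
    y_col: str = "y",
) -> WLRFit:
    """Fit one weighted logistic regression on a covariate subset.

    First-order linear terms only.  Perfect separation (non-convergence or
    exploding coefficients/SEs) is flagged on the returned fit rather than
    raised, so subset enumeration can skip it; a singular design raises.
    """
    subset = tuple(subset)
    y = sites[y_col].to_numpy(dtype=float)
    if isinstance(weights, Weights) or weights is None:
        w = observation_weights(y, weights)
    else:
        w = np.asarray(weights, dtype=float)
    X = np.column_stack(
        [np.ones(len(sites))] + [sites[c].to_numpy(dtype=float) for c in subset]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design for subset {subset}")
    names = ["Intercept"] + list(subset)
    k = len(names)
    separated = False
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
            maxiter=200, tol=1e-10
        )
        converged = bool(res.converged)
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        llf = float(res.llf)
        if not converged or np.abs(params).max() > 1e3 or not np.isfinite(bse).all() \
                or bse.max() > 1e4:
            separated = True
    except Exception as exc:  # statsmodels raises on hopeless separation
        logger.info("fit failed for subset %s: %s", subset, exc)
        params = pd.Series(np.nan, index=names)
        bse = pd.Series(np.nan, index=names)
        llf = -np.inf
        converged = False
        separated = True
    return WLRFit(
        covariates=subset, params=params, bse=bse, llf=llf, k=k,
        aicc=aicc(llf, k, len(sites)) if np.isfinite(llf) else np.inf,
        n_obs=len(sites), converged=converged, separated=separated,
    )


def enumerate_candidates(
    covariates, n_nests: int | None = None, cap: int | None = None
) -> list[tuple[str, ...]]:
    """All covariate subsets of size 0..cap, cap = ceil(n_nests / 10).

    Deterministic order: size-major, lexicographic by covariate position.
    Includes the intercept-only (empty) subset.
    """
    covariates = list(covariates)
    if cap is None:
        if n_nests is None:
            cap = len(covariates)
        else:
            cap = math.ceil(n_nests / 10)
    cap = min(cap, len(covariates))
    out: list[tuple[str, ...]] = []
    for size in range(cap + 1):
        out.extend(itertools.combinations(covariates, size))
    return out


@dataclass
class ModelRanking:
    """Candidates ordered by AICc with deltas and Akaike weights."""

    fits: list[WLRFit]
    delta_aicc: np.ndarray
    akaike_weights: np.ndarray
    n_excluded: int = 0

    @property
    def best(self) -> WLRFit:
        return self.fits[0]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariates": [" + ".join(f.covariates) or "Intercept-only" for f in self.fits],
            "K": [f.k for f in self.fits],
            "logL": [f.llf for f in self.fits],
            "AICc": [f.aicc for f in self.fits],
            "dAICc": self.delta_aicc,
            "weight": self.akaike_weights,
        })


def rank_models(fits: list[WLRFit]) -> ModelRanking:
    """Rank successful fits by AICc (ties: smaller K, then lexicographic)."""
    ok = [f for f in fits if not f.separated and np.isfinite(f.aicc)]
    n_excluded = len(fits) - len(ok)
    if n_excluded:
        logger.info("excluded %d separation-failed candidate fits from ranking", n_excluded)
    if not ok:
        raise ValueError("no successful fits to rank")
    ok.sort(key=lambda f: (f.aicc, f.k, f.covariates))
    a = np.array([f.aicc for f in ok])
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    return ModelRanking(fits=ok, delta_aicc=delta, akaike_weights=w / w.sum(),
                        n_excluded=n_excluded)


def within_top(ranking: ModelRanking, delta: float = DELTA_AICC_THRESHOLD) -> list[WLRFit]:
    """Fits within ``delta`` AICc units of the best model (inclusive)."""
    return [f for f, d in zip(ranking.fits, ranking.delta_aicc) if d <= delta]


def pooled_candidate_covariates(
    rankings: list[ModelRanking], delta: float = DELTA_AICC_THRESHOLD
) -> list[str]:
    """Union of covariates in any within-delta model across locations,
    in first-appearance order."""
    out: list[str] = []
    for ranking in rankings:
        for fit in within_top(ranking, delta):
            for c in fit.covariates:
                if c not in out:
                    out.append(c)
    if not out:
        raise ValueError("pooled candidate covariate set is empty")
    return out


def vif(sites: pd.DataFrame, covariates) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per covariate (unweighted OLS).

    Exact collinearity is reported as ``inf``.
    """
    covariates = list(covariates)
    if len(covariates) < 2:
        raise ValueError("VIF requires at least two covariates")
    out = {}
    for j, c in enumerate(covariates):
        others = [o for o in covariates if o != c]
        X = np.column_stack(
            [np.ones(len(sites))] + [sites[o].to_numpy(dtype=float) for o in others]
        )
        yj = sites[c].to_numpy(dtype=float)
        coef, _, _, _ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ coef
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
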