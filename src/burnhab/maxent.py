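"""Presence-background maximum-entropy habitat model.

Fits the Gibbs distribution q(x) proportional to exp(sum_j lambda_j f_j(x))
over a finite background sample, choosing coefficients to maximise the
L1-penalised mean log-likelihood of the presence sites:

    l(lambda) = lambda . fbar_presence - log Z_background(lambda)
                - sum_j beta_j |lambda_j|

The objective is concave; it is solved as a smooth bound-constrained problem
by splitting each coefficient into positive and negative parts (L-BFGS-B with
analytic gradient).  At beta = 0 the optimum satisfies the moment-matching
constraints E_q[f_j] = fbar_presence_j.

Features are linear, quadratic and pairwise-product terms of the base
covariates, each rescaled to [0, 1] over the training background; prediction
clamps features to the training bounds.  Habitat suitability uses the
logistic transform HSI = e^H q / (1 + e^H q), where H is the entropy of the
fitted background distribution, so a site with the typical probability mass
q = e^-H scores 0.5.

The per-variable contribution is a leave-variable-out gain drop: refit
without all features involving the variable and report the loss of penalised
training gain, normalised to sum to 100 across variables.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

CONTRIBUTION_THRESHOLD = 5.0  # percent gain


@dataclass(frozen=True)
class FeatureSet:
    """Linear + quadratic + pairwise-product expansion with [0, 1] scaling.

    ``bounds`` are per-covariate (min, max) over the training background; the
    same bounds clamp covariates at prediction time.
    """

    covariates: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    quadratic: bool = True
    products: bool = True

    @classmethod
    def from_background(
        cls, background: pd.DataFrame, covariates, quadratic: bool = True, products: bool = True
    ) -> "FeatureSet":
        covariates = tuple(covariates)
        bounds = {}
        for c in covariates:
            lo, hi = float(background[c].min()), float(background[c].max())
            bounds[c] = (lo, hi)
        return cls(covariates, bounds, quadratic, products)

    @property
    def names(self) -> list[str]:
        out = [f"lin:{c}" for c in self.covariates]
        if self.quadratic:
            out += [f"quad:{c}" for c in self.covariates]
        if self.products:
            out += [f"prod:{a}*{b}" for a, b in itertools.combinations(self.covariates, 2)]
        return out

    def variables_of(self, name: str) -> tuple[str, ...]:
        kind, rest = name.split(":", 1)
        return tuple(rest.split("*")) if kind == "prod" else (rest,)

    def transform(self, sites: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        scaled = {}
        for c in self.covariates:
            lo, hi = self.bounds[c]
            x = sites[c].to_numpy(dtype=float)
            if clamp:
                n_out = int(((x < lo) | (x > hi)).sum())
                if n_out:
                    logger.info("clamping %d values of %s to training bounds", n_out, c)
                x = np.clip(x, lo, hi)
            scaled[c] = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
        cols = [scaled[c] for c in self.covariates]
        if self.quadratic:
            cols += [scaled[c] ** 2 for c in self.covariates]
        if self.products:
            cols += [scaled[a] * scaled[b] for a, b in itertools.combinations(self.covariates, 2)]
        return np.column_stack(cols)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    features: FeatureSet
    feature_names: list[str]
    lam: np.ndarray
    penalties: np.ndarray
    log_z: float  # log sum over background of exp(lambda . f)
    entropy: float  # H of the fitted background distribution
    n_background: int
    gain: float  # penalised training gain over the uniform model
    contributions: dict[str, float] = field(default_factory=dict)

    def raw(self, sites: pd.DataFrame) -> np.ndarray:
        """Gibbs probability mass exp(lambda . f - log Z); sums to 1 over the
        training background."""
        F = self.features.transform(sites)
        return np.exp(F @ self.lam - self.log_z)

    def logistic(self, sites: pd.DataFrame) -> np.ndarray:
        """HSI in (0, 1): e^H q / (1 + e^H q)."""
        eq = np.exp(self.entropy) * self.raw(sites)
        return eq / (1.0 + eq)

    # cross-location evaluation protocol
    score = logistic

    def to_json(self) -> str:
        return json.dumps({
            "covariates": list(self.features.covariates),
            "bounds": {k: list(v) for k, v in self.features.bounds.items()},
            "quadratic": self.features.quadratic,
            "products": self.features.products,
            "coefficients": dict(zip(self.feature_names, self.lam.tolist())),
            "penalties": self.penalties.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "gain": self.gain,
            "contributions": self.contributions,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        fs = FeatureSet(
            tuple(d["covariates"]), {k: tuple(v) for k, v in d["bounds"].items()},
            d["quadratic"], d["products"],
        )
        names = list(d["coefficients"])
        return cls(
            features=fs, feature_names=names,
            lam=np.array([d["coefficients"][n] for n in names]),
            penalties=np.array(d["penalties"]), log_z=d["log_z"], entropy=d["entropy"],
            n_background=d["n_background"], gain=d["gain"],
            contributions=d.get("contributions", {}),
        )


def _solve(F_bg, f_pres_mean, penalties, tol, max_iter):
    """Maximise the penalised presence log-likelihood over lambda."""
    n_feat = F_bg.shape[1]

    def negobj(uv):
        lam = uv[:n_feat] - uv[n_feat:]
        a = F_bg @ lam
        lz = logsumexp(a)
        q = np.exp(a - lz)
        ll = lam @ f_pres_mean - lz
        grad_lam = f_pres_mean - q @ F_bg
        g = np.concatenate([-grad_lam + penalties, grad_lam + penalties])
        return -(ll - penalties @ (uv[:n_feat] + uv[n_feat:])), g

    res = minimize(
        negobj, np.zeros(2 * n_feat), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * n_feat),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and "ROUND" not in str(res.message).upper():
        raise RuntimeError(f"maxent optimisation failed to converge: {res.message}")
    return res.x[:n_feat] - res.x[n_feat:]


def fit_maxent(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    features: FeatureSet,
    beta: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> MaxentModel:
    """Fit the penalised maximum-entropy model.

    ``beta`` is a dimensionless multiplier: the L1 penalty on feature j is
    ``beta * sd_background(f_j) / sqrt(n_presence)``, so regularisation
    relaxes with presence sample size.  ``beta = 0`` gives exact moment
    matching; very large beta shrinks every coefficient to 0 (uniform model).
    Constant features over the background are dropped with a warning.
    """
    if len(presence) < 1:
        raise ValueError("at least one presence site is required")
    if len(background) < len(presence):
        raise ValueError("background must be at least as large as the presence sample")
    names = features.names
    F_bg = features.transform(background, clamp=False)
    F_pres = features.transform(presence, clamp=True)

    sd = F_bg.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant features over background: {dropped}")
    names = [n for n, k in zip(names, keep) if k]
    F_bg, F_pres, sd = F_bg[:, keep], F_pres[:, keep], sd[keep]

    penalties = beta * sd / np.sqrt(len(presence))
    lam = _solve(F_bg, F_pres.mean(axis=0), penalties, tol, max_iter)

    a = F_bg @ lam
    log_z = float(logsumexp(a))
    q = np.exp(a - log_z)
    entropy = float(-(q * np.log(q)).sum())
    n = len(background)
    # penalised mean presence log-likelihood improvement over the uniform model
    gain = float(
        lam @ F_pres.mean(axis=0) - log_z + np.log(n) - penalties @ np.abs(lam)
    )
    return MaxentModel(
        features=features, feature_names=names, lam=lam, penalties=penalties,
        log_z=log_z, entropy=entropy, n_background=n, gain=gain,
    )


def variable_contribution(
    model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame, beta: float = 1.0
) -> dict[str, float]:
    """Percent-of-gain contribution per covariate (leave-variable-out).

    Contribution of v = gain(full) - gain(refit without every feature
    involving v), floored at 0 and normalised to sum to 100.
    """
    covs = model.features.covariates
    if len(covs) == 1:
        return {covs[0]: 100.0}
    drops = {}
    for v in covs:
        reduced = FeatureSet(
            tuple(c for c in covs if c != v),
            {c: b for c, b in model.features.bounds.items() if c != v},
            model.features.quadratic, model.features.products,
        )
        sub = fit_maxent(presence, background, reduced, beta=beta)
        drops[v] = max(model.gain - sub.gain, 0.0)
    total = sum(drops.values())
    if total == 0:
        return {v: 100.0 / len(covs) for v in covs}
    return {v: 100.0 * d / total for v, d in drops.items()}


def retain_and_refit(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    beta: float = 1.0,
    threshold: float = CONTRIBUTION_THRESHOLD,
) -> MaxentModel:
    """Single-pass retention: drop covariates contributing < threshold % gain,
    refit on the survivors."""
    contrib = model.contributions or variable_contribution(model, presence, background, beta)
    kept = [v for v in model.features.covariates if contrib[v] >= threshold]
    if not kept:
        raise ValueError(
            f"no covariate reaches the {threshold}% contribution threshold: {contrib}"
        )
    if len(kept) == len(model.features.covariates):
        model.contributions = contrib
        return model
    reduced = FeatureSet(
        tuple(kept), {c: model.features.bounds[c] for c in kept},
        model.features.quadratic, model.features.products,
    )
    refit = fit_maxent(presence, background, reduced, beta=beta)
    refit.contributions = variable_contribution(refit, presence, background, beta)
    return refit


def balance_background(
    sites: pd.DataFrame, seed: int = 0, role_col: str = "role", location_col: str = "location"
) -> pd.DataFrame:
    """Subsample available (background) sites so their per-location proportions
    match the per-location proportions of nest sites, for pooled fits."""
    rng = np.random.default_rng(seed)
    nests = sites[sites[role_col] == "nest"]
    avail = sites[sites[role_col] == "available"]
    other = sites[~sites[role_col].isin(["available"])]
    nest_prop = nests[location_col].value_counts(normalize=True)
    # largest feasible background preserving the nest proportions
    n_total = int(min(
        avail[avail[location_col] == loc].shape[0] / p for loc, p in nest_prop.items()
    ))
    parts = []
    for loc, p in nest_prop.items():
        pool = avail[avail[location_col] == loc]
        take = int(round(p * n_total))
        parts.append(pool.iloc[rng.choice(len(pool), size=min(take, len(pool)), replace=False)])
    return pd.concat([other] + parts, ignore_index=True)
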