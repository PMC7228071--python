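"""Discrimination accuracy and cross-location transferability.

AUC is the Mann-Whitney estimator P(score_nest > score_reference) + 1/2
P(tie); confidence intervals are stratified percentile bootstrap (resampling
within class).  A model is called transferable at a location when the lower
95% CI limit for AUC exceeds 0.5 (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_pos: int
    n_neg: int
    seed: int
    level: float = 0.95
    development: bool | None = None  # evaluated at the model's own data?

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid AUC result: ci=({self.ci_low}, {self.ci_high}), auc={self.auc}"
            )


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC; ties count 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def bootstrap_auc_ci(
    pos_scores,
    neg_scores,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    development: bool | None = None,
) -> AUCResult:
    """Stratified percentile-bootstrap CI for AUC; reproducible given seed."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    point = auc(pos, neg)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = auc(
            pos[rng.integers(0, len(pos), len(pos))],
            neg[rng.integers(0, len(neg), len(neg))],
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    # the percentile interval need not contain the point estimate exactly
    return AUCResult(
        auc=point, ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
        n_boot=n_boot, n_pos=len(pos), n_neg=len(neg), seed=seed, level=level,
        development=development,
    )


def cross_apply(
    model,
    sites: pd.DataFrame,
    reference_role: str = "non-nest",
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    development: bool = False,
) -> AUCResult:
    """Apply a fitted model at a (possibly different) location and score it.

    ``model`` must expose ``score(sites) -> ndarray`` (both the weighted
    logistic fit and the maximum-entropy model do).  The positive class is
    nests; the reference class is non-nests for the logistic model and
    available sites for the maximum-entropy model.
    """
    needed = getattr(model, "covariates", None) or getattr(
        getattr(model, "features", None), "covariates", ()
    )
    missing = [c for c in needed if c not in sites.columns]
    if missing:
        raise ValueError(f"target sites are missing model covariates: {missing}")
    pos = sites[sites["role"] == "nest"]
    ref = sites[sites["role"] == reference_role]
    if len(pos) == 0 or len(ref) == 0:
        raise ValueError(
            f"need both nests and {reference_role!r} sites at the target location"
        )
    return bootstrap_auc_ci(
        model.score(pos), model.score(ref),
        n_boot=n_boot, level=level, seed=seed, development=development,
    )


def transferable(result: AUCResult) -> bool:
    """True iff the lower CI limit strictly exceeds 0.5."""
    return result.ci_low > 0.5
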