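"""Calibration of HSIs against hatched-nest densities.

Reference sites (available sites for the maximum-entropy model, non-nest
sites for the weighted logistic model) are assumed to represent the area
surveyed, so the share of reference sites in an HSI interval estimates the
share of surveyed area there.  Hatched-nest density in an interval is then
(hatched nests in interval) / (area share x total surveyed area).

The module provides:

* an equal-area moving-window density curve along the HSI gradient,
* three suitability classes (low / moderate / high) from two thresholds,
  lower-inclusive ([t1, t2) is moderate, >= t2 is high),
* per-class density, expected percent of nests under equal-area sampling,
  and area surveyed,
* spatial block-bootstrap CIs resampling 600-m grid cells with replacement,
  with median-unbiased (type-8) quantile endpoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_LABELS = ("low", "moderate", "high")
N_BOOT_DEFAULT = 5000


@dataclass
class DensityCurve:
    """Moving-window hatched-nest densities along the HSI gradient."""

    mids: np.ndarray  # median reference HSI per window
    densities: np.ndarray  # hatched nests per ha
    window_frac: float
    step_frac: float


@dataclass
class SuitabilityClasses:
    """Per-class density calibration in the style of a management table."""

    thresholds: tuple[float, float]
    labels: tuple[str, ...]
    density: np.ndarray
    percent_nests: np.ndarray
    area_ha: np.ndarray
    n_nests: np.ndarray
    density_ci: np.ndarray | None = None  # (3, 2)
    percent_ci: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "class": self.labels,
            "density": self.density,
            "percent_nests": self.percent_nests,
            "area_ha": self.area_ha,
            "n_nests": self.n_nests,
        })
        if self.density_ci is not None:
            df["density_lo"] = self.density_ci[:, 0]
            df["density_hi"] = self.density_ci[:, 1]
        if self.percent_ci is not None:
            df["percent_lo"] = self.percent_ci[:, 0]
            df["percent_hi"] = self.percent_ci[:, 1]
        return df


def quantile_type8(x, p):
    """Median-unbiased quantile (plotting position (k - 1/3) / (n + 1/3))."""
    return np.quantile(np.asarray(x, dtype=float), p, method="median_unbiased")


def moving_window_density(
    nest_hsi,
    reference_hsi,
    total_area_ha: float,
    window_frac: float = 0.1,
    step_frac: float = 0.01,
) -> DensityCurve:
    """Equal-area moving-window density curve.

    Windows span contiguous ``window_frac`` shares of the sorted reference
    HSIs (equal estimated area), advanced by ``step_frac``.  A window's HSI
    span runs from its first reference value (inclusive) to the first
    reference value beyond it (exclusive); the outermost windows extend to
    +/- infinity, so with ``step_frac == window_frac`` the windows tile the
    HSI axis and every nest is counted exactly once.  Pass hatched nests only.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    if not 0 < step_frac <= window_frac:
        raise ValueError("step_frac must be in (0, window_frac]")
    if total_area_ha <= 0:
        raise ValueError("total_area_ha must be > 0")
    ref = np.sort(np.asarray(reference_hsi, dtype=float))
    nests = np.asarray(nest_hsi, dtype=float)
    n = len(ref)
    if n == 0:
        raise ValueError("reference HSIs must be non-empty")
    win_n = max(1, int(round(window_frac * n)))
    step_n = max(1, int(round(step_frac * n)))
    starts = list(range(0, n - win_n + 1, step_n))
    if starts[-1] != n - win_n:
        starts.append(n - win_n)
    mids, dens = [], []
    window_area = window_frac * total_area_ha
    for j, a in enumerate(starts):
        lo = -np.inf if a == 0 else ref[a]
        hi = np.inf if a + win_n >= n else ref[a + win_n]
        count = int(((nests >= lo) & (nests < hi)).sum())
        mids.append(float(np.median(ref[a: a + win_n])))
        dens.append(count / window_area)
    return DensityCurve(
        mids=np.array(mids), densities=np.array(dens),
        window_frac=window_frac, step_frac=step_frac,
    )


def classify(hsi, thresholds) -> np.ndarray:
    """Class index per HSI: 0 low (< t1), 1 moderate ([t1, t2)), 2 high (>= t2)."""
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError(f"thresholds must satisfy t1 < t2, got {thresholds}")
    h = np.asarray(hsi, dtype=float)
    return np.where(h < t1, 0, np.where(h < t2, 1, 2))


def percent_nests(densities) -> np.ndarray:
    """Expected percent of hatched nests per class under equal-area sampling:
    100 * density_c / sum(density)."""
    d = np.asarray(densities, dtype=float)
    total = np.nansum(d)
    if total == 0:
        return np.zeros_like(d)
    return 100.0 * d / total


def _class_counts(hsi, thresholds) -> np.ndarray:
    return np.bincount(classify(hsi, thresholds), minlength=3).astype(float)


def class_summaries(
    nest_hsi,
    reference_hsi,
    thresholds,
    total_area_ha: float,
) -> SuitabilityClasses:
    """Density, percent-nests and area surveyed per suitability class.

    ``nest_hsi`` must be hatched nests only.  A class holding no reference
    sites has zero area and an undefined density (NaN, flagged by a warning).
    """
    if total_area_ha <= 0:
        raise ValueError("total_area_ha must be > 0")
    n_ref = _class_counts(reference_hsi, thresholds)
    n_nest = _class_counts(nest_hsi, thresholds)
    share = n_ref / n_ref.sum()
    area = share * total_area_ha
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(area > 0, n_nest / area, np.nan)
    if (area == 0).any():
        empty = [CLASS_LABELS[i] for i in range(3) if area[i] == 0]
        warnings.warn(f"no reference sites in class(es) {empty}; density undefined there")
    return SuitabilityClasses(
        thresholds=tuple(thresholds), labels=CLASS_LABELS,
        density=density, percent_nests=percent_nests(density),
        area_ha=area, n_nests=n_nest,
    )


def suggest_thresholds(curve: DensityCurve) -> tuple[float, float]:
    """Advisory thresholds at the two largest density increases of the curve.

    User-specified thresholds always override these.  A flat curve yields the
    tertile HSIs with a warning.
    """
    if len(curve.mids) < 3:
        raise ValueError("need at least three windows to suggest thresholds")
    d = curve.densities
    if np.ptp(d) < 1e-12:
        warnings.warn("density curve is flat; returning tertile HSIs")
        return tuple(np.quantile(curve.mids, [1 / 3, 2 / 3]))
    jumps = np.diff(d)
    top2 = np.sort(np.argsort(jumps)[-2:])
    t = [(curve.mids[i] + curve.mids[i + 1]) / 2.0 for i in top2]
    if np.isclose(t[0], t[1]):
        warnings.warn("two largest density breaks coincide; returning tertile HSIs")
        return tuple(np.quantile(curve.mids, [1 / 3, 2 / 3]))
    return (float(t[0]), float(t[1]))


def block_bootstrap_density(
    nest_hsi,
    nest_cells,
    reference_hsi,
    reference_cells,
    thresholds,
    total_area_ha: float,
    n_boot: int = N_BOOT_DEFAULT,
    level: float = 0.95,
    seed: int = 0,
) -> SuitabilityClasses:
    """Class summaries with spatial block-bootstrap CIs.

    The sampling unit is the 600-m grid cell: cells (with all their nests and
    reference sites) are resampled with replacement, preserving the cell
    count; class densities and percent-nests are recomputed per resample and
    the CI endpoints are type-8 (median-unbiased) quantiles.  A single cell
    gives a degenerate CI equal to the point estimate, with a warning.
    """
    point = class_summaries(nest_hsi, reference_hsi, thresholds, total_area_ha)
    cells = pd.unique(np.concatenate([np.asarray(nest_cells), np.asarray(reference_cells)]))
    n_cells = len(cells)
    if n_cells == 1:
        warnings.warn("single bootstrap cell; CIs degenerate to the point estimate")
        point.density_ci = np.column_stack([point.density, point.density])
        point.percent_ci = np.column_stack([point.percent_nests, point.percent_nests])
        return point

    cell_index = {c: i for i, c in enumerate(cells)}
    nest_cls = classify(nest_hsi, thresholds)
    ref_cls = classify(reference_hsi, thresholds)
    nest_counts = np.zeros((n_cells, 3))
    ref_counts = np.zeros((n_cells, 3))
    for cell, cls in zip(np.asarray(nest_cells), nest_cls):
        nest_counts[cell_index[cell], cls] += 1
    for cell, cls in zip(np.asarray(reference_cells), ref_cls):
        ref_counts[cell_index[cell], cls] += 1

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n_cells, size=(n_boot, n_cells))
    boot_density = np.empty((n_boot, 3))
    boot_percent = np.empty((n_boot, 3))
    for b in range(n_boot):
        nc = nest_counts[picks[b]].sum(axis=0)
        rc = ref_counts[picks[b]].sum(axis=0)
        rtot = rc.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            area = rc / rtot * total_area_ha if rtot > 0 else np.zeros(3)
            boot_density[b] = np.where(area > 0, nc / area, np.nan)
        boot_percent[b] = percent_nests(boot_density[b])
    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        d_lo = np.array([quantile_type8(boot_density[~np.isnan(boot_density[:, c]), c], alpha)
                         if np.isfinite(boot_density[:, c]).any() else np.nan for c in range(3)])
        d_hi = np.array([quantile_type8(boot_density[~np.isnan(boot_density[:, c]), c], 1 - alpha)
                         if np.isfinite(boot_density[:, c]).any() else np.nan for c in range(3)])
        p_lo = np.array([quantile_type8(boot_percent[~np.isnan(boot_percent[:, c]), c], alpha)
                         for c in range(3)])
        p_hi = np.array([quantile_type8(boot_percent[~np.isnan(boot_percent[:, c]), c], 1 - alpha)
                         for c in range(3)])
    point.density_ci = np.column_stack([d_lo, d_hi])
    point.percent_ci = np.column_stack([p_lo, p_hi])
    return point
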