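"""Residual, variogram, and calibration diagnostics for fitted models.

Residual spatial structure is the main adjudicator between the candidate
models: a model that absorbs the spatial signal leaves a flat residual
variogram (nugget only), while a misspecified one shows semivariance
rising with distance.  Empirical variograms are computed from county
centroid distances one census year at a time and summarized by a weighted
least-squares Matern fit; predictive calibration is checked through the
uniformity of probability integral transform (PIT) values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .inference import FitResult
from .panel import PanelDataset

__all__ = [
    "VariogramEstimate",
    "PitSummary",
    "compute_residuals",
    "residual_table",
    "empirical_variogram",
    "residual_variogram",
    "matern_correlation",
    "matern_semivariance",
    "fit_matern_variogram",
    "pit_uniformity_summary",
]


@dataclass(frozen=True)
class VariogramEstimate:
    """Binned semivariances with an optional fitted Matern model.

    Semivariance in bin k is (1 / (2 N_k)) * sum over pairs in the bin of
    the squared residual difference.  Fitted parameters: nugget, partial
    sill, range (km), smoothness (chosen from a small candidate set), and
    the weighted-least-squares objective at the optimum.
    """

    bin_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    max_dist: float
    nugget: float | None = None
    partial_sill: float | None = None
    range_km: float | None = None
    smoothness: float | None = None
    objective: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class PitSummary:
    counts: np.ndarray
    expected: float
    chi_square: float
    dof: int


def compute_residuals(fit: FitResult, panel: PanelDataset) -> np.ndarray:
    """Posterior-predictive mean minus observed value, per observation."""
    y = panel.data["y"].to_numpy(float)
    if len(y) != fit.n_obs:
        raise ValueError("panel does not match the fitted model")
    return fit.mu_mean - y


def residual_table(fit: FitResult, panel: PanelDataset) -> pd.DataFrame:
    """(county, year, residual) table suitable for any mapping tool."""
    r = compute_residuals(fit, panel)
    return pd.DataFrame({
        "county_id": panel.data["county_id"],
        "year": panel.data["year"],
        "residual": r,
    })


def empirical_variogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 15,
    max_dist: float | None = None,
) -> VariogramEstimate:
    """Equal-width binned semivariogram of one year's residuals.

    ``coords`` is an (n, 2) array of planar centroid coordinates in km;
    ``max_dist`` defaults to half the maximum pairwise distance.  The
    estimate is invariant to observation order.
    """
    residuals = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if residuals.ndim != 1 or len(residuals) != len(coords):
        raise ValueError("residuals and coords must align")
    if len(residuals) < 2:
        raise ValueError("need at least 2 points for a variogram")
    d = pdist(coords)
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    sq = pdist(residuals[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:], right=True)
    inside = d <= max_dist
    counts = np.bincount(which[inside], minlength=n_bins)[:n_bins]
    sums = np.bincount(which[inside], weights=sq[inside], minlength=n_bins)[:n_bins]
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramEstimate(bin_centers=centers, semivariance=gamma,
                             pair_counts=counts, max_dist=max_dist)


def residual_variogram(
    fit: FitResult,
    panel: PanelDataset,
    year: int,
    n_bins: int = 15,
    max_dist: float | None = None,
) -> VariogramEstimate:
    """Variogram of one census year's residuals at the county centroids."""
    if panel.centroids is None:
        raise ValueError("panel has no centroids")
    r = compute_residuals(fit, panel)
    mask = (panel.data["year"] == year).to_numpy()
    if not mask.any():
        raise ValueError(f"no observations for year {year}")
    ids = panel.data.loc[mask, "county_id"]
    coords = panel.centroids.loc[ids, ["x_km", "y_km"]].to_numpy(float)
    return empirical_variogram(r[mask], coords, n_bins=n_bins, max_dist=max_dist)


def matern_correlation(h: np.ndarray, range_km: float, smoothness: float) -> np.ndarray:
    """Matern correlation at lag h for smoothness in {0.5, 1.5, 2.5}."""
    h = np.asarray(h, dtype=float)
    x = np.maximum(h, 0.0) / max(range_km, 1e-12)
    if smoothness == 0.5:
        return np.exp(-x)
    if smoothness == 1.5:
        s = np.sqrt(3.0) * x
        return (1.0 + s) * np.exp(-s)
    if smoothness == 2.5:
        s = np.sqrt(5.0) * x
        return (1.0 + s + s * s / 3.0) * np.exp(-s)
    raise ValueError("smoothness must be one of 0.5, 1.5, 2.5")


def matern_semivariance(h: np.ndarray, nugget: float, partial_sill: float,
                        range_km: float, smoothness: float) -> np.ndarray:
    """gamma(h) = nugget + partial_sill * (1 - Matern correlation)."""
    return nugget + partial_sill * (1.0 - matern_correlation(h, range_km, smoothness))


def fit_matern_variogram(
    vg: VariogramEstimate,
    smoothness_candidates: Sequence[float] = (0.5, 1.5, 2.5),
) -> VariogramEstimate:
    """Weighted least-squares Matern fit to a binned variogram.

    Weights are pair counts divided by the squared empirical semivariance
    (Cressie-style); smoothness is selected from the candidate set by the
    best objective.  An all-zero variogram returns a flagged nugget-only
    fit.  Deterministic given the inputs.
    """
    ok = (vg.pair_counts > 0) & np.isfinite(vg.semivariance)
    h = vg.bin_centers[ok]
    g = vg.semivariance[ok]
    n = vg.pair_counts[ok].astype(float)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-empty bins to fit a variogram")
    if np.allclose(g, 0.0):
        return replace(vg, nugget=0.0, partial_sill=0.0,
                       range_km=vg.max_dist / 10.0, smoothness=0.5,
                       objective=0.0, degenerate=True)

    floor = max(g[g > 0].min() * 1e-3, 1e-30)
    wts = np.sqrt(n) / np.maximum(g, floor)
    scale = g.mean()
    best = None
    for nu in smoothness_candidates:
        for r0 in (vg.max_dist / 10.0, vg.max_dist / 3.0, vg.max_dist):
            x0 = np.array([0.5 * scale, 0.5 * scale, r0])

            def resid(p, nu=nu):
                return wts * (matern_semivariance(h, p[0], p[1], p[2], nu) - g)

            sol = least_squares(
                resid, x0,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10.0 * vg.max_dist]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            obj = float(np.sum(sol.fun**2))
            if best is None or obj < best[0] - 1e-15:
                best = (obj, nu, sol.x)
    obj, nu, p = best
    return replace(vg, nugget=float(p[0]), partial_sill=float(p[1]),
                   range_km=float(p[2]), smoothness=float(nu),
                   objective=obj, degenerate=False)


def pit_uniformity_summary(pit_values: np.ndarray, n_bins: int = 20) -> PitSummary:
    """Histogram of PIT values with a chi-square statistic against uniformity.

    Under a calibrated model the PIT values are approximately uniform on
    [0, 1]; the statistic compares equal-width bin counts to their common
    expectation, with n_bins - 1 degrees of freedom.
    """
    pit = np.asarray(pit_values, dtype=float)
    if pit.size == 0:
        raise ValueError("empty PIT input")
    if np.any((pit < 0) | (pit > 1)):
        raise ValueError("PIT values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(pit, bins=edges)
    expected = pit.size / n_bins
    chi2 = float(np.sum((counts - expected) ** 2) / expected)
    return PitSummary(counts=counts, expected=expected, chi_square=chi2,
                      dof=n_bins - 1)


def plot_variogram(vg: VariogramEstimate, ax=None):  # pragma: no cover - optional plotting
    """Plot the binned semivariances and, if present, the Matern fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(vg.bin_centers, vg.semivariance, "o", label="empirical")
    if vg.nugget is not None:
        hh = np.linspace(0, vg.max_dist, 200)
        ax.plot(hh, matern_semivariance(hh, vg.nugget, vg.partial_sill,
                                        vg.range_km, vg.smoothness),
                "-", label=f"Matern (nu={vg.smoothness})")
    ax.set_xlabel("distance (km)")
    ax.set_ylabel("semivariance")
    ax.legend()
    return ax


def plot_pit_histogram(pit_values: np.ndarray, n_bins: int = 20, ax=None):  # pragma: no cover
    """PIT histogram with the uniform reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(pit_values, bins=np.linspace(0, 1, n_bins + 1), density=True)
    ax.axhline(1.0, ls="--", color="k")
    ax.set_xlabel("PIT")
    ax.set_ylabel("density")
    return ax
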