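"""Synthetic county-lattice panels with the structure the analysis assumes.

The generator stands in for the national county panel: a rook-adjacency
grid of "counties" observed over four census years, spatially smooth
covariates (crop shares, income, farm size, growing degree days, and the
proportion of land in cropland), and a response drawn from the latent
Gaussian model with a chosen random-effect configuration.  Default
parameter values are the posterior means of the best spatiotemporal model
(fixed effects, residual SD 0.054, AR1 coefficient 0.708, random-effect
SDs), so recovery experiments target those values.

Intrinsic CAR fields are drawn exactly from the Besag density restricted
to its positive-eigenvalue subspace via eigendecomposition of the
structure matrix; separable space-time fields use the Kronecker eigenbasis
of (AR1 precision) x (ICAR structure).  All randomness flows from a single
integer seed through numpy's PCG64 generator, so panels are bit-for-bit
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .models import build_ar1_precision, build_icar_structure
from .panel import (
    COVARIATES,
    DEFAULT_CENSUS_YEARS,
    AdjacencyGraph,
    PanelDataset,
    center_covariates,
)

__all__ = [
    "SimConfig",
    "TABLE_BETA",
    "make_grid_lattice",
    "icar_sample",
    "spacetime_sample",
    "simulate_covariates",
    "simulate_response",
    "simulate_censoring",
    "simulate_panel",
    "write_simulation",
]

#: Fixed-effect values of the best-fitting spatiotemporal model (posterior
#: means): intercept, the seven covariates in canonical order, and the
#: per-year trend.
TABLE_BETA: dict[str, float] = {
    "intercept": 0.265,
    "x_corn": 0.398,
    "x_cov": 0.605,
    "x_sw": 0.041,
    "x_income": 0.004,
    "x_size": 0.012,
    "x_gdd": 0.030,
    "x_crop": 0.050,
    "year": 0.005,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    Precisions are 1/SD^2 of the corresponding random-effect scales of the
    best model: exchangeable county SD 0.005, exchangeable year SD 0.008,
    space-time intercept scale 0.150.  ``generative_model`` selects which
    random-effect blocks are active (1: none; 4: iid county + iid year;
    5: adds a CAR x AR1 slope on proportion cropland; 6: adds a CAR x AR1
    intercept).
    """

    grid_rows: int = 20
    grid_cols: int = 20
    years: tuple[int, ...] = DEFAULT_CENSUS_YEARS
    seed: int = 0
    beta: Mapping[str, float] = field(default_factory=lambda: dict(TABLE_BETA))
    sigma: float = 0.054
    tau_space: float = 1.0 / 0.150**2
    rho: float = 0.708
    tau_iid_county: float = 1.0 / 0.005**2
    tau_iid_year: float = 1.0 / 0.008**2
    censor_prob: float = 0.0
    generative_model: int = 6

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        for name in ("tau_space", "tau_iid_county", "tau_iid_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ValueError("censor_prob must lie in [0, 1)")
        if self.generative_model not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"unknown generative_model {self.generative_model}")


def make_grid_lattice(rows: int, cols: int) -> tuple[AdjacencyGraph, pd.DataFrame]:
    """Rook-adjacency grid of counties with unit-km centroid spacing.

    Returns the graph (rows*cols nodes, rows*(cols-1) + cols*(rows-1)
    edges) and a centroid table indexed by county id.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    n = rows * cols
    ids = [f"c{k:04d}" for k in range(n)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            if c + 1 < cols:
                edges.append((k, k + 1))
            if r + 1 < rows:
                edges.append((k, k + cols))
    comps = _components_from_edges(n, edges)
    graph = AdjacencyGraph(node_ids=tuple(ids),
                           edges=tuple(sorted(edges)),
                           components=comps)
    cent = pd.DataFrame(
        {"x_km": [float(k % cols) for k in range(n)],
         "y_km": [float(k // cols) for k in range(n)]},
        index=pd.Index(ids, name="county_id"),
    )
    return graph, cent


def _components_from_edges(n, edges):
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)
    return tuple(tuple(sorted(g)) for g in
                 sorted(groups.values(), key=lambda g: min(g)))


def _state_ids(rows: int, cols: int, block: int = 5) -> list[str]:
    ids = []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"S{r // block}{c // block}")
    return ids


# ---------------------------------------------------------------------------
# Gaussian Markov random field draws
# ---------------------------------------------------------------------------

class _IcarBasis:
    """Eigendecomposition of the ICAR structure matrix, computed once."""

    def __init__(self, graph: AdjacencyGraph) -> None:
        w = build_icar_structure(graph).toarray()
        vals, vecs = np.linalg.eigh(w)
        pos = vals > 1e-9 * max(vals.max(), 1.0)
        self.eigvals = vals[pos]
        self.eigvecs = vecs[:, pos]
        self.n = graph.n_nodes


def icar_sample(basis: _IcarBasis, rng: np.random.Generator,
                tau: float = 1.0, size: int = 1) -> np.ndarray:
    """Draws from the intrinsic CAR density on its sum-to-zero subspace."""
    z = rng.standard_normal((size, basis.eigvals.size))
    fields = (z / np.sqrt(tau * basis.eigvals)) @ basis.eigvecs.T
    return fields[0] if size == 1 else fields


def spacetime_sample(basis: _IcarBasis, n_years: int, rho: float, tau: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One draw of a CAR x AR1 field, year-major, sum-to-zero per year.

    The precision is tau * kron(AR1(rho), W); eigenvalues factor as
    products of the AR1 precision and positive ICAR eigenvalues, so a draw
    is an independent Gaussian in the Kronecker eigenbasis.
    """
    p = build_ar1_precision(n_years, rho).toarray()
    lam, vec_t = np.linalg.eigh(p)
    z = rng.standard_normal((n_years, basis.eigvals.size))
    scale = 1.0 / np.sqrt(tau * np.outer(lam, basis.eigvals))
    coef = z * scale
    # field[t, i] = sum_{a,j} coef[a, j] vec_t[t, a] eigvecs[i, j]
    field = vec_t @ coef @ basis.eigvecs.T
    return field.reshape(-1)  # year-major


def _smooth_field(basis: _IcarBasis, rng: np.random.Generator, n_years: int,
                  s_spatial: float, s_iid: float, s_year: float) -> np.ndarray:
    """A standardized spatially smooth field with small temporal wobble.

    County-level ICAR draw (normalized to unit sample SD) plus iid jitter,
    shared across years, plus an independent smaller smooth perturbation
    per year.  Shape (n_years, n_counties).
    """
    base = icar_sample(basis, rng)
    base = base / max(base.std(), 1e-12)
    base = s_spatial * base + s_iid * rng.standard_normal(basis.n)
    out = np.tile(base, (n_years, 1))
    if s_year > 0:
        for t in range(n_years):
            pert = icar_sample(basis, rng)
            out[t] += s_year * pert / max(pert.std(), 1e-12)
    scale = np.sqrt(s_spatial**2 + s_iid**2 + s_year**2)
    return out / scale


def simulate_covariates(graph: AdjacencyGraph, config: SimConfig,
                        centroids: pd.DataFrame | None = None) -> PanelDataset:
    """Spatially autocorrelated covariates on the lattice (no response yet).

    Proportion-valued fields are logistic transforms of smooth Gaussian
    fields; the three crop shares are rescaled where needed so their sum
    stays below one; income, farm size and GDD are affine (or log-affine)
    transforms to ranges matching the national panel (income in thousand
    USD/ha, size in km^2 per operator, GDD in thousands of degree days).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    basis = _IcarBasis(graph)
    n_t = len(config.years)
    rows_cfg = {
        # name: (location, spatial SD, iid SD, yearly SD) on the latent scale
        "x_corn": (-1.10, 1.2, 0.3, 0.25),
        "x_cov": (-2.94, 1.5, 0.4, 0.25),
        "x_sw": (-0.85, 1.2, 0.3, 0.25),
        "x_crop": (-0.95, 1.3, 0.3, 0.20),
        "x_income": (0.0, 1.0, 0.3, 0.25),
        "x_size": (0.0, 1.0, 0.3, 0.20),
        "x_gdd": (0.0, 1.0, 0.1, 0.05),
    }
    latent = {}
    for name, (loc, s_sp, s_iid, s_yr) in rows_cfg.items():
        g = _smooth_field(basis, rng, n_t, s_sp, s_iid, s_yr)
        latent[name] = loc + g * np.sqrt(s_sp**2 + s_iid**2 + s_yr**2)

    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    corn = expit(latent["x_corn"])
    cov = expit(latent["x_cov"])
    sw = expit(latent["x_sw"])
    total = corn + cov + sw
    shrink = np.where(total > 0.95, 0.95 / total, 1.0)
    corn, cov, sw = corn * shrink, cov * shrink, sw * shrink
    crop = expit(latent["x_crop"])
    income = 0.61 + 0.9 * latent["x_income"]
    size = np.exp(0.07 + 0.65 * latent["x_size"])
    gdd = np.clip(3.2 + 1.1 * latent["x_gdd"], 0.3, 6.1)

    states = _state_ids(config.grid_rows, config.grid_cols)
    frames = []
    for t, year in enumerate(config.years):
        frames.append(pd.DataFrame({
            "county_id": graph.node_ids,
            "state_id": states,
            "year": year,
            "y": np.nan,
            "x_corn": corn[t], "x_cov": cov[t], "x_sw": sw[t],
            "x_income": income[t], "x_size": size[t], "x_gdd": gdd[t],
            "x_crop": crop[t],
        }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["county_id", "year"]).reset_index(drop=True)
    for f in ("y",) + COVARIATES:
        df[f"cens_{f}"] = False
    if centroids is None:
        _, centroids = make_grid_lattice(config.grid_rows, config.grid_cols)
    return PanelDataset(data=df, years=config.years, centroids=centroids)


def simulate_response(panel: PanelDataset, graph: AdjacencyGraph,
                      config: SimConfig) -> tuple[PanelDataset, dict]:
    """Draw the response from the configured generative process.

    Requires centered covariates (the fixed-effect values apply on the
    centered scale).  Returns the panel with ``y`` filled and a dictionary
    of realized latent effects for recovery testing.  The response is not
    clipped: the likelihood is Gaussian.
    """
    means = panel.data[list(COVARIATES)].mean()
    if not np.allclose(means, 0.0, atol=1e-8):
        raise ValueError("covariates must be centered before simulating the response")
    gm = config.generative_model
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    out = panel.copy()
    df = out.data
    n = len(df)
    beta = dict(TABLE_BETA)
    beta.update(config.beta)

    year_c = df["year"].to_numpy(float) - float(np.mean(panel.years))
    eta = np.full(n, beta["intercept"])
    for cov_name in COVARIATES:
        eta += beta[cov_name] * df[cov_name].to_numpy(float)
    eta += beta["year"] * year_c

    cidx = np.array([panel.county_index[c] for c in df["county_id"]])
    yidx = np.array([panel.years.index(int(t)) for t in df["year"]])
    n_c, n_t = panel.n_counties, len(panel.years)
    truth: dict = {"beta": beta, "sigma": config.sigma, "generative_model": gm}

    if gm >= 4:
        u_county = rng.standard_normal(n_c) / np.sqrt(config.tau_iid_county)
        u_year = rng.standard_normal(n_t) / np.sqrt(config.tau_iid_year)
        eta += u_county[cidx] + u_year[yidx]
        truth["u_county"] = u_county
        truth["u_year"] = u_year
    basis = _IcarBasis(graph) if gm in (5, 6) else None
    if gm == 5:
        u_st = spacetime_sample(basis, n_t, config.rho, config.tau_space, rng)
        eta += u_st[yidx * n_c + cidx] * df["x_crop"].to_numpy(float)
        truth["u_spacetime_slope"] = u_st
        truth["rho"] = config.rho
    if gm == 6:
        u_st = spacetime_sample(basis, n_t, config.rho, config.tau_space, rng)
        eta += u_st[yidx * n_c + cidx]
        truth["u_spacetime"] = u_st
        truth["rho"] = config.rho

    df["y"] = eta + config.sigma * rng.standard_normal(n)
    truth["eta"] = eta
    return out, truth


def simulate_censoring(panel: PanelDataset, config: SimConfig) -> PanelDataset:
    """Mask covariate entries independently with probability censor_prob.

    Emulates anonymity suppression in the source census (metrics withheld
    when derived from a single farm).  Masked values become NaN with their
    ``cens_*`` flag set; deterministic given the seed.
    """
    out = panel.copy()
    if config.censor_prob == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    df = out.data
    for cov in COVARIATES:
        mask = rng.uniform(size=len(df)) < config.censor_prob
        df.loc[mask, cov] = np.nan
        df.loc[mask, f"cens_{cov}"] = True
    return out


def simulate_panel(config: SimConfig) -> tuple[PanelDataset, AdjacencyGraph, dict]:
    """Generate a complete analysis-ready panel plus its generating truth.

    Covariates are drawn, centered, the response is simulated on the
    centered scale, the covariates are then returned to their natural
    units (adding the grand means back), and censoring is applied.  The
    returned panel is therefore *uncentered*: run the standard
    impute/filter/center preprocessing before fitting, exactly as for real
    data.
    """
    graph, cent = make_grid_lattice(config.grid_rows, config.grid_cols)
    covs = simulate_covariates(graph, config, centroids=cent)
    centered = center_covariates(covs)
    with_y, truth = simulate_response(centered, graph, config)
    df = with_y.data
    for cov_name in COVARIATES:
        df[cov_name] = df[cov_name] + centered.covariate_means[cov_name]
    truth["covariate_means"] = dict(centered.covariate_means)
    out = PanelDataset(data=df, years=config.years, centroids=cent)
    out = simulate_censoring(out, config)
    return out, graph, truth


def write_simulation(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write panel/adjacency/centroid files in the formats the reader expects."""
    from .panel import write_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, graph, truth = simulate_panel(config)
    paths = {
        "panel": out / "panel.csv",
        "adjacency": out / "adjacency.csv",
        "centroids": out / "centroids.csv",
    }
    write_panel(panel, paths["panel"])
    edges = pd.DataFrame(
        [(graph.node_ids[i], graph.node_ids[j]) for i, j in graph.edges],
        columns=["county_a", "county_b"],
    )
    edges.to_csv(paths["adjacency"], index=False)
    panel.centroids.reset_index().to_csv(paths["centroids"], index=False)
    return paths
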