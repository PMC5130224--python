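"""Declarative specifications of Models 1-6 and their linear-algebra parts.

The six competing models share a Gaussian likelihood with identity link and
seven fixed covariate effects; they differ in how they absorb spatial and
temporal structure:

* Model 1 - intercept + 7 covariates (a plain GLM).
* Model 2 - adds a state factor and a continuous year effect.
* Model 3 - adds state x cropland, year x cropland and state x year x
  cropland interactions.
* Model 4 - Model 1 + year effect + exchangeable (iid) county and year
  random intercepts.
* Model 5 - Model 4 + a spatially (ICAR) and temporally (AR1) structured
  random *slope* on proportion cropland (a spatially varying coefficient).
* Model 6 - Model 4 + a spatially and temporally structured random
  *intercept*.

Priors follow the conventional vague defaults: Normal(0, precision 0)
intercept, Normal(0, precision 0.001) fixed effects, Log-Gamma(1, 0.00005)
on every log precision, and Normal(0, precision 0.15) on the transformed
AR1 coefficient log((1 + rho) / (1 - rho)).

The intrinsic CAR (Besag) structure matrix is the unscaled graph Laplacian
D - W; the separable space-time precision is the Kronecker product of a
stationary unit-marginal-variance AR1 precision over years with that
Laplacian, subject to sum-to-zero constraints over counties within each
year and connected component.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import yaml

from .panel import COVARIATES, AdjacencyGraph, PanelDataset

__all__ = [
    "FixedEffectTerm",
    "LatentBlock",
    "ModelSpec",
    "make_model_spec",
    "build_design_matrix",
    "build_icar_structure",
    "build_ar1_precision",
    "ar1_pattern_matrices",
    "ar1_coefficients",
    "build_spacetime_precision",
    "spacetime_constraints",
]

LOG_GAMMA_PRIOR = (1.0, 0.00005)  # (shape, rate) on a precision
RHO_PRIOR = (0.0, 0.15)  # (mean, precision) on log((1+rho)/(1-rho))

LATENT_KINDS = ("iid_county", "iid_year", "icar_ar1_intercept", "icar_ar1_slope")
_FIXED_KINDS = ("intercept", "covariate", "year", "state",
                "year_x", "state_x", "state_year_x")


@dataclass(frozen=True)
class FixedEffectTerm:
    """One fixed-effect term of the linear predictor.

    ``kind`` selects how columns are produced: a single covariate column, a
    centered continuous year, reference-coded state indicators, or products
    of those with a covariate.  ``prior_precision`` 0 encodes the flat
    intercept prior.
    """

    name: str
    kind: str
    covariate: str | None = None
    prior_mean: float = 0.0
    prior_precision: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in _FIXED_KINDS:
            raise ValueError(f"unknown fixed-effect kind {self.kind!r}")
        if self.prior_precision < 0:
            raise ValueError("prior precision must be >= 0")


@dataclass(frozen=True)
class LatentBlock:
    """One random-effect block: exchangeable or separable space-time.

    Space-time blocks (``icar_ar1_*``) put an intrinsic CAR structure over
    counties whose effects evolve across census years as a stationary AR1
    process; slope blocks additionally name the covariate they multiply.
    """

    kind: str
    covariate: str | None = None
    precision_prior: tuple[float, float] = LOG_GAMMA_PRIOR
    rho_prior: tuple[float, float] = RHO_PRIOR

    def __post_init__(self) -> None:
        if self.kind not in LATENT_KINDS:
            raise ValueError(f"unknown latent block kind {self.kind!r}")
        if self.kind == "icar_ar1_slope" and not self.covariate:
            raise ValueError("slope blocks must name a covariate")

    @property
    def is_spacetime(self) -> bool:
        return self.kind.startswith("icar_ar1")


@dataclass(frozen=True)
class ModelSpec:
    """A complete model: fixed terms, latent blocks, Gaussian likelihood."""

    model_id: int
    fixed_terms: tuple[FixedEffectTerm, ...]
    latent_blocks: tuple[LatentBlock, ...] = ()
    error_precision_prior: tuple[float, float] = LOG_GAMMA_PRIOR

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "fixed_terms": [
                {"name": t.name, "kind": t.kind, "covariate": t.covariate,
                 "prior_mean": t.prior_mean, "prior_precision": t.prior_precision}
                for t in self.fixed_terms
            ],
            "latent_blocks": [
                {"kind": b.kind, "covariate": b.covariate,
                 "precision_prior": list(b.precision_prior),
                 "rho_prior": list(b.rho_prior)}
                for b in self.latent_blocks
            ],
            "priors": {"error_precision": list(self.error_precision_prior)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        terms = tuple(
            FixedEffectTerm(name=t["name"], kind=t["kind"],
                            covariate=t.get("covariate"),
                            prior_mean=t.get("prior_mean", 0.0),
                            prior_precision=t.get("prior_precision", 0.001))
            for t in d["fixed_terms"]
        )
        blocks = tuple(
            LatentBlock(kind=b["kind"], covariate=b.get("covariate"),
                        precision_prior=tuple(b.get("precision_prior", LOG_GAMMA_PRIOR)),
                        rho_prior=tuple(b.get("rho_prior", RHO_PRIOR)))
            for b in d.get("latent_blocks", [])
        )
        err = tuple(d.get("priors", {}).get("error_precision", LOG_GAMMA_PRIOR))
        return cls(model_id=int(d["model_id"]), fixed_terms=terms,
                   latent_blocks=blocks, error_precision_prior=err)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def make_model_spec(
    model_id: int,
    panel: PanelDataset | None = None,
    graph: AdjacencyGraph | None = None,
) -> ModelSpec:
    """Build the specification for one of Models 1-6.

    Models 5 and 6 require the adjacency ``graph``; AR1 blocks require at
    least two census years in the panel.
    """
    if model_id not in range(1, 7):
        raise ValueError(f"model_id must be 1..6, got {model_id}")
    if model_id in (5, 6):
        if graph is None:
            raise ValueError(f"Model {model_id} requires an adjacency graph")
        if panel is not None and len(panel.years) < 2:
            raise ValueError("AR1 blocks require at least 2 census years")

    base = [FixedEffectTerm("intercept", "intercept", prior_precision=0.0)]
    base += [FixedEffectTerm(c, "covariate", covariate=c) for c in COVARIATES]
    terms = list(base)
    blocks: list[LatentBlock] = []

    if model_id >= 2:
        if model_id in (2, 3):
            terms.append(FixedEffectTerm("state", "state"))
        terms.append(FixedEffectTerm("year", "year"))
    if model_id == 3:
        terms.append(FixedEffectTerm("state:x_crop", "state_x", covariate="x_crop"))
        terms.append(FixedEffectTerm("year:x_crop", "year_x", covariate="x_crop"))
        terms.append(FixedEffectTerm("state:year:x_crop", "state_year_x", covariate="x_crop"))
    if model_id >= 4:
        blocks.append(LatentBlock("iid_county"))
        blocks.append(LatentBlock("iid_year"))
    if model_id == 5:
        blocks.append(LatentBlock("icar_ar1_slope", covariate="x_crop"))
    if model_id == 6:
        blocks.append(LatentBlock("icar_ar1_intercept"))
    return ModelSpec(model_id=model_id, fixed_terms=tuple(terms),
                     latent_blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def centered_year(panel: PanelDataset) -> np.ndarray:
    """Year as a centered continuous covariate, in calendar-year units.

    With censuses (1997, 2002, 2007, 2012) this codes the years as
    (-7.5, -2.5, 2.5, 7.5), so a slope on this column is a per-year effect.
    """
    mean_year = float(np.mean(panel.years))
    return panel.data["year"].to_numpy(float) - mean_year


def build_design_matrix(
    spec: ModelSpec, panel: PanelDataset
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Expand a spec's fixed terms into an observation-by-term matrix.

    Returns ``(X, names, prior_precisions)`` with a deterministic column
    order.  State factors use reference coding with the first state in
    sorted-id order as the reference; interaction columns are elementwise
    products of their parents.
    """
    df = panel.data
    n = len(df)
    states = sorted(df["state_id"].unique())
    nonref = states[1:]
    year_c = centered_year(panel)

    cols: list[np.ndarray] = []
    names: list[str] = []
    precs: list[float] = []

    def add(col: np.ndarray, name: str, prec: float) -> None:
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
        precs.append(prec)

    for term in spec.fixed_terms:
        if term.kind == "intercept":
            add(np.ones(n), term.name, term.prior_precision)
        elif term.kind == "covariate":
            if term.covariate not in df.columns:
                raise KeyError(f"covariate {term.covariate!r} absent from panel")
            add(df[term.covariate].to_numpy(float), term.name, term.prior_precision)
        elif term.kind == "year":
            add(year_c, term.name, term.prior_precision)
        elif term.kind == "state":
            for s in nonref:
                add((df["state_id"] == s).to_numpy(float), f"state[{s}]", term.prior_precision)
        elif term.kind == "year_x":
            z = df[term.covariate].to_numpy(float)
            add(year_c * z, f"year:{term.covariate}", term.prior_precision)
        elif term.kind == "state_x":
            z = df[term.covariate].to_numpy(float)
            for s in nonref:
                ind = (df["state_id"] == s).to_numpy(float)
                add(ind * z, f"state[{s}]:{term.covariate}", term.prior_precision)
        elif term.kind == "state_year_x":
            z = df[term.covariate].to_numpy(float)
            counts = df.groupby("state_id")["county_id"].nunique()
            small = counts[counts < 3]
            if len(small):
                warnings.warn(
                    f"states with < 3 counties give near-singular interaction "
                    f"columns: {list(small.index)}", stacklevel=2)
            for s in nonref:
                ind = (df["state_id"] == s).to_numpy(float)
                add(ind * year_c * z, f"state[{s}]:year:{term.covariate}", term.prior_precision)

    X = np.column_stack(cols)
    zero = ~np.any(X != 0.0, axis=0)
    if zero.any():
        warnings.warn(f"all-zero design column(s): {[names[i] for i in np.flatnonzero(zero)]}",
                      stacklevel=2)
    return X, names, np.asarray(precs, dtype=float)


# ---------------------------------------------------------------------------
# Precision structures
# ---------------------------------------------------------------------------

def build_icar_structure(graph: AdjacencyGraph) -> sp.csr_matrix:
    """Intrinsic CAR (Besag) structure matrix D - W for a neighbour graph.

    Unscaled; rank is n_nodes minus the number of connected components, the
    null space being spanned by per-component constant vectors.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    if graph.n_edges == 0:
        return sp.csr_matrix((n, n))
    rows, cols = zip(*graph.edges)
    i = np.array(rows + cols)
    j = np.array(cols + rows)
    w = sp.coo_matrix((np.ones(2 * graph.n_edges), (i, j)), shape=(n, n))
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


def build_ar1_precision(
    n_times: int, rho: float, marginal_precision: float = 1.0
) -> sp.csr_matrix:
    """Precision of a stationary AR1 with unit marginal variance, scaled.

    Tridiagonal: end diagonal 1/(1-rho^2), interior (1+rho^2)/(1-rho^2),
    off-diagonal -rho/(1-rho^2), all times ``marginal_precision``.  Its
    inverse is ``rho**|i-j| / marginal_precision``.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    e_end, e_int, e_off = ar1_pattern_matrices(n_times)
    c_end, c_int, c_off = ar1_coefficients(rho)
    q = c_end * e_end + c_int * e_int + c_off * e_off
    return (marginal_precision * q).tocsr()


def ar1_pattern_matrices(n_times: int) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
    """Fixed sparsity patterns whose rho-dependent combination is the AR1 precision."""
    t = n_times
    end = np.zeros(t)
    end[0] = 1.0
    end[-1] = 1.0
    interior = 1.0 - end if t > 1 else np.zeros(t)
    if t == 1:
        end[:] = 1.0  # single time point: unit precision
    e_end = sp.diags(end).tocsr()
    e_int = sp.diags(interior).tocsr()
    if t > 1:
        off = np.ones(t - 1)
        e_off = (sp.diags(off, 1) + sp.diags(off, -1)).tocsr()
    else:
        e_off = sp.csr_matrix((1, 1))
    return e_end, e_int, e_off


def ar1_coefficients(rho: float) -> tuple[float, float, float]:
    """Scalars multiplying the three AR1 patterns: ends, interior, off-diagonal."""
    denom = 1.0 - rho * rho
    return 1.0 / denom, (1.0 + rho * rho) / denom, -rho / denom


def ar1_log_det(n_times: int, rho: float) -> float:
    """log det of the unit-marginal-variance AR1 precision."""
    return -(n_times - 1) * np.log1p(-rho * rho)


def build_spacetime_precision(
    graph: AdjacencyGraph,
    n_years: int,
    rho: float,
    tau: float = 1.0,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Separable CAR x AR1 precision over county-year effects.

    Returns ``(Q, C)``: the Kronecker product (AR1 over years) x (ICAR over
    counties) scaled by ``tau``, in year-major ordering (index = year *
    n_counties + county), and the sum-to-zero constraint matrix ``C`` (one
    row per connected component per year).  Before constraints the null
    space has dimension components x years; on ``{C u = 0}`` the form is
    positive definite.
    """
    if n_years < 2:
        raise ValueError("AR1 blocks require >= 2 time points")
    w = build_icar_structure(graph)
    p = build_ar1_precision(n_years, rho)
    q = (tau * sp.kron(p, w, format="csr")).tocsr()
    return q, spacetime_constraints(graph, n_years)


def spacetime_constraints(graph: AdjacencyGraph, n_years: int) -> sp.csr_matrix:
    """Sum-to-zero rows over counties, per component within each year."""
    n = graph.n_nodes
    rows, cols, vals = [], [], []
    r = 0
    for t in range(n_years):
        for comp in graph.components:
            for i in comp:
                rows.append(r)
                cols.append(t * n + i)
                vals.append(1.0)
            r += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(r, n_years * n))


def spacetime_rank(graph: AdjacencyGraph, n_years: int) -> int:
    """Rank of the Kronecker precision: years x (counties - components)."""
    return n_years * (graph.n_nodes - graph.n_components)
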