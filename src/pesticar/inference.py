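"""Blocked Gibbs MCMC for the latent Gaussian insecticide-use models.

The joint model is

    y = X beta + sum_l A_l u_l + eps,     eps ~ N(0, sigma^2 I)

with Gaussian priors on beta (flat intercept, vague slopes), exchangeable
or intrinsic-CAR x AR1 priors on the latent blocks u_l, and Gamma
(equivalently Log-Gamma on the log scale) hyperpriors on all precisions.

Each sweep performs:

(a) one joint draw of every Gaussian quantity (beta and all u_l) from its
    Gaussian full conditional, using a sparse Cholesky-type factorization
    of the full conditional precision, followed by an exact sum-to-zero
    constraint correction (conditioning by kriging) for the improper
    space-time blocks;
(b) conjugate Gamma draws of the error precision and every block precision;
(c) a random-walk Metropolis update of each AR1 coefficient on the
    transformed scale log((1 + rho)/(1 - rho)), with proposal scales
    adapted toward 0.44 acceptance during burn-in only.

Small systems (no latent blocks) fall back to dense Cholesky; larger ones
use SuperLU in symmetric mode without pivoting, which yields a valid
L L^T factorization for symmetric positive definite precisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import ndtr

from .models import (
    ModelSpec,
    ar1_coefficients,
    ar1_log_det,
    ar1_pattern_matrices,
    build_design_matrix,
    build_icar_structure,
)
from .panel import AdjacencyGraph, PanelDataset

__all__ = [
    "SamplerConfig",
    "FitResult",
    "fit_model",
    "compute_dic",
    "delta_dic",
    "compute_pit",
    "posterior_summary",
    "central_interval",
    "write_fit",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length and tuning knobs for the Gibbs sampler."""

    n_iterations: int = 10_000
    n_burnin: int = 2_000
    thin: int = 5
    seed: int = 0
    rho_proposal_scale: float = 0.6
    adapt_window: int = 50
    dense_cutoff: int = 250  # joint dims at or below this use dense Cholesky
    n_loo_hyper_draws: int = 20  # hyperparameter draws used for LOO PIT (0 disables)

    def __post_init__(self) -> None:
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior draws, summaries and diagnostics from one fitted model."""

    model_id: int
    spec_hash: str
    seed: int
    term_names: list[str]
    county_ids: tuple[str, ...]
    years: tuple[int, ...]
    n_obs: int
    beta_draws: np.ndarray            # (S, p)
    latent_draws: dict[str, np.ndarray]   # label -> (S, q_l)
    sigma2_draws: np.ndarray          # (S,)
    tau_draws: dict[str, np.ndarray]
    rho_draws: dict[str, np.ndarray]
    mu_draws: np.ndarray              # (S, n)
    deviance_trace: np.ndarray        # (S,)
    dic: float
    p_d: float
    pit: np.ndarray                   # leave-one-out PIT (calibration diagnostic)
    pit_posterior: np.ndarray         # posterior-predictive PIT
    residuals: np.ndarray             # predictive mean minus observed
    acceptance_rates: dict[str, float]
    config: SamplerConfig

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def mu_mean(self) -> np.ndarray:
        return self.mu_draws.mean(axis=0)

    def beta_mean(self) -> pd.Series:
        return pd.Series(self.beta_draws.mean(axis=0), index=self.term_names)

    def latent_mean(self, label: str) -> np.ndarray:
        return self.latent_draws[label].mean(axis=0)

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self)


# ---------------------------------------------------------------------------
# Factorizations
# ---------------------------------------------------------------------------

class _DenseFactor:
    def __init__(self, q: np.ndarray) -> None:
        self._l = np.linalg.cholesky(q)

    def solve(self, b: np.ndarray) -> np.ndarray:
        y = sla.solve_triangular(self._l, b, lower=True)
        return sla.solve_triangular(self._l, y, lower=True, trans="T")

    def noise_vector(self, rng: np.random.Generator) -> np.ndarray:
        """A draw with covariance Q, so that Q^{-1} v ~ N(0, Q^{-1})."""
        z = rng.standard_normal(self._l.shape[0])
        return self._l @ z


class _SparseFactor:
    """L L^T factorization of an SPD sparse matrix via symmetric SuperLU."""

    def __init__(self, q: sp.csc_matrix) -> None:
        self._lu = splu(q, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                        options=dict(SymmetricMode=True))
        d = self._lu.U.diagonal()
        if not np.array_equal(self._lu.perm_r, self._lu.perm_c) or np.any(d <= 0):
            raise np.linalg.LinAlgError("symmetric factorization failed")
        self._ls = (self._lu.L @ sp.diags(np.sqrt(d))).tocsc()
        self._perm_r = self._lu.perm_r
        self._n = q.shape[0]

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(np.asarray(b, dtype=float))

    def noise_vector(self, rng: np.random.Generator) -> np.ndarray:
        """A draw with covariance Q (permuted Cholesky factor times noise)."""
        z = rng.standard_normal(self._n)
        return (self._ls @ z)[self._perm_r]


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    label: str
    kind: str
    sl: slice
    rank: int
    quad_patterns: list[sp.csr_matrix] = field(default_factory=list)  # spacetime only
    rho_prior: tuple[float, float] = (0.0, 0.15)
    precision_prior: tuple[float, float] = (1.0, 5e-5)

    @property
    def is_spacetime(self) -> bool:
        return self.kind.startswith("icar_ar1")


def _embed(m: sp.spmatrix, offset: int, dim: int) -> sp.coo_matrix:
    m = m.tocoo()
    return sp.coo_matrix((m.data, (m.row + offset, m.col + offset)), shape=(dim, dim))


def _align_components(mats: list[sp.spmatrix]) -> tuple[sp.csc_matrix, list[np.ndarray]]:
    """Pad components onto one shared sparsity pattern.

    Returns the pattern (a csc matrix whose data is ignored) and one data
    array per component aligned to it, so each sweep assembles the joint
    precision as a weighted sum of data vectors.
    """
    pattern = mats[0].tocsc(copy=True)
    pattern.data = np.abs(pattern.data) + 1.0
    for m in mats[1:]:
        extra = m.tocsc(copy=True)
        extra.data = np.abs(extra.data) + 1.0
        pattern = (pattern + extra).tocsc()
    pattern.sum_duplicates()
    pattern.sort_indices()
    n_rows = pattern.shape[0]
    cols = np.repeat(np.arange(pattern.shape[1]), np.diff(pattern.indptr))
    keys = cols.astype(np.int64) * n_rows + pattern.indices  # ascending in csc order
    aligned = []
    for m in mats:
        m = m.tocsc(copy=True)
        m.sum_duplicates()
        m.sort_indices()
        mcols = np.repeat(np.arange(m.shape[1]), np.diff(m.indptr))
        mkeys = mcols.astype(np.int64) * n_rows + m.indices
        pos = np.searchsorted(keys, mkeys)
        if pos.size and (pos.max() >= keys.size or not np.array_equal(keys[pos], mkeys)):
            raise RuntimeError("sparsity alignment failed")
        data = np.zeros(keys.size)
        data[pos] = m.data
        aligned.append(data)
    return pattern, aligned


class _System:
    """Preassembled pieces of the Gaussian full conditional."""

    def __init__(self, spec: ModelSpec, panel: PanelDataset,
                 graph: AdjacencyGraph | None) -> None:
        df = panel.data
        self.y = df["y"].to_numpy(float)
        n = len(df)
        x, names, prior_prec = build_design_matrix(spec, panel)
        self.term_names = names
        p = x.shape[1]

        county_ids = panel.county_ids
        if graph is not None and tuple(graph.node_ids) != tuple(county_ids):
            raise ValueError("graph node ordering does not match the panel's counties")
        cidx = np.array([panel.county_index[c] for c in df["county_id"]])
        yidx = np.array([panel.years.index(int(t)) for t in df["year"]])
        n_c, n_t = len(county_ids), len(panel.years)

        z_parts: list[sp.spmatrix] = [sp.csr_matrix(x)]
        self.blocks: list[_Block] = []
        offset = p
        needs_graph = any(b.is_spacetime for b in spec.latent_blocks)
        if needs_graph and graph is None:
            raise ValueError("space-time blocks require an adjacency graph")
        w = build_icar_structure(graph) if graph is not None else None

        self._prior_components: list[sp.spmatrix] = []
        self._component_tags: list[tuple] = []
        self.constraints: list[tuple[slice, sp.csr_matrix]] = []

        for b in spec.latent_blocks:
            if b.kind == "iid_county":
                q_l = n_c
                a = sp.csr_matrix((np.ones(n), (np.arange(n), cidx)), shape=(n, q_l))
                struct = [sp.eye(q_l, format="csr")]
                rank = q_l
            elif b.kind == "iid_year":
                q_l = n_t
                a = sp.csr_matrix((np.ones(n), (np.arange(n), yidx)), shape=(n, q_l))
                struct = [sp.eye(q_l, format="csr")]
                rank = q_l
            else:
                q_l = n_t * n_c
                vals = (np.ones(n) if b.kind == "icar_ar1_intercept"
                        else df[b.covariate].to_numpy(float))
                cols = yidx * n_c + cidx
                a = sp.csr_matrix((vals, (np.arange(n), cols)), shape=(n, q_l))
                pats = ar1_pattern_matrices(n_t)
                struct = [sp.kron(e, w, format="csr") for e in pats]
                rank = n_t * (n_c - graph.n_components)

            label = b.kind if b.covariate is None else f"{b.kind}[{b.covariate}]"
            sl = slice(offset, offset + q_l)
            blk = _Block(label=label, kind=b.kind, sl=sl, rank=rank,
                         rho_prior=b.rho_prior, precision_prior=b.precision_prior)
            if blk.is_spacetime:
                blk.quad_patterns = struct
                from .models import spacetime_constraints
                self.constraints.append((sl, spacetime_constraints(graph, n_t)))
            self.blocks.append(blk)
            z_parts.append(a)
            bi = len(self.blocks) - 1
            for k, s in enumerate(struct):
                self._prior_components.append(s)
                self._component_tags.append(("block", bi, k))
            offset += q_l

        self.dim = offset
        self.n_c, self.n_t = n_c, n_t
        self.graph = graph
        z = sp.hstack(z_parts).tocsr()
        self.z = z
        self.zty = z.T @ self.y
        ztz = (z.T @ z).tocsr()
        p_fixed = sp.diags(np.concatenate([prior_prec, np.zeros(self.dim - p)]))

        mats = [ztz, p_fixed] + [
            _embed(m, self.blocks[tag[1]].sl.start, self.dim)
            for m, tag in zip(self._prior_components, self._component_tags)
        ]
        tags = [("error",), ("one",)] + self._component_tags
        # Improper space-time blocks leave the joint precision singular in
        # the direction confounding their constant mode with the flat
        # intercept; a tiny diagonal jitter (relative to the largest
        # diagonal entry) restores numerical rank.  The sum-to-zero
        # constraint correction then conditions away those modes, so the
        # sampled distribution on the constraint set is unaffected to
        # within the jitter's O(1e-8) relative perturbation.
        for bi, blk in enumerate(self.blocks):
            if blk.is_spacetime:
                q_l = blk.sl.stop - blk.sl.start
                mats.append(_embed(sp.eye(q_l, format="csr"), blk.sl.start, self.dim))
                tags.append(("jitter", bi))
        self.n_beta = p

        self.dense = self.dim <= 0  # set by caller via use_dense
        self.pattern, self.aligned = _align_components(mats)
        self.tags = tags
        if self.constraints:
            rows = []
            for sl, c in self.constraints:
                full = sp.csr_matrix((c.shape[0], self.dim))
                full = sp.hstack([
                    sp.csr_matrix((c.shape[0], sl.start)), c,
                    sp.csr_matrix((c.shape[0], self.dim - sl.stop)),
                ]).tocsr()
                rows.append(full)
            self.c_joint = sp.vstack(rows).tocsr()
            self.c_dense_t = np.asarray(self.c_joint.T.todense())
        else:
            self.c_joint = None
            self.c_dense_t = None

    def precision_data(self, sigma2: float, taus: Sequence[float],
                       rhos: Sequence[float]) -> np.ndarray:
        data = np.zeros_like(self.aligned[0])
        jitter_arrs = []
        for tag, arr in zip(self.tags, self.aligned):
            if tag[0] == "error":
                data += arr / sigma2
            elif tag[0] == "one":
                data += arr
            elif tag[0] == "jitter":
                jitter_arrs.append(arr)
            else:
                _, bi, k = tag
                blk = self.blocks[bi]
                if blk.is_spacetime:
                    coefs = ar1_coefficients(rhos[bi])
                    data += taus[bi] * coefs[k] * arr
                else:
                    data += taus[bi] * arr
        if jitter_arrs:
            eps = 1e-8 * float(np.abs(data).max())
            for arr in jitter_arrs:
                data += eps * arr
        return data


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def _gaussian_log_density_sum(y: np.ndarray, mu: np.ndarray, sigma2: float) -> float:
    n = len(y)
    rss = float(np.sum((y - mu) ** 2))
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + rss / sigma2)


def deviance(y: np.ndarray, mu: np.ndarray, sigma2: float) -> float:
    """-2 x Gaussian log likelihood at (mu, sigma^2)."""
    return -2.0 * _gaussian_log_density_sum(y, mu, sigma2)


def _loo_pit_terms(sysm: "_System", factor, y: np.ndarray, sigma2: float,
                   zt_dense: np.ndarray) -> np.ndarray:
    """Phi(a_i / sqrt(d_i)) for every observation, at one hyperparameter state.

    Exact Gaussian leave-one-out: a = Sigma^{-1} y = (y - Z m) / sigma^2 and
    d = diag(Sigma^{-1}) = 1/sigma^2 - diag(Z Q^{-1} Z^T) / sigma^4, with m
    the (constrained) conditional posterior mean of the latent state and
    Q^{-1} the constrained posterior covariance.
    """
    rhs = np.column_stack([sysm.zty / sigma2, zt_dense])
    sol = factor.solve(rhs)
    if sysm.c_joint is not None:
        vt = factor.solve(sysm.c_dense_t)
        s_mat = sysm.c_joint @ vt
        sol = sol - vt @ np.linalg.solve(s_mat, sysm.c_joint @ sol)
    m_c = sol[:, 0]
    m_cols = sol[:, 1:]
    s_diag = np.asarray(sysm.z.multiply(m_cols.T).sum(axis=1)).ravel()
    a = (y - sysm.z @ m_c) / sigma2
    d = np.maximum(1.0 / sigma2 - s_diag / sigma2**2, 1e-12)
    return ndtr(a / np.sqrt(d))


def fit_model(
    spec: ModelSpec,
    panel: PanelDataset,
    graph: AdjacencyGraph | None = None,
    config: SamplerConfig | None = None,
) -> FitResult:
    """Fit a model spec by blocked Gibbs sampling.

    The panel must be centered (or at least preprocessed the way the spec
    expects); models with space-time blocks require ``graph`` with node
    ordering matching the panel's sorted county ids.  Reproducible given
    ``config.seed``.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    sysm = _System(spec, panel, graph)
    y = sysm.y
    n = len(y)

    use_dense = sysm.dim <= config.dense_cutoff
    pattern_csc = sysm.pattern

    # initial state
    sigma2 = max(float(np.var(y)), 1e-10)
    taus = [100.0 for _ in sysm.blocks]
    rhos = [0.5 if b.is_spacetime else 0.0 for b in sysm.blocks]
    rho_scales = [config.rho_proposal_scale for _ in sysm.blocks]
    rho_accept = [0 for _ in sysm.blocks]
    rho_batch_accept = [0 for _ in sysm.blocks]
    rho_total = [0 for _ in sysm.blocks]
    theta = np.zeros(sysm.dim)

    a_err, b_err = spec.error_precision_prior

    n_keep = (config.n_iterations - config.n_burnin + config.thin - 1) // config.thin
    beta_draws = np.empty((n_keep, sysm.n_beta))
    latent_draws = {b.label: np.empty((n_keep, b.sl.stop - b.sl.start))
                    for b in sysm.blocks}
    sigma2_draws = np.empty(n_keep)
    tau_draws = {b.label: np.empty(n_keep) for b in sysm.blocks}
    rho_draws = {b.label: np.empty(n_keep) for b in sysm.blocks if b.is_spacetime}
    mu_draws = np.empty((n_keep, n))
    dev_trace = np.empty(n_keep)

    # Leave-one-out PIT is Rao-Blackwellized: conditional on the
    # hyperparameters, p(y_i | y_{-i}) is Gaussian with precision
    # d_i = [Sigma^{-1}]_{ii} and standardized residual a_i / sqrt(d_i),
    # where a = Sigma^{-1} y = (y - Z m) / sigma^2 (the kriging
    # cross-validation identity); the PIT averages Phi(a_i / sqrt(d_i))
    # over a subsample of hyperparameter draws.
    n_loo = min(config.n_loo_hyper_draws, n_keep)
    loo_at = set(np.unique(np.linspace(0, n_keep - 1, n_loo).astype(int))) if n_loo else set()
    loo_sum = np.zeros(n)
    loo_count = 0
    zt_dense = sysm.z.T.toarray() if loo_at else None

    kept = 0
    for it in range(config.n_iterations):
        # (a) joint Gaussian draw of beta and all latent effects
        data = sysm.precision_data(sigma2, taus, rhos)
        q = sp.csc_matrix((data, pattern_csc.indices, pattern_csc.indptr),
                          shape=pattern_csc.shape)
        try:
            factor = _DenseFactor(q.toarray()) if use_dense else _SparseFactor(q)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"precision factorization failed at iteration {it}; "
                "review constraints and priors") from exc
        b_vec = sysm.zty / sigma2 + factor.noise_vector(rng)
        if sysm.c_joint is not None:
            sol = factor.solve(np.column_stack([b_vec, sysm.c_dense_t]))
            theta, vt = sol[:, 0], sol[:, 1:]
            s = sysm.c_joint @ vt
            corr = np.linalg.solve(s, sysm.c_joint @ theta)
            theta = theta - vt @ corr
        else:
            theta = factor.solve(b_vec)
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"non-finite latent state at iteration {it}")

        is_kept = (it >= config.n_burnin
                   and (it - config.n_burnin) % config.thin == 0)
        if is_kept and kept in loo_at:
            # uses the same factor (and sigma2) that produced this draw
            loo_sum += _loo_pit_terms(sysm, factor, y, sigma2, zt_dense)
            loo_count += 1

        mu = sysm.z @ theta
        resid = y - mu

        # (b) conjugate precision updates
        rss = float(resid @ resid)
        tau_err = rng.gamma(a_err + 0.5 * n, 1.0 / (b_err + 0.5 * rss))
        sigma2 = 1.0 / tau_err

        for bi, blk in enumerate(sysm.blocks):
            u = theta[blk.sl]
            a_t, b_t = blk.precision_prior
            if blk.is_spacetime:
                quads = [float(u @ (k @ u)) for k in blk.quad_patterns]
                coefs = ar1_coefficients(rhos[bi])
                quad = sum(c * qd for c, qd in zip(coefs, quads))
                taus[bi] = rng.gamma(a_t + 0.5 * blk.rank, 1.0 / (b_t + 0.5 * quad))

                # (c) random-walk Metropolis on transformed rho
                rho_total[bi] += 1
                t_cur = np.log((1 + rhos[bi]) / (1 - rhos[bi]))
                t_prop = t_cur + rho_scales[bi] * rng.standard_normal()
                r_prop = np.tanh(t_prop / 2.0)
                m0, pr = blk.rho_prior
                n_pos = blk.rank // sysm.n_t

                def log_target(r, t):
                    c = ar1_coefficients(r)
                    qd = sum(ck * qk for ck, qk in zip(c, quads))
                    return (0.5 * n_pos * ar1_log_det(sysm.n_t, r)
                            - 0.5 * taus[bi] * qd - 0.5 * pr * (t - m0) ** 2)

                if np.log(rng.uniform()) < log_target(r_prop, t_prop) - log_target(rhos[bi], t_cur):
                    rhos[bi] = float(r_prop)
                    rho_accept[bi] += 1
                    rho_batch_accept[bi] += 1
                if (it < config.n_burnin and (it + 1) % config.adapt_window == 0):
                    rate = rho_batch_accept[bi] / config.adapt_window
                    rho_scales[bi] = float(np.clip(
                        rho_scales[bi] * np.exp(rate - 0.44), 1e-3, 10.0))
                    rho_batch_accept[bi] = 0
            else:
                quad = float(u @ u)
                q_l = blk.sl.stop - blk.sl.start
                taus[bi] = rng.gamma(a_t + 0.5 * q_l, 1.0 / (b_t + 0.5 * quad))

        # record
        if is_kept:
            beta_draws[kept] = theta[:sysm.n_beta]
            for blk in sysm.blocks:
                latent_draws[blk.label][kept] = theta[blk.sl]
            sigma2_draws[kept] = sigma2
            for bi, blk in enumerate(sysm.blocks):
                tau_draws[blk.label][kept] = taus[bi]
                if blk.is_spacetime:
                    rho_draws[blk.label][kept] = rhos[bi]
            mu_draws[kept] = mu
            dev_trace[kept] = deviance(y, mu, sigma2)
            kept += 1

    assert kept == n_keep
    mu_bar = mu_draws.mean(axis=0)
    sigma2_bar = float(sigma2_draws.mean())
    dic, p_d = compute_dic(dev_trace, deviance(y, mu_bar, sigma2_bar))
    pit_posterior = _pit_from_draws(y, mu_draws, sigma2_draws)
    pit = loo_sum / loo_count if loo_count else pit_posterior
    residuals = mu_bar - y

    acc = {blk.label: (rho_accept[bi] / rho_total[bi] if rho_total[bi] else np.nan)
           for bi, blk in enumerate(sysm.blocks) if blk.is_spacetime}
    return FitResult(
        model_id=spec.model_id, spec_hash=spec.spec_hash(), seed=config.seed,
        term_names=sysm.term_names, county_ids=tuple(panel.county_ids),
        years=tuple(panel.years), n_obs=n,
        beta_draws=beta_draws, latent_draws=latent_draws,
        sigma2_draws=sigma2_draws, tau_draws=tau_draws, rho_draws=rho_draws,
        mu_draws=mu_draws, deviance_trace=dev_trace, dic=dic, p_d=p_d,
        pit=pit, pit_posterior=pit_posterior, residuals=residuals,
        acceptance_rates=acc, config=config,
    )


# ---------------------------------------------------------------------------
# Model comparison and calibration
# ---------------------------------------------------------------------------

def compute_dic(deviance_trace: Sequence[float],
                deviance_at_posterior_mean: float) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    pD = mean deviance - deviance at the posterior mean; DIC = mean
    deviance + pD.  pD can be negative in pathological fits and is
    reported as is.
    """
    trace = np.asarray(deviance_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(trace.mean())
    p_d = dbar - float(deviance_at_posterior_mean)
    return dbar + p_d, p_d


def delta_dic(dics: Mapping) -> dict:
    """DIC differences from the best (lowest-DIC) model."""
    if not dics:
        raise ValueError("need at least one DIC value")
    best = min(dics.values())
    return {k: float(v - best) for k, v in dics.items()}


def _pit_from_draws(y: np.ndarray, mu_draws: np.ndarray,
                    sigma2_draws: np.ndarray) -> np.ndarray:
    sd = np.sqrt(sigma2_draws)[:, None]
    return ndtr((y[None, :] - mu_draws) / sd).mean(axis=0)


def compute_pit(fit: FitResult, panel: PanelDataset) -> np.ndarray:
    """Posterior-predictive probability integral transform per observation.

    PIT_i = E_draws[ Phi((y_i - mu_i) / sigma) ], the predictive
    probability that a replicate does not exceed the observed value;
    approximately uniform when the model is well calibrated.
    """
    y = panel.data["y"].to_numpy(float)
    if len(y) != fit.n_obs:
        raise ValueError("panel does not match the fitted model")
    return _pit_from_draws(y, fit.mu_draws, fit.sigma2_draws)


def central_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed central credible interval from posterior draws."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def posterior_summary(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, central interval, and P(value <= 0) per parameter.

    Fixed effects are followed by the residual standard deviation, the
    random-effect standard deviations, and any AR1 coefficients.
    """
    rows = []

    def row(name, draws, tail=True):
        lo, hi = central_interval(draws, level)
        rows.append({
            "parameter": name,
            "mean": float(np.mean(draws)),
            f"q{100 * (1 - level) / 2:g}": lo,
            f"q{100 * (1 + level) / 2:g}": hi,
            "p_le_zero": float(np.mean(draws <= 0.0)) if tail else np.nan,
        })

    for j, name in enumerate(fit.term_names):
        row(name, fit.beta_draws[:, j])
    row("model_error_sd", np.sqrt(fit.sigma2_draws), tail=False)
    for label, draws in fit.tau_draws.items():
        row(f"sd[{label}]", 1.0 / np.sqrt(draws), tail=False)
    for label, draws in fit.rho_draws.items():
        row(f"rho[{label}]", draws, tail=False)
    return pd.DataFrame(rows).set_index("parameter")


def write_fit(fit: FitResult, out_dir: str | Path) -> None:
    """Persist a fit: summary table, run metadata, and draw archive."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit.summary().to_csv(out / "summary.csv")
    meta = {
        "model_id": fit.model_id,
        "spec_hash": fit.spec_hash,
        "seed": fit.seed,
        "n_obs": fit.n_obs,
        "n_draws": fit.n_draws,
        "dic": fit.dic,
        "p_d": fit.p_d,
        "acceptance_rates": fit.acceptance_rates,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    draws = pd.DataFrame(fit.beta_draws, columns=fit.term_names)
    draws["sigma2"] = fit.sigma2_draws
    for label, arr in fit.tau_draws.items():
        draws[f"tau[{label}]"] = arr
    for label, arr in fit.rho_draws.items():
        draws[f"rho[{label}]"] = arr
    draws["deviance"] = fit.deviance_trace
    try:
        draws.to_parquet(out / "draws.parquet")
    except ImportError:
        draws.to_csv(out / "draws.csv", index=False)
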