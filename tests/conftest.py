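"""Shared fixtures: small panels, lattices, and replicate model fits.

Expensive replicate experiments (used by the model-selection and
diagnostic-contrast acceptance checks) are computed once per session and
shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pesticar as pc


def make_toy_panel(rows=None, years=(1997, 2002, 2007, 2012)) -> pc.PanelDataset:
    """A tiny hand-written two-county panel."""
    if rows is None:
        rows = []
        for cid, st in [("A", "S1"), ("B", "S1")]:
            for k, year in enumerate(years):
                rows.append(dict(
                    county_id=cid, state_id=st, year=year,
                    y=0.2 + 0.05 * k, x_corn=0.3, x_cov=0.05, x_sw=0.2,
                    x_income=0.5, x_size=1.0, x_gdd=3.0,
                    x_crop=0.4 if cid == "A" else 0.1,
                ))
    df = pd.DataFrame(rows)
    for f in ("y",) + pc.COVARIATES:
        df[f"cens_{f}"] = False
    return pc.PanelDataset(data=df, years=years)


@pytest.fixture
def toy_panel():
    return make_toy_panel()


@pytest.fixture(scope="session")
def small_sim():
    """One 8x8 Model 6 panel, preprocessed, with its graph and truth."""
    cfg = pc.SimConfig(grid_rows=8, grid_cols=8, seed=42)
    panel, graph0, truth = pc.simulate_panel(cfg)
    proc = pc.preprocess(panel, threshold=0.0)
    graph = pc.build_adjacency(
        [(graph0.node_ids[i], graph0.node_ids[j]) for i, j in graph0.edges], proc)
    return proc, graph, truth, cfg


def simulate_and_fit(seed: int, model_ids, rows=10, cols=10,
                     n_iterations=600, n_burnin=200, fit_seed_offset=10_000,
                     generative_model=6, n_loo=0):
    """Generate one replicate panel and fit the requested models on it."""
    cfg = pc.SimConfig(grid_rows=rows, grid_cols=cols, seed=seed,
                       generative_model=generative_model)
    panel, graph0, truth = pc.simulate_panel(cfg)
    proc = pc.preprocess(panel, threshold=0.0)
    graph = pc.build_adjacency(
        [(graph0.node_ids[i], graph0.node_ids[j]) for i, j in graph0.edges], proc)
    fits = {}
    for m in model_ids:
        spec = pc.make_model_spec(m, proc, graph)
        fits[m] = pc.fit_model(
            spec, proc, graph if m >= 4 else None,
            pc.SamplerConfig(n_iterations=n_iterations, n_burnin=n_burnin,
                             thin=1, seed=seed + fit_seed_offset,
                             n_loo_hyper_draws=n_loo))
    return proc, graph, truth, fits


@pytest.fixture(scope="session")
def replicate_fits_m1_m4_m6():
    """20 replicate Model 6 datasets, each fitted by Models 1, 4 and 6.

    Shared by the model-selection-recovery and diagnostic-contrast checks.
    """
    out = []
    for r in range(20):
        proc, graph, truth, fits = simulate_and_fit(300 + r, (1, 4, 6), n_loo=10)
        out.append((proc, graph, truth, fits))
    return out
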