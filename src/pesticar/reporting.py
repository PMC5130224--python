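"""Interpretive outputs: effect translations, standardized coefficients,
spatially varying coefficients, and model-comparison tables.

An *effect translation* turns a posterior-mean slope into the implied
change in relative insecticide use over a stated covariate change (for
example, a corn-share increase from 0.40 to 0.80 under a slope of 0.398
implies a change of 0.16).  Standardized coefficients multiply each slope
by its covariate's standard deviation, putting covariates measured in
different units on a common footing.  Spatially varying coefficients (SVC)
add the county-year random slope to the global cropland slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import FitResult, central_interval, delta_dic
from .panel import COVARIATES, PanelDataset

__all__ = [
    "EffectTranslation",
    "effect_translation",
    "translation_table",
    "standardized_coefficients",
    "svc_coefficients",
    "comparison_table",
    "descriptive_statistics",
]

PLACEHOLDER = "."  # marks a term absent from a model, as in printed tables


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (0.075 -> 0.08, -0.075 -> -0.08)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EffectTranslation:
    covariate: str
    from_value: float
    to_value: float
    coefficient: float
    implied_change: float
    decimals: int = 2


def effect_translation(coefficient: float, from_value: float, to_value: float,
                       decimals: int = 2) -> float:
    """Implied change in the response for a covariate moving from -> to.

    ``coefficient * (to - from)``, rounded half away from zero.  Linear in
    the coefficient and antisymmetric under swapping the endpoints.
    """
    return round_half_away(coefficient * (to_value - from_value), decimals)


def translation_table(
    coefficients: Mapping[str, float],
    scenarios: Mapping[str, tuple[float, float]],
    decimals: int = 2,
) -> pd.DataFrame:
    """Tabulate effect translations for named covariate scenarios."""
    rows = []
    for name, (lo, hi) in scenarios.items():
        coef = coefficients[name]
        rows.append(EffectTranslation(
            covariate=name, from_value=lo, to_value=hi, coefficient=coef,
            implied_change=effect_translation(coef, lo, hi, decimals),
            decimals=decimals,
        ).__dict__)
    return pd.DataFrame(rows)


def standardized_coefficients(fit: FitResult, panel: PanelDataset,
                              scale_by_response_sd: bool = False) -> pd.DataFrame:
    """Slope times covariate standard deviation, per fixed covariate.

    The convention multiplies by the covariate SD only (not further
    divided by the response SD); set ``scale_by_response_sd`` to divide by
    SD(y) as well.  Zero-variance covariates are flagged and reported as 0.
    """
    means = fit.beta_mean()
    sd_y = float(panel.data["y"].std(ddof=0))
    rows = []
    for cov in COVARIATES:
        if cov not in means.index:
            continue
        sd = float(panel.data[cov].std(ddof=0))
        flagged = sd == 0.0
        std = 0.0 if flagged else means[cov] * sd
        if scale_by_response_sd and not flagged:
            std /= sd_y
        rows.append({"covariate": cov, "slope": float(means[cov]),
                     "covariate_sd": sd, "standardized": float(std),
                     "zero_variance": flagged})
    return pd.DataFrame(rows).set_index("covariate")


def svc_coefficients(fit: FitResult) -> pd.DataFrame:
    """Spatially varying cropland slope per county and year.

    The SVC value is the posterior mean of the global proportion-cropland
    fixed effect plus the county-year random slope.  Requires a fit whose
    spec contains a space-time slope block.
    """
    label = next((lb for lb in fit.latent_draws if lb.startswith("icar_ar1_slope")), None)
    if label is None:
        raise ValueError("fit has no spatially varying slope block")
    global_slope = float(fit.beta_mean()["x_crop"])
    u = fit.latent_mean(label)  # year-major
    n_c = len(fit.county_ids)
    rows = []
    for t, year in enumerate(fit.years):
        for i, cid in enumerate(fit.county_ids):
            rows.append({"county_id": cid, "year": year,
                         "svc": global_slope + float(u[t * n_c + i])})
    return pd.DataFrame(rows)


_HYPER_ROWS = [
    ("model_error_sd", "model_error_sd"),
    ("sd[iid_county]", "sd_county_iid"),
    ("sd[iid_year]", "sd_year_iid"),
    ("sd[icar_ar1_intercept]", "sd_spacetime_intercept"),
    ("sd[icar_ar1_slope[x_crop]]", "sd_spacetime_slope"),
    ("rho[icar_ar1_intercept]", "rho_intercept_ar1"),
    ("rho[icar_ar1_slope[x_crop]]", "rho_slope_ar1"),
]


def comparison_table(fits: Mapping[int, FitResult], level: float = 0.95) -> pd.DataFrame:
    """Side-by-side model comparison: coefficients, scales, DIC, delta-DIC.

    One column per model; absent terms are rendered as the period
    placeholder.  Cells show "mean (lo, hi)" central intervals.
    """
    if not fits:
        raise ValueError("need at least one fit")
    order = sorted(fits)
    dics = {m: fits[m].dic for m in order}
    deltas = delta_dic(dics)

    fixed_rows = ["intercept"] + list(COVARIATES) + ["year"]
    index = fixed_rows + [r for _, r in _HYPER_ROWS] + ["dic", "delta_dic"]
    table = pd.DataFrame(PLACEHOLDER, index=index, columns=[f"model_{m}" for m in order])

    def cell(draws):
        lo, hi = central_interval(draws, level)
        return f"{np.mean(draws):.3f} ({lo:.3f}, {hi:.3f})"

    for m in order:
        fit = fits[m]
        col = f"model_{m}"
        for j, name in enumerate(fit.term_names):
            if name in fixed_rows:
                table.loc[name, col] = cell(fit.beta_draws[:, j])
        table.loc["model_error_sd", col] = cell(np.sqrt(fit.sigma2_draws))
        for label, row in _HYPER_ROWS[1:5]:
            key = label[3:-1]  # strip "sd[" ... "]"
            if key in fit.tau_draws:
                table.loc[row, col] = cell(1.0 / np.sqrt(fit.tau_draws[key]))
        for label, row in _HYPER_ROWS[5:]:
            key = label[4:-1]
            if key in fit.rho_draws:
                table.loc[row, col] = cell(fit.rho_draws[key])
        table.loc["dic", col] = f"{fit.dic:.1f}"
        table.loc["delta_dic", col] = f"{deltas[m]:.1f}"
    return table


def descriptive_statistics(panel: PanelDataset) -> pd.Series:
    """Sample means of the response and covariates over all records."""
    cols = ["y"] + list(COVARIATES)
    return panel.data[cols].mean()
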