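"""Standardization of longline catch counts into spatial nCPUE surfaces.

Catch counts per set are modelled with a negative-binomial additive model:
log(hooks) offset, a tensor-product spatial smooth over (lon, lat), gear
type as a fixed factor, and year/month/boat as ridge-penalized factors
(a working approximation to random intercepts).  The fitted model predicts
the expected number of individuals caught per 1000 hooks at every cell of
the analysis grid — the standardized relative-abundance surface that feeds
the intraspecific trophic pressure index.

Separate models are intended per species and basin; species with an excess
of zero catches in a basin are refused rather than fitted (a model on
all-zero counts estimates nothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GridSpec, DriverLayer
from .pgam import (FactorTerm, GamFit, TensorTerm, fit_gam, negative_binomial)

__all__ = ["ZeroCatchError", "CpueModelSpec", "fit_nb_additive", "predict_abundance",
           "split_basin"]


class ZeroCatchError(ValueError):
    """Raised when a species/basin stratum has too few positive catches."""


@dataclass(frozen=True)
class CpueModelSpec:
    """Structural choices of one standardization model."""

    k_space: int = 8                 # marginal spline basis size per axis
    gear_col: str = "gear"
    random_cols: tuple[str, ...] = ("year", "month", "boat")
    min_sets: int = 50
    min_positive: int = 10           # refuse below this many non-zero catches


def split_basin(sets: pd.DataFrame, gibraltar_lon: float = -5.6) -> dict[str, pd.DataFrame]:
    """Split longline sets at the Strait of Gibraltar longitude."""
    med = sets[sets["lon"] >= gibraltar_lon]
    atl = sets[sets["lon"] < gibraltar_lon]
    return {"mediterranean": med, "atlantic": atl}


def fit_nb_additive(sets: pd.DataFrame, species: str,
                    spec: CpueModelSpec | None = None,
                    lambdas="gcv") -> GamFit:
    """Fit the negative-binomial standardization model for one species.

    ``sets`` must carry ``lon, lat, hooks`` plus the catch column
    ``catch_<species>`` and the gear/year/month/boat metadata.  Factors
    with a single observed level are dropped silently (they are not
    estimable).  The NB overdispersion is profiled by ML.
    """
    spec = spec or CpueModelSpec()
    col = f"catch_{species}"
    if col not in sets.columns:
        raise KeyError(f"missing catch column {col!r}")
    if len(sets) < spec.min_sets:
        raise ValueError(f"need >= {spec.min_sets} sets, got {len(sets)}")
    if (sets["hooks"] <= 0).any():
        raise ValueError("hooks must be positive")
    y = sets[col].to_numpy(dtype=float)
    if (y > 0).sum() < spec.min_positive:
        raise ZeroCatchError(
            f"{species}: only {int((y > 0).sum())} positive catches in "
            f"{len(y)} sets — excess of zero catch observations, no model fitted")

    terms: list = [TensorTerm("lon", "lat", k=spec.k_space)]
    if sets[spec.gear_col].nunique() >= 2:
        terms.append(FactorTerm(spec.gear_col))
    for c in spec.random_cols:
        if sets[c].nunique() >= 2:
            terms.append(FactorTerm(c, penalized=True))

    fit = fit_gam(sets, y, terms, family=negative_binomial(1.0),
                  offset=np.log(sets["hooks"].to_numpy(dtype=float)),
                  lambdas=lambdas, estimate_nb_alpha=True)
    return fit


def predict_abundance(fit: GamFit, grid: GridSpec, species: str = "",
                      gear_levels: list[str] | None = None) -> DriverLayer:
    """Predict the standardized nCPUE surface on the analysis grid.

    Predictions are made at cell centres with the offset fixed at 1000
    hooks.  Gear is handled by averaging the response-scale predictions
    over the observed gear levels; penalized factors (year/month/boat)
    are set to their zero population level.  Cells outside the spatial
    support of the fitted sets (the data bounding box) are flagged
    missing.
    """
    if not fit.converged:
        raise RuntimeError("model did not converge; refusing to predict")
    lon, lat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    cells = pd.DataFrame({"lon": lon.ravel(), "lat": lat.ravel()})
    offset = np.full(len(cells), np.log(1000.0))

    gear_term = next((t for t in fit.terms if isinstance(t, FactorTerm)
                      and not t.penalized), None)
    if gear_term is None:
        pred = fit.predict(cells, offset=offset)
    else:
        levels = gear_levels or gear_term.levels_
        preds = []
        for g in levels:
            d = cells.copy()
            d[gear_term.name] = g
            preds.append(fit.predict(d, offset=offset))
        pred = np.mean(preds, axis=0)

    # flag cells outside the fitted spatial support
    te = next(t for t in fit.terms if isinstance(t, TensorTerm))
    inx = (cells["lon"] >= te.knots_x_[0]) & (cells["lon"] <= te.knots_x_[-1])
    iny = (cells["lat"] >= te.knots_y_[0]) & (cells["lat"] <= te.knots_y_[-1])
    valid = (inx & iny).to_numpy()
    vals = np.where(valid, pred, np.nan).reshape(grid.n_lat, grid.n_lon)
    return DriverLayer(name=f"ncpue_{species}" if species else "ncpue",
                       grid=grid, values=vals)
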