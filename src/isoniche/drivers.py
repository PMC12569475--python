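"""Gamma additive models relating competition metrics to their drivers.

CCD and ITP computed per 1-degree grid cell are strictly positive (after a
logged offset adjustment for zero-abundance cells) and right-skewed, so
they are modelled with a gamma family on a log link.  Candidate models mix
linear terms, univariate smooths of drivers (productivity, mixed-layer
depth, fishing effort, competitor abundance), a species fixed factor, and
a tensor-product spatial smooth.  Before fitting, drivers are screened for
pairwise Spearman correlation and one member of each highly collinear pair
is dropped.  Candidates are ranked by AIC and deviance explained.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DriverLayer
from .pgam import (FactorTerm, GamFit, LinearTerm, SmoothTerm, TensorTerm,
                   fit_gam, gamma_log)

logger = logging.getLogger(__name__)

__all__ = ["spearman_screen", "adjust_positive", "fit_gamma_additive",
           "select_model", "partial_effects", "make_terms"]


def spearman_screen(layers: dict[str, DriverLayer], threshold: float = 0.8,
                    priority: list[str] | None = None):
    """Drop one member of every driver pair with |Spearman rho| > threshold.

    ``priority`` lists layer names from most to least preferred; when a
    pair is collinear the lower-priority member is dropped (default: the
    later name in the dict).  Constant layers have undefined rank
    correlation and are flagged and excluded.  Returns
    ``(retained dict, correlation DataFrame, dropped list)``.
    """
    names = list(layers)
    grid = layers[names[0]].grid
    for n in names[1:]:
        if layers[n].grid != grid:
            raise ValueError("layers are on different grids")
    common = np.logical_and.reduce([layers[n].valid for n in names])
    flagged = []
    for n in names:
        v = layers[n].values[common]
        if np.ptp(v) == 0:
            flagged.append(n)
            logger.warning("spearman_screen: layer %r is constant, excluded", n)
    names = [n for n in names if n not in flagged]

    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        rho = stats.spearmanr(layers[a].values[common], layers[b].values[common]).statistic
        corr.loc[a, b] = corr.loc[b, a] = rho

    rank = {n: i for i, n in enumerate(priority or names)}
    dropped = set(flagged)
    for a, b in itertools.combinations(names, 2):
        if a in dropped or b in dropped:
            continue
        if abs(corr.loc[a, b]) > threshold:
            victim = max(a, b, key=lambda n: rank.get(n, len(rank)))
            dropped.add(victim)
            logger.info("spearman_screen: dropping %r (|rho|=%.2f with %r)",
                        victim, abs(corr.loc[a, b]), a if victim == b else b)
    retained = {n: layers[n] for n in layers if n not in dropped}
    return retained, corr, sorted(dropped)


def adjust_positive(values: np.ndarray, rel: float = 1e-3) -> tuple[np.ndarray, float]:
    """Shift a nonnegative response into gamma support.

    Zero cells (e.g. ITP where predicted abundance is zero) get an offset
    of ``rel`` times the smallest positive value; the offset used is
    returned and logged loudly so it cannot pass unnoticed.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("response must be >= 0")
    if np.all(v > 0):
        return v, 0.0
    pos = v[v > 0]
    if len(pos) == 0:
        raise ValueError("response is identically zero; nothing to model")
    eps = float(pos.min() * rel)
    nz = int((v == 0).sum())
    logger.warning("adjust_positive: %d zero cells shifted by +%.3g for gamma support",
                   nz, eps)
    return v + eps, eps


def make_terms(term_spec: list) -> list:
    """Build engine terms from a compact spec.

    Each entry is ``("linear", col)``, ``("smooth", col[, k])``,
    ``("factor", col)`` or ``("tensor", xcol, ycol[, k])``.
    """
    out = []
    for entry in term_spec:
        kind = entry[0]
        if kind == "linear":
            out.append(LinearTerm(entry[1]))
        elif kind == "smooth":
            out.append(SmoothTerm(entry[1], k=entry[2] if len(entry) > 2 else 6))
        elif kind == "factor":
            out.append(FactorTerm(entry[1]))
        elif kind == "tensor":
            out.append(TensorTerm(entry[1], entry[2], k=entry[3] if len(entry) > 3 else 6))
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    return out


def fit_gamma_additive(records: pd.DataFrame, response: str,
                       term_spec: list, lambdas="gcv") -> GamFit:
    """Fit one gamma/log-link additive model for a competition metric.

    The response must be strictly positive; run :func:`adjust_positive`
    first when zeros are structurally possible.  Offending rows are named
    in the error otherwise.
    """
    y = records[response].to_numpy(dtype=float)
    bad = np.nonzero(~(y > 0))[0]
    if len(bad):
        raise ValueError(
            f"gamma response must be > 0; offending rows (first 10): {bad[:10].tolist()}")
    return fit_gam(records, y, make_terms(term_spec), family=gamma_log(),
                   lambdas=lambdas)


@dataclass(frozen=True)
class ModelRanking:
    table: pd.DataFrame          # one row per candidate: aic, dev_explained, n_terms
    best_index: int


def select_model(fits: list[GamFit], names: list[str] | None = None):
    """Rank candidate fits by AIC (lower better), DE and parsimony.

    All candidates must be fitted on the same rows.  Ties on AIC within
    1e-6 are broken by fewer terms (and logged).  Returns
    ``(best fit, ModelRanking)``.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 candidate fits")
    n0 = fits[0].n_obs
    if any(f.n_obs != n0 for f in fits):
        raise ValueError("candidates fitted on differing numbers of rows")
    names = names or [f"m{i}" for i in range(len(fits))]
    tab = pd.DataFrame({
        "model": names,
        "aic": [f.aic for f in fits],
        "dev_explained": [f.deviance_explained for f in fits],
        "edf": [f.edf for f in fits],
        "n_terms": [len(f.terms) for f in fits],
    })
    order = np.lexsort((tab["n_terms"], np.round(tab["aic"], 6)))
    tab = tab.iloc[order].reset_index(drop=True)
    best = int(order[0])
    if len(order) > 1 and abs(fits[order[0]].aic - fits[order[1]].aic) < 1e-6:
        logger.info("select_model: AIC tie between %s and %s, fewer-terms rule applied",
                    names[order[0]], names[order[1]])
    return fits[best], ModelRanking(table=tab, best_index=best)


def partial_effects(fit: GamFit, label: str, n_points: int = 100) -> pd.DataFrame:
    """Centred partial effect of one term over its covariate range.

    Returns a table with the covariate grid, the effect on the linear
    predictor scale and pointwise 95% Wald confidence bounds.  For the
    spatial tensor term the grid covers the fitted lon/lat box and the
    output has ``lon, lat`` columns (a raster in long form).
    """
    term = next((t for t in fit.terms if t.label == label), None)
    if term is None:
        raise KeyError(f"unknown term {label!r}")
    if isinstance(term, TensorTerm):
        xs = np.linspace(term.knots_x_[0], term.knots_x_[-1], int(np.sqrt(n_points) * 2))
        ys = np.linspace(term.knots_y_[0], term.knots_y_[-1], int(np.sqrt(n_points) * 2))
        gx, gy = np.meshgrid(xs, ys)
        df = pd.DataFrame({term.name_x: gx.ravel(), term.name_y: gy.ravel()})
        eff, se = fit.partial_effect(label, df)
        df["effect"] = eff
        df["lo"], df["hi"] = eff - 1.96 * se, eff + 1.96 * se
        return df
    if isinstance(term, FactorTerm):
        df = pd.DataFrame({term.name: term.levels_ if term.penalized else term.cols_})
        eff, se = fit.partial_effect(label, df)
        return pd.DataFrame({term.name: df[term.name], "effect": eff,
                             "lo": eff - 1.96 * se, "hi": eff + 1.96 * se})
    if isinstance(term, SmoothTerm):
        x = np.linspace(term.knots_[0], term.knots_[-1], n_points)
    else:  # linear
        x = np.linspace(term.center_ - 1, term.center_ + 1, n_points)
    df = pd.DataFrame({term.name: x})
    eff, se = fit.partial_effect(label, df)
    return pd.DataFrame({term.name: x, "effect": eff,
                         "lo": eff - 1.96 * se, "hi": eff + 1.96 * se})
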