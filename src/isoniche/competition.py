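"""Inter- and intraspecific competition metrics in isotope space.

Interspecific similarity: the distance to the competitor's centroid (CCD),
the mean Euclidean distance in (d13C, d15N) space between a species'
centroid C_i and the centroids C_k of its N available competitors,

    CCD_i = (1/N) * sum_k ||C_i - C_k||_2 .

Low CCD means competitors sit close together in isotope space, i.e.
similar resource use.

Intraspecific pressure: the intraspecific trophic pressure index,

    ITP = log(nCPUE + 1) / KUD_area ,

standardized abundance (individuals per 1000 hooks) over the 95% KUD
niche area.  Abundant species with narrow niches score high — many
conspecifics squeezed onto few resources.

Group comparisons follow the conventional gate: Shapiro-Wilk normality
check, then one-way ANOVA with Tukey HSD, otherwise Kruskal-Wallis with
pairwise Wilcoxon rank-sum tests.  Species/region structure of the raw
bivariate isotope values is tested with a two-way PERMANOVA on the
Euclidean distance matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_centroids", "compute_ccd", "compute_itp", "summarize_metric",
    "compare_groups", "permanova2", "GroupComparison", "PermanovaResult",
]


def compute_centroids(samples: pd.DataFrame, by: str = "region") -> pd.DataFrame:
    """Per species x key centroids (mean d13C, d15N) and sample counts."""
    g = samples.groupby(["species", by], observed=True)
    out = g.agg(c_d13c=("d13c", "mean"), c_d15n=("d15n", "mean"),
                n=("d13c", "size")).reset_index()
    return out.rename(columns={by: "key"})


def compute_ccd(centroids: pd.DataFrame) -> pd.DataFrame:
    """Mean Euclidean distance from each species' centroid to its competitors'.

    ``centroids`` needs columns ``key, species, c_d13c, c_d15n`` (one row
    per species per key).  Keys with a single species yield no records
    (there is no competitor to measure against) and are logged.  In the
    two-species case CCD is symmetric.
    """
    records = []
    for key, grp in centroids.groupby("key", observed=True):
        if len(grp) < 2:
            logger.info("CCD: key %r has a single species, skipped", key)
            continue
        pts = grp[["c_d13c", "c_d15n"]].to_numpy()
        for i, (_, row) in enumerate(grp.iterrows()):
            d = np.linalg.norm(pts - pts[i], axis=1)
            others = np.delete(d, i)
            records.append({"key": key, "species": row["species"],
                            "ccd": float(others.mean()),
                            "n_competitors": len(others)})
    return pd.DataFrame(records, columns=["key", "species", "ccd", "n_competitors"])


def compute_itp(ncpue, kud_area, log_base: float = math.e):
    """Elementwise ITP = log(nCPUE + 1) / KUD_area.

    Natural logarithm by default (configurable base).  Zero abundance
    gives ITP = 0 for any niche area; non-positive areas are invalid.
    """
    ncpue = np.asarray(ncpue, dtype=float)
    area = np.asarray(kud_area, dtype=float)
    if np.any(ncpue < 0):
        raise ValueError("nCPUE must be >= 0")
    if np.any(area <= 0):
        raise ValueError("KUD area must be > 0")
    return np.log1p(ncpue) / np.log(log_base) / area


def summarize_metric(records: pd.DataFrame, value: str,
                     by: str = "species") -> pd.DataFrame:
    """Group mean +/- SD of a competition metric; empty groups are omitted.

    SD is reported as NaN for singleton groups (undefined, not zero).
    """
    g = records.dropna(subset=[value]).groupby(by, observed=True)[value]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    return out


@dataclass
class GroupComparison:
    """Outcome of the normality-gated omnibus test plus pairwise follow-ups."""

    normal: bool
    omnibus_test: str            # "anova" | "kruskal"
    statistic: float
    df: tuple
    p_value: float
    shapiro_p: dict[str, float]
    pairwise: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def compare_groups(values, groups, alpha: float = 0.05,
                   pairwise: bool = True) -> GroupComparison:
    """Compare a metric across groups with a Shapiro-Wilk gated design.

    If every group (n >= 3) passes Shapiro-Wilk at ``alpha``, a one-way
    ANOVA with Tukey HSD pairwise comparisons is used; otherwise
    Kruskal-Wallis with pairwise Wilcoxon rank-sum tests.  Groups with
    fewer than 3 values cannot be normality-tested and force the
    nonparametric branch.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[groups == g] for g in labels}

    shapiro_p: dict = {}
    normal = True
    for g, v in by.items():
        if len(v) < 3:
            normal = False
            shapiro_p[g] = np.nan
            continue
        if np.ptp(v) == 0:
            normal = False
            shapiro_p[g] = 0.0
            continue
        p = stats.shapiro(v).pvalue
        shapiro_p[g] = float(p)
        if p < alpha:
            normal = False

    if normal:
        stat, p = stats.f_oneway(*[by[g] for g in labels])
        pw = None
        if pairwise:
            tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
            pw = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        k, n = len(labels), len(values)
        return GroupComparison(True, "anova", float(stat), (k - 1, n - k),
                               float(p), shapiro_p, pw)
    stat, p = stats.kruskal(*[by[g] for g in labels])
    pw = None
    if pairwise:
        rows = []
        for a, b in itertools.combinations(labels, 2):
            r = stats.ranksums(by[a], by[b])
            rows.append({"group1": a, "group2": b,
                         "statistic": float(r.statistic), "p_value": float(r.pvalue)})
        pw = pd.DataFrame(rows)
    return GroupComparison(False, "kruskal", float(stat), (len(labels) - 1,),
                           float(p), shapiro_p, pw)


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[str, str]
    ss: tuple[float, float]
    df: tuple[int, int]
    pseudo_f: tuple[float, float]
    p_value: tuple[float, float]
    ss_residual: float
    df_residual: int
    n_perm: int


def _hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def _dummies(factor: np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Series(factor)).to_numpy(dtype=float)


def permanova2(responses: np.ndarray, factor_a, factor_b,
               n_perm: int = 999, seed: int = 0,
               exact: bool = False) -> PermanovaResult:
    """Two-way PERMANOVA on the Euclidean distance matrix.

    Sequential (Type I) sums of squares with factor A entered first are
    partitioned from the Gower-centred matrix of squared distances.
    Significance is by free permutation of rows: pseudo-F of each factor
    is recomputed on permuted distance matrices and

        p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) .

    ``exact=True`` enumerates all n! row permutations instead (identity
    included, p = fraction of permutations with F >= F_obs); feasible
    only for small n.
    """
    Y = np.asarray(responses, dtype=float)
    fa, fb = np.asarray(factor_a), np.asarray(factor_b)
    if len(pd.unique(fa)) < 2 or len(pd.unique(fb)) < 2:
        raise ValueError("each factor needs at least two levels")
    n = len(Y)
    d2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J

    Xa, Xb = _dummies(fa), _dummies(fb)
    one = np.ones((n, 1))
    Ha = _hat(np.hstack([one, Xa]))
    Hab = _hat(np.hstack([one, Xa, Xb]))
    df_a = np.linalg.matrix_rank(np.hstack([one, Xa])) - 1
    df_b = np.linalg.matrix_rank(np.hstack([one, Xa, Xb])) - 1 - df_a
    df_res = n - 1 - df_a - df_b
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats_for(Gp):
        ss_tot = np.trace(Gp)
        ss_a = float(np.sum(Ha * Gp))          # tr(Ha G), G centred
        ss_ab = float(np.sum(Hab * Gp))
        ss_b = ss_ab - ss_a
        ss_res = ss_tot - ss_ab
        f_a = (ss_a / df_a) / (ss_res / df_res)
        f_b = (ss_b / df_b) / (ss_res / df_res)
        return ss_a, ss_b, ss_res, f_a, f_b

    ss_a, ss_b, ss_res, f_a, f_b = stats_for(G)

    if exact:
        perms = itertools.permutations(range(n))
        count_a = count_b = total = 0
        for pm in perms:
            idx = np.asarray(pm)
            Gp = G[np.ix_(idx, idx)]
            *_, fpa, fpb = stats_for(Gp)
            count_a += fpa >= f_a - 1e-12
            count_b += fpb >= f_b - 1e-12
            total += 1
        p_a, p_b = count_a / total, count_b / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count_a = count_b = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            *_, fpa, fpb = stats_for(Gp)
            count_a += fpa >= f_a
            count_b += fpb >= f_b
        p_a = (1 + count_a) / (1 + n_perm)
        p_b = (1 + count_b) / (1 + n_perm)
        n_used = n_perm

    return PermanovaResult(
        terms=("factor_a", "factor_b"), ss=(float(ss_a), float(ss_b)),
        df=(int(df_a), int(df_b)), pseudo_f=(float(f_a), float(f_b)),
        p_value=(float(p_a), float(p_b)), ss_residual=float(ss_res),
        df_residual=int(df_res), n_perm=int(n_used),
    )
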