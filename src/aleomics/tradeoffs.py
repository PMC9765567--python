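"""Regulatory trade-off detection via jump-specific PCA and ANCOVA.

To avoid testing all iModulon pairs, candidate iModulons are first
filtered by principal-component analysis of jump-specific activity
differences: an iModulon qualifies if it carries an absolute loading above
a weight threshold in any component explaining at least a minimum fraction
of the variance. Candidate pairs are then tested on flask-level activities
with a Pearson sign filter and an ANCOVA (common slope, strain-specific
intercepts); trade-offs are negatively correlated pairs whose ANCOVA fit
is near-perfect (R^2 above threshold) with a BH-significant slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .convergence import bh_fdr
from .datatypes import SampleMeta, ValidationError

log = logging.getLogger(__name__)


def jump_pca(
    delta_a: pd.DataFrame,
    exclusions: Sequence[tuple[str, str]] | None = None,
    robust_z_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """PCA of the jumps x iModulons activity-difference matrix.

    Columns are mean-centered (no variance scaling) and components come
    from the covariance eigendecomposition. ``exclusions`` lists
    (jump_id, imodulon) outlier cells to neutralise; each is replaced by
    the column mean of the remaining jumps, removing its influence while
    keeping the jump in the analysis. ``robust_z_max``, when set, flags any
    cell with |value - median| / (1.4826 MAD) above the limit the same way.

    Returns (component scores jumps x k, explained-variance ratios summing
    to 1, loadings as a components x iModulons DataFrame).
    """
    x = delta_a.copy().astype(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 jumps and >= 2 iModulons")
    cells = list(exclusions or [])
    if robust_z_max is not None:
        med = x.median(axis=0)
        mad = 1.4826 * (x - med).abs().median(axis=0)
        for col in x.columns:
            if mad[col] == 0:
                continue
            z = (x[col] - med[col]).abs() / mad[col]
            cells += [(j, col) for j in x.index[z > robust_z_max]]
    for jump, imod in cells:
        if jump not in x.index or imod not in x.columns:
            raise ValidationError(f"unknown exclusion cell ({jump!r}, {imod!r})")
        others = x.loc[x.index != jump, imod]
        x.loc[jump, imod] = others.mean()
        log.info("jump_pca: neutralised outlier (%s, %s)", jump, imod)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    ev = s**2
    ev_ratio = ev / ev.sum()
    scores = u * s
    loadings = pd.DataFrame(
        vt, index=[f"PC{i + 1}" for i in range(vt.shape[0])], columns=x.columns
    )
    return scores, ev_ratio, loadings


def select_candidates(
    loadings: pd.DataFrame,
    ev_ratios: np.ndarray,
    weight_min: float = 0.10,
    ev_min: float = 0.05,
) -> list[str]:
    """iModulons with |loading| > weight_min in any component with EV >= ev_min."""
    selected: set[str] = set()
    for i, ev in enumerate(ev_ratios):
        if ev < ev_min:
            continue
        row = loadings.iloc[i]
        selected.update(row.index[row.abs() > weight_min])
    return sorted(selected)


@dataclass
class AncovaFit:
    r2: float
    slope: float
    slope_p: float
    homogeneity_p: float  # interaction F-test: strain-specific slopes?


def ancova_fit(
    y: Sequence[float], x: Sequence[float], strains: Sequence[str]
) -> AncovaFit:
    """Common-slope ANCOVA of y on x with strain-specific intercepts.

    ``homogeneity_p`` is the F-test p-value of adding strain x slope
    interactions; a small value means the strain regression lines are not
    parallel.
    """
    df = pd.DataFrame(
        {"y": np.asarray(y, float), "x": np.asarray(x, float),
         "strain": list(strains)}
    )
    if df["strain"].nunique() < 2:
        raise ValidationError("need >= 2 strains")
    if (df.groupby("strain").size() < 3).any():
        raise ValidationError("need >= 3 samples per strain")
    if np.std(df["x"]) == 0:
        raise ValidationError("x is constant; ANCOVA undefined")
    base = smf.ols("y ~ x + C(strain)", data=df).fit()
    inter = smf.ols("y ~ x * C(strain)", data=df).fit()
    comparison = sm.stats.anova_lm(base, inter)
    homogeneity_p = float(comparison["Pr(>F)"].iloc[1])
    if np.isnan(homogeneity_p):
        homogeneity_p = 1.0
    return AncovaFit(
        r2=float(base.rsquared),
        slope=float(base.params["x"]),
        slope_p=float(base.pvalues["x"]),
        homogeneity_p=homogeneity_p,
    )


@dataclass
class TradeoffPair:
    """A negatively coupled iModulon pair surviving the ANCOVA screen."""

    imodulon_a: str
    imodulon_b: str
    pearson_r: float
    ancova_r2: float
    slope: float
    q: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.pearson_r >= 0:
            raise ValidationError("trade-off pairs must be negatively correlated")
        if not (0.0 <= self.ancova_r2 <= 1.0):
            raise ValidationError("ancova_r2 outside [0, 1]")


def detect_tradeoffs(
    a: pd.DataFrame,
    meta: Sequence[SampleMeta],
    candidates: Sequence[str],
    r2_min: float = 0.95,
    fdr: float = 0.05,
    categories: Mapping[str, str] | None = None,
) -> tuple[list[TradeoffPair], pd.DataFrame]:
    """Screen candidate iModulon pairs for negative regulatory coupling.

    ``a`` is the flask-level (replicate-averaged) iModulons x flasks
    activity matrix; ``meta`` must map each column to a strain (column
    names "strain:flask" produced by replicate collapapsing are also
    accepted directly). Every unordered candidate pair is tested: pooled
    flask-level Pearson correlation, and common-slope ANCOVA of the later
    (alphabetically) iModulon on the earlier. Pairs qualify when the
    Pearson r is negative, the BH-adjusted ANCOVA slope p is <= ``fdr``
    and the ANCOVA R^2 exceeds ``r2_min``.

    Returns (qualifying pairs sorted by q, full per-pair test table).
    """
    missing = [c for c in candidates if c not in a.index]
    if missing:
        raise ValidationError(f"candidates absent from activity matrix: {missing}")
    strain_of: dict[str, str] = {m.sample_id: m.strain for m in meta}
    strains = []
    for col in a.columns:
        if col in strain_of:
            strains.append(strain_of[col])
        elif ":" in col:
            strains.append(col.split(":", 1)[0])
        else:
            raise ValidationError(f"cannot resolve strain for column {col!r}")
    cats = dict(categories or {})
    rows = []
    for im_a, im_b in combinations(sorted(candidates), 2):
        ya = a.loc[im_a].to_numpy(dtype=float)
        yb = a.loc[im_b].to_numpy(dtype=float)
        if np.std(ya) == 0 or np.std(yb) == 0:
            continue
        r, _ = stats.pearsonr(ya, yb)
        fit = ancova_fit(yb, ya, strains)
        rows.append(
            {
                "imodulon_a": im_a,
                "imodulon_b": im_b,
                "pearson_r": float(r),
                "ancova_r2": fit.r2,
                "slope": fit.slope,
                "slope_p": fit.slope_p,
                "homogeneity_p": fit.homogeneity_p,
            }
        )
    table = pd.DataFrame(rows)
    if not len(table):
        return [], table
    table["q"] = bh_fdr(table["slope_p"])
    keep = (
        (table["pearson_r"] < 0)
        & (table["q"] <= fdr)
        & (table["ancova_r2"] > r2_min)
    )
    pairs = [
        TradeoffPair(
            imodulon_a=row.imodulon_a,
            imodulon_b=row.imodulon_b,
            pearson_r=row.pearson_r,
            ancova_r2=row.ancova_r2,
            slope=row.slope,
            q=row.q,
            group=cats.get(row.imodulon_a, cats.get(row.imodulon_b, "")),
        )
        for row in table[keep].itertuples()
    ]
    pairs.sort(key=lambda p: (p.q, p.imodulon_a, p.imodulon_b))
    return pairs, table
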