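"""Convergence/divergence rank statistics and shared screens.

Convergence of a phenotype across strains is tested by transforming the
per-strain means at the wild-type (WT) and endpoint (EP) stages into
vectors of unordered pairwise distances (s strains give s(s-1)/2 distances
each) and asking, with a one-sided Mann-Whitney U test, whether the EP
distances are stochastically smaller (convergent) or larger (divergent)
than the WT distances. p-values use the normal approximation with
continuity correction — the exact tables do not cover small-U, tied
configurations — and are Benjamini-Hochberg adjusted across the phenotype
panel within each direction.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PhenotypeTable, ValidationError


def pairwise_distances(values: pd.Series | Sequence[float]) -> np.ndarray:
    """All unordered-pair absolute differences of per-strain means.

    The pair order is canonical: pairs (i, j), i < j, in the input order of
    the strains. Six strains give 15 distances.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValidationError(
            f"need >= 2 non-missing strain values, got {arr.size}"
        )
    return np.array([abs(arr[i] - arr[j]) for i, j in combinations(range(arr.size), 2)])


def mwu_u(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Mann-Whitney U counted as pairs (x < y), ties counted half.

    With xs = EP distances and ys = WT distances, large U means the EP
    values are systematically smaller (convergence); small U means the
    reverse (divergence).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValidationError("both samples must be non-empty")
    less = (xs[:, None] < ys[None, :]).sum()
    ties = (xs[:, None] == ys[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def _tie_term(pooled: np.ndarray) -> float:
    """Standard tie correction term sum(t^3 - t) over tied groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mwu_normal_p(
    U: float,
    n1: int,
    n2: int,
    alternative: str = "less",
    continuity: bool = True,
    tie_term: float = 0.0,
) -> float:
    """Normal-approximation p-value for the Mann-Whitney U statistic.

    ``alternative="less"`` gives the lower tail (U small), "greater" the
    upper tail. ``tie_term`` is sum(t^3 - t) over tied groups in the pooled
    sample (0 when there are no ties). When the variance degenerates (all
    values tied) the test is uninformative and p = 1 is returned with a
    warning.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("n1 and n2 must be >= 1")
    if alternative not in ("less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n = n1 + n2
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("Mann-Whitney variance is zero (all values tied); p = 1")
        return 1.0
    cc = 0.5 if continuity else 0.0
    sd = np.sqrt(var)
    if alternative == "less":
        return float(stats.norm.cdf((U + cc - mean) / sd))
    return float(stats.norm.sf((U - cc - mean) / sd))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_convergence(
    table: PhenotypeTable, fdr: float = 0.05
) -> pd.DataFrame:
    """Label each phenotype convergent, divergent, or neither.

    For each phenotype, per-strain WT and EP means are converted to
    pairwise-distance vectors and two one-sided Mann-Whitney tests are run
    on (EP distances vs WT distances): the upper tail of U (EP < WT pairs
    dominate) supports convergence, the lower tail divergence. BH is
    applied within each direction across the panel; a phenotype is labelled
    by whichever direction passes ``fdr`` (the two one-sided tests cannot
    both pass).

    Returns a frame with columns phenotype_id, U, p_convergent,
    p_divergent, q_convergent, q_divergent, label.
    """
    rows = []
    for pid in table.phenotype_ids:
        wt = table.stage_means(pid, "WT").dropna()
        ep = table.stage_means(pid, "EP").dropna()
        common = [s for s in wt.index if s in set(ep.index)]
        if len(common) < 2:
            warnings.warn(f"phenotype {pid!r} lacks WT/EP means for >= 2 strains; skipped")
            continue
        d_wt = pairwise_distances(wt.loc[common])
        d_ep = pairwise_distances(ep.loc[common])
        u = mwu_u(d_ep, d_wt)
        tie = _tie_term(np.concatenate([d_ep, d_wt]))
        n1, n2 = d_ep.size, d_wt.size
        p_conv = mwu_normal_p(u, n1, n2, "greater", tie_term=tie)
        p_div = mwu_normal_p(u, n1, n2, "less", tie_term=tie)
        rows.append({"phenotype_id": pid, "U": u, "p_convergent": p_conv, "p_divergent": p_div})
    if not rows:
        return pd.DataFrame(
            columns=["phenotype_id", "U", "p_convergent", "p_divergent",
                     "q_convergent", "q_divergent", "label"]
        )
    out = pd.DataFrame(rows)
    out["q_convergent"] = bh_fdr(out["p_convergent"])
    out["q_divergent"] = bh_fdr(out["p_divergent"])
    label = np.where(
        out["q_convergent"] <= fdr,
        "convergent",
        np.where(out["q_divergent"] <= fdr, "divergent", "neither"),
    )
    out["label"] = label
    return out


def growth_correlation_screen(
    values: pd.DataFrame,
    growth_rates: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of per-flask values against growth rate, pooled.

    ``values`` is targets x observations (columns aligned with
    ``growth_rates``). Targets with constant values are reported with
    r = 0, p = 1 and can never be significant. Returns a frame with
    columns target, r, p, q, significant.
    """
    common = [c for c in values.columns if c in growth_rates.index]
    if len(common) < 3:
        raise ValidationError("need >= 3 paired observations")
    g = growth_rates.loc[common].to_numpy(dtype=float)
    rows = []
    for target, row in values[common].iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~(np.isnan(y) | np.isnan(g))
        if ok.sum() < 3 or np.std(y[ok]) == 0 or np.std(g[ok]) == 0:
            rows.append({"target": target, "r": 0.0, "p": 1.0})
            continue
        r, p = stats.pearsonr(y[ok], g[ok])
        rows.append({"target": target, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] <= fdr
    return out


def anova_f_strain(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F statistic and upper-tail p.

    ``groups`` holds the observations of one variable grouped by strain.
    When every group has zero within-group variance but means differ, the
    F statistic is infinite by convention and p = 0 (with a warning).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValidationError("each group needs >= 2 observations")
    all_ = np.concatenate(gs)
    grand = all_.mean()
    k = len(gs)
    n = all_.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance everywhere; F = inf, p = 0")
        return float("inf"), 0.0
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    f = ms_between / ms_within
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p
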