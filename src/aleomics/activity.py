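"""iModulon activity projection and differential-activation analysis.

Expression decomposes as X = M.A where M is a fixed gene-weight basis from
ICA of a reference compendium and A holds per-sample activities. New
samples are projected onto the basis by the least-squares solution
A = pinv(M).X over the shared gene set. Differential iModulon activation
(DIMA) compares mean activities between two conditions against a
log-normal null fitted to absolute activity differences between biological
replicates; a change is called significant only if its BH-adjusted p-value
passes and the absolute change exceeds a minimum-change threshold (default
5 activity units).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .convergence import anova_f_strain, bh_fdr
from .datatypes import (
    ActivityMatrix,
    ExpressionMatrix,
    IModulonModel,
    SampleMeta,
    ValidationError,
)

log = logging.getLogger(__name__)


def project_activities(
    m: IModulonModel,
    x: ExpressionMatrix,
    center: Sequence[str] | None = None,
    min_gene_fraction: float = 0.5,
) -> ActivityMatrix:
    """Project expression onto the iModulon basis: A = pinv(M).X.

    The projection uses the exact string intersection of gene ids between
    M and X; it refuses to run if fewer than ``min_gene_fraction`` of M's
    genes match. ``center`` optionally names a reference sample set whose
    per-gene mean is subtracted from X before projection (activity
    differences are invariant to this choice).
    """
    shared = [g for g in m.gene_ids if g in set(x.gene_ids)]
    frac = len(shared) / len(m.gene_ids)
    log.info(
        "project_activities: %d shared genes (%.0f%% of basis)",
        len(shared), 100 * frac,
    )
    if frac < min_gene_fraction:
        raise ValidationError(
            f"only {len(shared)}/{len(m.gene_ids)} basis genes present in "
            f"expression matrix (< {min_gene_fraction:.0%})"
        )
    mm = m.weights.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mm)
    k = mm.shape[1]
    if rank < k:
        raise ValidationError(
            f"basis restricted to shared genes is rank deficient: "
            f"{k - rank} dimension(s) lost"
        )
    xx = x.data.loc[shared].to_numpy(dtype=float)
    if center is not None:
        ref = x.data.loc[shared, list(center)].to_numpy(dtype=float)
        xx = xx - ref.mean(axis=1, keepdims=True)
    a = np.linalg.pinv(mm) @ xx
    return ActivityMatrix(
        pd.DataFrame(a, index=m.imodulon_names, columns=x.sample_ids)
    )


def explained_variance(
    m: IModulonModel,
    a: ActivityMatrix,
    x: ExpressionMatrix,
    sample_subset: Sequence[str] | None = None,
    centered: bool = True,
) -> float:
    """Fraction of expression variance captured by the basis on a subset.

    Computed as 1 - ||R||_F^2 / ||X_c||_F^2 where R = X - M.A restricted to
    the subset and, in the default centered mode, both R and X are centered
    per gene over the subset (so the denominator is the per-gene expression
    variance). Uncentered mode skips the centering on both sides.
    """
    samples = list(sample_subset) if sample_subset is not None else x.sample_ids
    shared = [g for g in m.gene_ids if g in set(x.gene_ids)]
    xx = x.data.loc[shared, samples].to_numpy(dtype=float)
    mm = m.weights.loc[shared].to_numpy(dtype=float)
    aa = a.data.loc[m.imodulon_names, samples].to_numpy(dtype=float)
    resid = xx - mm @ aa
    if centered:
        xx = xx - xx.mean(axis=1, keepdims=True)
        resid = resid - resid.mean(axis=1, keepdims=True)
    denom = float((xx**2).sum())
    if denom == 0:
        raise ValidationError("zero-variance sample subset")
    return 1.0 - float((resid**2).sum()) / denom


@dataclass
class LogNormalNull:
    """Log-normal null for absolute replicate activity differences."""

    mu: float
    sigma: float
    n_fit: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.n_fit < 10:
            warnings.warn(
                f"log-normal null fitted on only {self.n_fit} differences"
            )

    def p_value(self, delta: float) -> float:
        """Upper-tail probability of |delta| under the null; 0 maps to p=1."""
        d = abs(delta)
        if d == 0:
            return 1.0
        return float(stats.norm.sf((np.log(d) - self.mu) / self.sigma))


def fit_replicate_null(
    a: ActivityMatrix, replicate_groups: Mapping[str, Sequence[str]]
) -> LogNormalNull:
    """Fit the log-normal replicate null from pooled |activity differences|.

    Differences are taken between every pair of replicate samples within
    each group, pooled across all iModulons; exact zeros (undefined on the
    log scale) are dropped with a logged count. The maximum-likelihood fit
    is mu = mean(log d), sigma = std(log d).
    """
    diffs: list[np.ndarray] = []
    for group, members in replicate_groups.items():
        members = list(members)
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                diffs.append(
                    np.abs(
                        a.data[members[i]].to_numpy(dtype=float)
                        - a.data[members[j]].to_numpy(dtype=float)
                    )
                )
    if not diffs:
        raise ValidationError("no replicate pairs available")
    d = np.concatenate(diffs)
    nonzero = d[d > 0]
    dropped = d.size - nonzero.size
    if dropped:
        log.info("fit_replicate_null: dropped %d zero differences", dropped)
    if nonzero.size == 0:
        raise ValidationError("all replicate differences are zero")
    logd = np.log(nonzero)
    sigma = float(np.std(logd))
    if sigma == 0:
        raise ValidationError("replicate differences are all identical")
    return LogNormalNull(mu=float(np.mean(logd)), sigma=sigma, n_fit=int(nonzero.size))


@dataclass
class DimaResult:
    """Differential iModulon activation between two conditions."""

    imodulon: str
    delta_activity: float
    p: float
    q: float
    significant: bool
    direction: str
    category: str = "unknown"


def dima(
    a: ActivityMatrix,
    pair: tuple[Sequence[str], Sequence[str]],
    null: LogNormalNull,
    min_change: float = 5.0,
    alpha: float = 0.05,
    min_fc: float | None = None,
    categories: Mapping[str, str] | None = None,
) -> list[DimaResult]:
    """Differential activation of every iModulon between two conditions.

    delta = mean(condition 2) - mean(condition 1); p is the upper-tail
    probability of |delta| under the replicate null, BH-adjusted across
    iModulons. Significance requires q <= alpha AND |delta| > min_change
    (and, if ``min_fc`` is set, an activity fold-change of at least that
    much).
    """
    cond1, cond2 = (list(pair[0]), list(pair[1]))
    if not cond1 or not cond2:
        raise ValidationError("both conditions must be non-empty")
    for s in cond1 + cond2:
        if s not in a.data.columns:
            raise ValidationError(f"sample {s!r} not in activity matrix")
    m1 = a.data[cond1].mean(axis=1)
    m2 = a.data[cond2].mean(axis=1)
    delta = (m2 - m1).to_numpy(dtype=float)
    ps = np.array([null.p_value(d) for d in delta])
    qs = bh_fdr(ps)
    cats = dict(categories or {})
    results = []
    for name, d, p, q in zip(a.imodulon_names, delta, ps, qs):
        sig = (q <= alpha) and (abs(d) > min_change)
        if sig and min_fc is not None:
            lo, hi = sorted([abs(m1[name]), abs(m2[name])])
            sig = lo == 0 or hi / lo >= min_fc
        results.append(
            DimaResult(
                imodulon=name,
                delta_activity=float(d),
                p=float(p),
                q=float(q),
                significant=bool(sig),
                direction="increased" if d >= 0 else "decreased",
                category=cats.get(name, "unknown"),
            )
        )
    return results


def dima_results_frame(results: Sequence[DimaResult], condition_pair: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "imodulon": r.imodulon,
                "condition_pair": condition_pair,
                "delta": r.delta_activity,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "direction": r.direction,
                "category": r.category,
            }
            for r in results
        ]
    )


def dima_screen(
    a: ActivityMatrix,
    meta: Sequence[SampleMeta],
    null: LogNormalNull,
    categories: Mapping[str, str] | None = None,
    min_change: float = 5.0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """DIMA tables for every ALE jump and for WT vs EP of each strain.

    Conditions are the replicate sample sets of the two flasks being
    compared. Returns {"jumps": per-jump results, "wt_ep": per-strain
    WT-vs-EP results, "category_counts": significant counts aggregated by
    functional category and direction}.
    """
    by_flask: dict[tuple[str, int], list[str]] = {}
    stage_of: dict[tuple[str, int], str] = {}
    for m in meta:
        if m.sample_id in a.data.columns:
            by_flask.setdefault((m.strain, m.flask_index), []).append(m.sample_id)
            stage_of[(m.strain, m.flask_index)] = m.stage
    strains = sorted({s for s, _ in by_flask})
    jump_frames, wt_ep_frames = [], []
    for strain in strains:
        flasks = sorted(f for s, f in by_flask if s == strain)
        for lo, hi in zip(flasks[:-1], flasks[1:]):
            res = dima(
                a, (by_flask[(strain, lo)], by_flask[(strain, hi)]),
                null, min_change=min_change, alpha=alpha, categories=categories,
            )
            jump_frames.append(
                dima_results_frame(res, f"{strain}:{lo}->{hi}").assign(strain=strain)
            )
        wt = [f for f in flasks if stage_of[(strain, f)] == "WT"]
        ep = [f for f in flasks if stage_of[(strain, f)] == "EP"]
        if wt and ep:
            res = dima(
                a, (by_flask[(strain, wt[0])], by_flask[(strain, ep[-1])]),
                null, min_change=min_change, alpha=alpha, categories=categories,
            )
            wt_ep_frames.append(
                dima_results_frame(res, f"{strain}:WT->EP").assign(strain=strain)
            )
    jumps = pd.concat(jump_frames, ignore_index=True) if jump_frames else pd.DataFrame()
    wt_ep = pd.concat(wt_ep_frames, ignore_index=True) if wt_ep_frames else pd.DataFrame()
    if len(wt_ep):
        sig = wt_ep[wt_ep["significant"]]
        counts = (
            sig.groupby(["category", "direction"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
    else:
        counts = pd.DataFrame(columns=["category", "direction", "count"])
    return {"jumps": jumps, "wt_ep": wt_ep, "category_counts": counts}


def wt_discriminating(
    a: ActivityMatrix,
    meta: Sequence[SampleMeta],
    fdr: float = 0.005,
) -> pd.DataFrame:
    """iModulons whose WT activities separate the strains (ANOVA F-test).

    Restricted to WT-stage samples; one one-way F-test per iModulon with
    strain as the factor, BH-adjusted across iModulons.
    """
    wt = [m for m in meta if m.stage == "WT" and m.sample_id in a.data.columns]
    strains = sorted({m.strain for m in wt})
    if len(strains) < 2:
        raise ValidationError("need WT samples from >= 2 strains")
    groups_ids = {
        s: [m.sample_id for m in wt if m.strain == s] for s in strains
    }
    if any(len(v) < 2 for v in groups_ids.values()):
        short = [s for s, v in groups_ids.items() if len(v) < 2]
        raise ValidationError(f"strains with < 2 WT samples: {short}")
    rows = []
    for name in a.imodulon_names:
        groups = [
            a.data.loc[name, ids].to_numpy(dtype=float)
            for ids in groups_ids.values()
        ]
        f, p = anova_f_strain(groups)
        rows.append({"imodulon": name, "F": f, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] <= fdr
    return out


def growth_correlated_imodulons(
    a: ActivityMatrix,
    meta: Sequence[SampleMeta],
    r_min: float = 0.75,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """iModulons coupled to growth rate consistently across strains.

    Per strain, the Pearson correlation of activity against flask growth
    rate is computed over that strain's samples; an iModulon qualifies when
    the median |R| across strains exceeds ``r_min`` and the median p-value
    is below ``p_max``. The reported sign is the sign of the median R.
    Constant activities within a strain contribute R = 0, p = 1.
    """
    by_strain: dict[str, list[SampleMeta]] = {}
    for m in meta:
        if m.sample_id in a.data.columns and not np.isnan(m.growth_rate):
            by_strain.setdefault(m.strain, []).append(m)
    for s, ms in by_strain.items():
        if len({m.flask_index for m in ms}) < 3:
            raise ValidationError(f"strain {s!r} has < 3 assayed flasks")
    rows = []
    for name in a.imodulon_names:
        rs, ps = [], []
        for s, ms in sorted(by_strain.items()):
            ids = [m.sample_id for m in ms]
            g = np.array([m.growth_rate for m in ms])
            y = a.data.loc[name, ids].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(g) == 0:
                rs.append(0.0)
                ps.append(1.0)
                continue
            r, p = stats.pearsonr(y, g)
            rs.append(float(r))
            ps.append(float(p))
        med_r = float(np.median(rs))
        med_abs_r = float(np.median(np.abs(rs)))
        med_p = float(np.median(ps))
        selected = (med_abs_r > r_min) and (med_p < p_max)
        rows.append(
            {
                "imodulon": name,
                "median_r": med_r,
                "median_abs_r": med_abs_r,
                "median_p": med_p,
                "sign": int(np.sign(med_r)) if selected else 0,
                "selected": selected,
            }
        )
    return pd.DataFrame(rows)
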