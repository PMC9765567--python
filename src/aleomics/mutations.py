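"""Mutation-systems correlate screening on jump-specific differences.

Each ALE jump either gains a mutation at a locus or it does not, giving a
binary feature per locus over jumps. Associations between these features
and jump-specific changes in reaction flux or iModulon activity are
screened with point-biserial correlation (equivalently a two-sample t) or
a seeded label-permutation test, BH-corrected separately within flux
targets and iModulon targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .convergence import bh_fdr
from .datatypes import MutationEvent, ValidationError
from .trajectory import Jump

log = logging.getLogger(__name__)


def build_features(
    mutations: Sequence[MutationEvent],
    jumps: Sequence[Jump],
    level: str = "gene",
    min_jumps: int = 2,
    strain_specific: bool = False,
) -> pd.DataFrame:
    """Binary jumps x mutation-features matrix of gained mutations.

    A feature is 1 for a jump iff at least one event at that locus (or
    exact nucleotide change, at ``level="nucleotide"``) is gained in the
    jump. Features present in fewer than ``min_jumps`` jumps are dropped
    (untestable) with a logged count. With ``strain_specific=True``,
    loci mutated in two or more strains additionally get per-strain
    refinements named "locus(strain)" (feature AND strain indicator).
    """
    if level not in ("gene", "nucleotide"):
        raise ValidationError(f"unknown feature level {level!r}")
    cols: dict[str, np.ndarray] = {}
    n = len(jumps)
    for i, j in enumerate(jumps):
        for locus in j.gained_mutations:
            cols.setdefault(locus, np.zeros(n, dtype=int))[i] = 1
    if strain_specific:
        strain_of_jump = np.array([j.strain for j in jumps])
        for locus, vec in list(cols.items()):
            strains_hit = sorted(set(strain_of_jump[vec == 1]))
            if len(strains_hit) >= 2:
                for s in strains_hit:
                    cols[f"{locus}({s})"] = vec * (strain_of_jump == s)
    matrix = pd.DataFrame(cols, index=[j.jump_id for j in jumps])
    counts = matrix.sum(axis=0)
    dropped = counts.index[counts < min_jumps]
    if len(dropped):
        log.info(
            "build_features: dropped %d feature(s) present in < %d jumps",
            len(dropped), min_jumps,
        )
    return matrix.drop(columns=dropped).sort_index(axis=1)


def associate(
    feature: Sequence[int],
    deltas: Sequence[float],
    method: str = "point_biserial",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Association between a binary jump feature and a continuous delta.

    Default is the point-biserial correlation with its two-sided t-based
    p-value. ``method="permutation"`` keeps the same statistic but derives
    the p-value from seeded random permutations of the feature labels.
    """
    f = np.asarray(feature, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if set(np.unique(f)) - {0.0, 1.0}:
        raise ValidationError("feature must be binary")
    if f.min() == f.max():
        raise ValidationError("feature has a single class; association undefined")
    r, p = stats.pointbiserialr(f, d)
    r = float(r)
    if method == "point_biserial":
        return r, float(p)
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(f)
        rp, _ = stats.pointbiserialr(perm, d)
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return r, (count + 1) / (n_permutations + 1)


@dataclass
class MutationCorrelate:
    """A significant mutation-feature / jump-delta association."""

    feature: str
    target: str
    target_kind: str  # "flux" or "imodulon"
    statistic: float
    p: float
    q: float
    n_jumps_with_feature: int


def screen_correlates(
    features: pd.DataFrame,
    delta_flux: pd.DataFrame | None,
    delta_activity: pd.DataFrame | None,
    fdr: float = 0.05,
    method: str = "point_biserial",
    seed: int = 0,
) -> tuple[list[MutationCorrelate], pd.DataFrame]:
    """Screen every mutation feature against every jump-delta target.

    ``delta_flux`` and ``delta_activity`` are jumps x targets frames
    aligned on the feature matrix's jump index. BH correction is applied
    separately within the flux and iModulon target families. Returns
    (significant correlates sorted by q, full test table).
    """
    rows = []
    for kind, deltas in (("flux", delta_flux), ("imodulon", delta_activity)):
        if deltas is None or deltas.empty:
            continue
        missing = [j for j in features.index if j not in deltas.index]
        if missing:
            raise ValidationError(f"jumps missing from {kind} deltas: {missing}")
        aligned = deltas.loc[features.index]
        for feat in features.columns:
            fvec = features[feat].to_numpy()
            if fvec.min() == fvec.max():
                continue
            for target in aligned.columns:
                d = aligned[target].to_numpy(dtype=float)
                if np.std(d) == 0:
                    continue
                r, p = associate(fvec, d, method=method, seed=seed)
                rows.append(
                    {
                        "feature": feat,
                        "target": target,
                        "target_kind": kind,
                        "statistic": r,
                        "p": p,
                        "n_jumps_with_feature": int(fvec.sum()),
                    }
                )
    table = pd.DataFrame(rows)
    if not len(table):
        return [], table
    table["q"] = np.nan
    for kind in table["target_kind"].unique():
        mask = table["target_kind"] == kind
        table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"])
    hits = [
        MutationCorrelate(
            feature=r.feature,
            target=r.target,
            target_kind=r.target_kind,
            statistic=r.statistic,
            p=r.p,
            q=r.q,
            n_jumps_with_feature=r.n_jumps_with_feature,
        )
        for r in table[table["q"] <= fdr].itertuples()
    ]
    hits.sort(key=lambda h: (h.q, h.feature, h.target))
    return hits, table
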