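"""Growth-rate fitting, monotone fitness trajectories, and jump differencing.

A "jump" is the difference between two consecutively assayed flasks of one
strain: in growth rate, in omics profiles (delta activities or fluxes), and
in the mutations gained between the two flasks. Differencing a 22-flask,
six-strain design yields 16 jumps (flasks minus strains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .datatypes import MutationEvent, SampleMeta, ValidationError, assayed_flasks


def growth_rate_from_od(times: Sequence[float], ods: Sequence[float]) -> float:
    """Exponential growth rate as the OLS slope of ln(OD600) on time (1/h)."""
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size < 2:
        raise ValidationError("need >= 2 OD measurements")
    if (od <= 0).any():
        raise ValidationError("OD600 values must be > 0")
    if (np.diff(t) <= 0).any():
        raise ValidationError("times must be strictly increasing")
    slope, _ = np.polyfit(t, np.log(od), 1)
    return float(slope)


def smooth_trajectory(
    flask_indices: Sequence[float],
    rates: Sequence[float],
    n_grid: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monotone fitness trajectory through per-flask growth rates.

    Node values are first made monotone non-decreasing by isotonic
    regression (pool-adjacent-violators), then interpolated with a
    monotonicity-preserving cubic (PCHIP), so the sampled curve never
    overshoots between nodes and never decreases.

    Returns (grid, smoothed values on grid, adjusted node values).
    """
    x = np.asarray(flask_indices, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size < 2:
        raise ValidationError("need >= 2 nodes")
    if (np.diff(x) <= 0).any():
        raise ValidationError("flask indices must be strictly increasing")
    iso = IsotonicRegression(increasing=True)
    y_adj = iso.fit_transform(x, y)
    interp = PchipInterpolator(x, y_adj)
    grid = np.unique(np.concatenate([np.linspace(x[0], x[-1], n_grid), x]))
    return grid, interp(grid), y_adj


def doubling_time_minutes(rate: float) -> float:
    """Doubling time in minutes for an exponential growth rate in 1/h."""
    if rate <= 0:
        raise ValidationError(f"growth rate must be > 0, got {rate}")
    return 60.0 * np.log(2.0) / rate


@dataclass
class Jump:
    """One consecutive assayed-flask difference within a strain."""

    strain: str
    from_flask: int
    to_flask: int
    delta_growth: float = float("nan")
    gained_mutations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.to_flask <= self.from_flask:
            raise ValidationError(
                f"to_flask ({self.to_flask}) must exceed from_flask "
                f"({self.from_flask})"
            )

    @property
    def jump_id(self) -> str:
        return f"{self.strain}:{self.from_flask}->{self.to_flask}"


def collapse_replicates(
    x: pd.DataFrame, meta: Sequence[SampleMeta]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicate columns to one profile per (strain, flask).

    ``x`` is features x samples. Returns (flask-level features matrix with
    columns "strain:flask", flask-level metadata frame with strain,
    flask_index, stage and mean growth_rate).
    """
    by_sample = {m.sample_id: m for m in meta}
    missing = [c for c in x.columns if c not in by_sample]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    cols: dict[str, list[str]] = {}
    info: dict[str, dict] = {}
    for c in x.columns:
        m = by_sample[c]
        key = f"{m.strain}:{m.flask_index}"
        cols.setdefault(key, []).append(c)
        info.setdefault(
            key,
            {"strain": m.strain, "flask_index": m.flask_index, "stage": m.stage,
             "growth_rates": []},
        )
        info[key]["growth_rates"].append(m.growth_rate)
    flask_x = pd.DataFrame(
        {k: x[v].mean(axis=1) for k, v in cols.items()}, index=x.index
    )
    flask_meta = pd.DataFrame(
        [
            {
                "flask_id": k,
                "strain": v["strain"],
                "flask_index": v["flask_index"],
                "stage": v["stage"],
                "growth_rate": float(np.nanmean(v["growth_rates"])),
            }
            for k, v in info.items()
        ]
    ).set_index("flask_id")
    order = flask_meta.sort_values(["strain", "flask_index"]).index
    return flask_x[order], flask_meta.loc[order]


def mutations_present_at(
    events: Sequence[MutationEvent],
    strain: str,
    flask: int,
    strain_flasks: Sequence[int],
    level: str = "gene",
) -> frozenset[str]:
    """Loci (or nucleotide ids) present in a strain's clone at a flask.

    A mutation persists once gained; events observed at an unassayed flask
    are attributed to the first assayed flask at or after the observation
    (with a warning).
    """
    flasks = sorted(strain_flasks)
    present: set[str] = set()
    for e in events:
        if e.strain != strain:
            continue
        obs = e.observed_flask
        if obs not in flasks:
            later = [f for f in flasks if f >= obs]
            if not later:
                continue
            warnings.warn(
                f"mutation {e.locus} observed at unassayed flask {obs}; "
                f"assigned to flask {later[0]}"
            )
            obs = later[0]
        if obs <= flask:
            key = e.locus if level == "gene" else (e.nucleotide_id or e.locus)
            present.add(key)
    return frozenset(present)


def compute_jumps(
    x: pd.DataFrame,
    meta: Sequence[SampleMeta],
    mutations: Sequence[MutationEvent] | None = None,
    level: str = "gene",
) -> tuple[pd.DataFrame, list[Jump]]:
    """Jump-specific differencing of a flask-level feature matrix.

    ``x`` is features x samples (replicates allowed; they are averaged per
    flask before differencing). For every consecutive pair of assayed
    flasks within a strain, one row of later-minus-earlier feature
    differences is emitted; the row order is strains sorted, flasks
    ascending. Gained mutations are loci present at the later flask but not
    the earlier one.

    Returns (JumpMatrix: jumps x features DataFrame indexed by jump_id,
    list of Jump records in the same order).
    """
    flask_x, flask_meta = collapse_replicates(x, meta)
    jumps: list[Jump] = []
    rows: list[np.ndarray] = []
    per_strain = assayed_flasks(list(meta))
    for strain in sorted(per_strain):
        flasks = per_strain[strain]
        if len(flasks) < 2:
            warnings.warn(f"strain {strain!r} has a single assayed flask; no jumps")
            continue
        for lo, hi in zip(flasks[:-1], flasks[1:]):
            key_lo, key_hi = f"{strain}:{lo}", f"{strain}:{hi}"
            delta = flask_x[key_hi] - flask_x[key_lo]
            dg = float(
                flask_meta.loc[key_hi, "growth_rate"]
                - flask_meta.loc[key_lo, "growth_rate"]
            )
            gained: frozenset[str] = frozenset()
            if mutations is not None:
                before = mutations_present_at(mutations, strain, lo, flasks, level)
                after = mutations_present_at(mutations, strain, hi, flasks, level)
                gained = frozenset(after - before)
            jumps.append(
                Jump(strain=strain, from_flask=lo, to_flask=hi,
                     delta_growth=dg, gained_mutations=gained)
            )
            rows.append(delta.to_numpy(dtype=float))
    matrix = pd.DataFrame(
        rows, index=[j.jump_id for j in jumps], columns=x.index
    )
    return matrix, jumps
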