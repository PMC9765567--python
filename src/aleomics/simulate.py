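"""Synthetic six-strain ALE multi-omics generator with planted truths.

Every downstream stage of the analysis has a recoverable signal planted
here: convergent/divergent/neutral phenotype trajectories, growth-coupled
iModulons (positive and negative), negatively coupled trade-off pairs,
strain-specific wild-type activity offsets, and mutations whose gain at a
jump shifts a reaction flux or an iModulon activity. Expression is
generated as X = M.A plus Gaussian noise from a sparse, near-orthogonal
gene-weight basis; biological replicates of a flask differ by a symmetric
perturbation whose magnitude is log-normal, matching the form of the
differential-activation null.

The default parameters define the study conditions emulated throughout the
test suite: 6 strains, 22 assayed flasks (16 jumps), biological duplicates,
growth plateaus in [0.98, 1.11] 1/h, an activity scale on which a
biologically meaningful shift is ~10 units against the minimum-change
threshold of 5, and a causal-mutation structure of 4 flux-coupled plus 8
activity-coupled loci.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as aio
from .datatypes import (
    ActivityMatrix,
    ExpressionMatrix,
    FluxRecord,
    IModulonModel,
    MutationEvent,
    PhenotypeTable,
    SampleMeta,
    ValidationError,
)

log = logging.getLogger(__name__)

DEFAULT_STRAINS = ("MG1655", "W3110", "BL21", "C", "W", "Crooks")

# 11 functional categories used for DIMA count aggregation
CATEGORIES = (
    "stress response", "translation", "carbon metabolism", "metal homeostasis",
    "amino acid biosynthesis", "nucleotide biosynthesis", "motility",
    "structural components", "energy metabolism", "regulatory", "unknown",
)

FLUX_REACTIONS = (
    "G6PDH", "ME2", "SUCCOAS", "EDD", "GLCpts", "CS", "PGI", "ATPS4r",
)

CAUSAL_FLUX_LOCI = {"zwf": "G6PDH", "pykF": "ME2", "lysC": "SUCCOAS", "edd": "EDD"}

CAUSAL_ACTIVITY_LOCI = (
    "rpoB", "rpoC", "spoT", "hns/tdk", "mrdA", "folM", "pntA/ydgH", "cspC",
)

BACKGROUND_LOCI = ("yabC", "intQ", "insH1", "ylbE", "wbbL", "rph")


@dataclass
class PlantedTruth:
    """Ground truth planted into one synthetic dataset."""

    convergent_phenotypes: list[str]
    divergent_phenotypes: list[str]
    neutral_phenotypes: list[str]
    growth_correlated_imodulons: dict[str, int]  # name -> +1 / -1
    tradeoff_pairs: list[tuple[str, str, float]]  # (a, b, c>0): b = -c*a + ...
    wt_offset_imodulons: dict[str, dict[str, float]]  # strain -> {imod: offset}
    causal_mutations: dict[str, tuple[str, str, float]]  # locus -> (kind, target, effect)

    def __post_init__(self) -> None:
        sets = [
            set(self.convergent_phenotypes),
            set(self.divergent_phenotypes),
            set(self.neutral_phenotypes),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValidationError(
                        f"phenotype labels overlap: {sorted(overlap)}"
                    )
        for a, b, c in self.tradeoff_pairs:
            if c <= 0:
                raise ValidationError(
                    f"trade-off pair ({a}, {b}) declares non-positive "
                    f"coupling coefficient {c}"
                )
        for locus, (kind, target, effect) in self.causal_mutations.items():
            if effect == 0 or not np.isfinite(effect):
                raise ValidationError(f"causal locus {locus!r} has zero effect")
            if kind not in ("flux", "imodulon"):
                raise ValidationError(f"causal locus {locus!r}: bad kind {kind!r}")

    def implied_negative_pairs(self) -> set[frozenset[str]]:
        """All iModulon pairs that are negatively coupled by construction.

        Besides the explicitly planted trade-off pairs, any positively and
        any negatively growth-coupled iModulon are themselves negatively
        correlated through their shared dependence on growth rate.
        """
        pairs = {frozenset((a, b)) for a, b, _ in self.tradeoff_pairs}
        pos = [k for k, s in self.growth_correlated_imodulons.items() if s > 0]
        neg = [k for k, s in self.growth_correlated_imodulons.items() if s < 0]
        pairs |= {frozenset((p, n)) for p in pos for n in neg}
        return pairs

    def to_json(self) -> dict:
        return {
            "convergent_phenotypes": sorted(self.convergent_phenotypes),
            "divergent_phenotypes": sorted(self.divergent_phenotypes),
            "neutral_phenotypes": sorted(self.neutral_phenotypes),
            "growth_correlated_imodulons": dict(
                sorted(self.growth_correlated_imodulons.items())
            ),
            "tradeoff_pairs": [list(t) for t in self.tradeoff_pairs],
            "wt_offset_imodulons": {
                s: dict(sorted(v.items()))
                for s, v in sorted(self.wt_offset_imodulons.items())
            },
            "causal_mutations": {
                k: list(v) for k, v in sorted(self.causal_mutations.items())
            },
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "PlantedTruth":
        return cls(
            convergent_phenotypes=list(obj["convergent_phenotypes"]),
            divergent_phenotypes=list(obj["divergent_phenotypes"]),
            neutral_phenotypes=list(obj["neutral_phenotypes"]),
            growth_correlated_imodulons={
                k: int(v) for k, v in obj["growth_correlated_imodulons"].items()
            },
            tradeoff_pairs=[
                (a, b, float(c)) for a, b, c in obj["tradeoff_pairs"]
            ],
            wt_offset_imodulons={
                s: {k: float(v) for k, v in d.items()}
                for s, d in obj["wt_offset_imodulons"].items()
            },
            causal_mutations={
                k: (v[0], v[1], float(v[2]))
                for k, v in obj["causal_mutations"].items()
            },
        )


@dataclass
class SimulationConfig:
    """Study conditions of the emulated six-strain ALE experiment."""

    strains: tuple[str, ...] = DEFAULT_STRAINS
    flasks_per_strain: tuple[int, ...] = (4, 4, 4, 4, 3, 3)  # 22 flasks
    replicates: int = 2
    n_genes: int = 1000
    n_imodulons: int = 24
    sparsity: float = 0.10
    expression_noise_sd: float = 0.10
    # replicate perturbation magnitude |d| ~ LogNormal(mu, sigma)
    replicate_mu: float = 0.0
    replicate_sigma: float = 0.5
    measurement_sd: float = 0.3  # independent per-sample activity noise
    flask_noise_sd: float = 0.5  # flask-level activity noise
    # constant per-iModulon activity level, shared by all samples; sets the
    # between-gene dynamic range of expression (replicate R^2 realism)
    # without touching any contrast, correlation or difference
    activity_level_sd: float = 15.0
    strain_baseline_sd: float = 1.5  # WT-state spread between strains
    growth_scale: float = 40.0  # activity units per 1/h around the pivot
    growth_pivot: float = 0.85
    tradeoff_amplitude: float = 5.0  # sd of the driving iModulon's flask values
    tradeoff_noise_sd: float = 0.3
    wt_offset: float = 15.0
    causal_effect: float = 10.0
    n_phenotypes: int = 62
    n_convergent: int = 10
    n_divergent: int = 2
    phenotype_wide_sd: float = 3.0
    phenotype_tight_sd: float = 0.15
    phenotype_neutral_sd: float = 1.0
    phenotype_noise_sd: float = 0.05
    # fraction of convergent phenotypes that also track growth rate, and
    # the strength/residual of that coupling
    phenotype_growth_fraction: float = 55 / 64
    phenotype_growth_beta: float = 15.0
    flux_noise_sd: float = 0.5
    background_rate: float = 1.0  # expected background loci placements scale

    def __post_init__(self) -> None:
        if len(self.flasks_per_strain) != len(self.strains):
            raise ValidationError("flasks_per_strain must match strains")
        if self.replicates < 2:
            raise ValidationError(
                "need >= 2 replicates to fit the replicate null"
            )
        if self.n_convergent + self.n_divergent > self.n_phenotypes:
            raise ValidationError("more planted labels than phenotypes")

    @property
    def imodulon_names(self) -> list[str]:
        return [f"IM{i + 1:02d}" for i in range(self.n_imodulons)]

    @property
    def categories(self) -> dict[str, str]:
        names = self.imodulon_names
        return {n: CATEGORIES[i % len(CATEGORIES)] for i, n in enumerate(names)}


def default_truth(config: SimulationConfig | None = None) -> PlantedTruth:
    """The default planted-signal layout for a simulation config.

    iModulons 1-3 are positively and 4-6 negatively growth-coupled; 7/8,
    9/10 and 11/12 form trade-off pairs; 13-16 carry strain-specific WT
    offsets; 13-20 are the targets of the eight activity-coupled causal
    loci; four flux-coupled loci target pentose-phosphate, malic-enzyme,
    TCA and Entner-Doudoroff reactions.
    """
    cfg = config or SimulationConfig()
    names = cfg.imodulon_names
    growth = {names[i]: +1 for i in range(3)} | {names[i]: -1 for i in range(3, 6)}
    tradeoffs = [
        (names[6], names[7], 1.0),
        (names[8], names[9], 0.8),
        (names[10], names[11], 1.2),
    ]
    wt_offsets = {
        cfg.strains[i % len(cfg.strains)]: {names[12 + i]: cfg.wt_offset}
        for i in range(4)
    }
    causal: dict[str, tuple[str, str, float]] = {}
    for i, (locus, rxn) in enumerate(CAUSAL_FLUX_LOCI.items()):
        causal[locus] = ("flux", rxn, cfg.causal_effect * (1 if i % 2 == 0 else -1))
    if len(names) < 24:
        raise ValidationError("default truth needs >= 24 iModulons")
    for i, locus in enumerate(CAUSAL_ACTIVITY_LOCI):
        causal[locus] = (
            "imodulon", names[16 + i], cfg.causal_effect * (1 if i % 2 == 0 else -1)
        )
    phen = [f"phen{i + 1:03d}" for i in range(cfg.n_phenotypes)]
    return PlantedTruth(
        convergent_phenotypes=phen[: cfg.n_convergent],
        divergent_phenotypes=phen[cfg.n_convergent: cfg.n_convergent + cfg.n_divergent],
        neutral_phenotypes=phen[cfg.n_convergent + cfg.n_divergent:],
        growth_correlated_imodulons=growth,
        tradeoff_pairs=tradeoffs,
        wt_offset_imodulons=wt_offsets,
        causal_mutations=causal,
    )


# ---------------------------------------------------------------------------
# stage generators


def generate_design(
    n_strains: int = 6,
    flasks_per_strain: Sequence[int] | None = None,
    replicates: int = 2,
    seed: int = 0,
    strains: Sequence[str] | None = None,
    plateau_range: tuple[float, float] = (0.98, 1.11),
    wt_range: tuple[float, float] = (0.55, 0.90),
) -> list[SampleMeta]:
    """Sample design: strains x assayed flasks x biological replicates.

    Growth rates rise monotonically from a strain-specific wild-type value
    to a plateau drawn from ``plateau_range``; stages are labelled WT for
    flask 0, EP for the last assayed flask, intermediate otherwise.
    """
    if n_strains < 2:
        raise ValidationError("need >= 2 strains")
    if replicates < 2:
        raise ValidationError("need >= 2 replicates (replicate null unfittable)")
    rng = np.random.default_rng(seed)
    names = list(strains) if strains else [
        DEFAULT_STRAINS[i] if i < len(DEFAULT_STRAINS) else f"S{i + 1}"
        for i in range(n_strains)
    ]
    if flasks_per_strain is None:
        flasks_per_strain = [4 if i < 4 else 3 for i in range(n_strains)]
    samples: list[SampleMeta] = []
    for s_idx, (strain, k) in enumerate(zip(names, flasks_per_strain)):
        wt = float(rng.uniform(*wt_range))
        plateau = float(rng.uniform(*plateau_range))
        incs = rng.uniform(0.5, 1.5, size=k - 1)
        fracs = np.concatenate([[0.0], np.cumsum(incs) / incs.sum()])
        rates = wt + (plateau - wt) * fracs
        gaps = rng.integers(3, 9, size=k - 1)
        flasks = np.concatenate([[0], np.cumsum(gaps)])
        for i, (flask, rate) in enumerate(zip(flasks, rates)):
            stage = "WT" if i == 0 else ("EP" if i == k - 1 else "intermediate")
            for r in range(1, replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{strain}_f{flask}_r{r}",
                        strain=strain,
                        flask_index=int(flask),
                        replicate_id=f"r{r}",
                        stage=stage,
                        growth_rate=float(rate),
                    )
                )
    return samples


def generate_imodulon_model(
    n_genes: int = 1000,
    n_imodulons: int = 24,
    sparsity: float = 0.10,
    seed: int = 0,
    names: Sequence[str] | None = None,
    categories: Mapping[str, str] | None = None,
) -> IModulonModel:
    """Sparse, near-orthogonal random gene-weight basis with full column rank.

    Each column has a random support of round(sparsity * n_genes) genes
    with unit-normalised Gaussian weights. A rank-deficient draw is
    redrawn with an incremented sub-seed (logged).
    """
    if n_genes <= n_imodulons:
        raise ValidationError("need n_genes > n_imodulons")
    if not (0 < sparsity <= 1):
        raise ValidationError("sparsity must lie in (0, 1]")
    names = list(names) if names else [f"IM{i + 1:02d}" for i in range(n_imodulons)]
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    support = max(1, round(sparsity * n_genes))
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        w = np.zeros((n_genes, n_imodulons))
        for j in range(n_imodulons):
            idx = rng.choice(n_genes, size=support, replace=False)
            vals = rng.normal(size=support)
            w[idx, j] = vals / np.linalg.norm(vals)
        if np.linalg.matrix_rank(w) == n_imodulons:
            if attempt:
                log.info("generate_imodulon_model: redrew %d time(s)", attempt)
            return IModulonModel(
                pd.DataFrame(w, index=genes, columns=names),
                dict(categories or {}),
            )
    raise ValidationError("could not draw a full-rank basis in 10 attempts")


def _flask_grid(design: Sequence[SampleMeta]) -> list[tuple[str, int, str, float]]:
    """(strain, flask, stage, growth) per assayed flask, strains in design order."""
    seen: dict[tuple[str, int], tuple[str, float]] = {}
    order: list[tuple[str, int]] = []
    for m in design:
        key = (m.strain, m.flask_index)
        if key not in seen:
            seen[key] = (m.stage, m.growth_rate)
            order.append(key)
    return [(s, f, seen[(s, f)][0], seen[(s, f)][1]) for s, f in order]


def generate_activities(
    design: Sequence[SampleMeta],
    truth: PlantedTruth,
    replicate_noise: tuple[float, float] = (0.0, 0.5),
    seed: int = 0,
    config: SimulationConfig | None = None,
    mutation_jumps: Mapping[str, Sequence[tuple[str, int]]] | None = None,
) -> ActivityMatrix:
    """Per-sample iModulon activities realising every planted signal.

    Flask-level values are built per signal class (growth-coupled,
    trade-off, WT offset, causal shift, background drift); each biological
    replicate then receives the flask value plus a symmetric perturbation
    of +/- d/2 with |d| log-normal, plus small independent measurement
    noise. ``mutation_jumps`` maps causal loci to the (strain, to_flask)
    jumps where they are gained; activity-targeting effects persist from
    the gaining flask onward.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    names = cfg.imodulon_names
    name_set = set(names)
    for k in truth.growth_correlated_imodulons:
        if k not in name_set:
            raise ValidationError(f"unknown iModulon in truth: {k!r}")
    for a, b, _ in truth.tradeoff_pairs:
        if a not in name_set or b not in name_set:
            raise ValidationError(f"unknown trade-off iModulon: ({a}, {b})")
    grid = _flask_grid(design)
    strains = sorted({s for s, *_ in grid})
    # constant per-iModulon levels (shared by every sample) plus
    # strain-specific baselines
    level = {im: float(rng.normal(0, cfg.activity_level_sd)) for im in names}
    base = {
        (im, s): level[im] + float(rng.normal(0, cfg.strain_baseline_sd))
        for im in names
        for s in strains
    }
    flask_vals: dict[tuple[str, str, int], float] = {}
    tradeoff_drive = {a: (b, c) for a, b, c in truth.tradeoff_pairs}
    tradeoff_driven = {b for _, b, _ in truth.tradeoff_pairs}
    for im in names:
        sign = truth.growth_correlated_imodulons.get(im)
        for s, f, stage, g in grid:
            if im in tradeoff_driven:
                continue  # filled from its driver below
            v = base[(im, s)]
            if sign is not None:
                v += sign * cfg.growth_scale * (g - cfg.growth_pivot)
            elif im in tradeoff_drive:
                v += float(rng.normal(0, cfg.tradeoff_amplitude))
            else:
                v += float(rng.normal(0, cfg.flask_noise_sd))
            offs = truth.wt_offset_imodulons.get(s, {})
            if stage == "WT" and im in offs:
                v += offs[im]
            flask_vals[(im, s, f)] = v
    for a, (b, c) in tradeoff_drive.items():
        for s, f, stage, g in grid:
            v = -c * flask_vals[(a, s, f)] + base[(b, s)] * 0.5
            v += float(rng.normal(0, cfg.tradeoff_noise_sd))
            offs = truth.wt_offset_imodulons.get(s, {})
            if stage == "WT" and b in offs:
                v += offs[b]
            flask_vals[(b, s, f)] = v
    # persistent causal shifts gained at jumps
    if mutation_jumps:
        for locus, placements in mutation_jumps.items():
            kind, target, effect = truth.causal_mutations.get(
                locus, (None, None, 0.0)
            )
            if kind != "imodulon":
                continue
            for strain, to_flask in placements:
                for s, f, _, _ in grid:
                    if s == strain and f >= to_flask:
                        flask_vals[(target, s, f)] += effect
    # sample-level: symmetric replicate split + measurement noise
    mu, sigma = replicate_noise
    data: dict[str, np.ndarray] = {}
    by_flask: dict[tuple[str, int], list[SampleMeta]] = {}
    for m in design:
        by_flask.setdefault((m.strain, m.flask_index), []).append(m)
    for (s, f), members in by_flask.items():
        members = sorted(members, key=lambda m: m.replicate_id)
        d = rng.lognormal(mu, sigma, size=len(names))
        split_sign = rng.choice([-1.0, 1.0], size=len(names))
        for i, m in enumerate(members):
            side = split_sign if i % 2 == 0 else -split_sign
            eps = rng.normal(0, cfg.measurement_sd, size=len(names))
            vals = np.array([flask_vals[(im, s, f)] for im in names])
            data[m.sample_id] = vals + side * d / 2.0 + eps
    columns = [m.sample_id for m in design]
    return ActivityMatrix(
        pd.DataFrame({c: data[c] for c in columns}, index=names)
    )


def generate_expression(
    m: IModulonModel,
    a: ActivityMatrix,
    noise_sd: float = 0.10,
    seed: int = 0,
) -> tuple[ExpressionMatrix, float]:
    """Expression X = M.A + iid Gaussian noise, shifted to be non-negative.

    Non-negativity (log-TPM is >= 0) is achieved by a single global
    additive shift equal to the most negative entry; the shift is returned
    so callers can undo it. The same constant on every gene adds the same
    offset to every projected sample, leaving differences, correlations
    and strain contrasts untouched.
    """
    rng = np.random.default_rng(seed)
    x = m.weights.to_numpy() @ a.data.loc[m.imodulon_names].to_numpy()
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, size=x.shape)
    shift = float(max(0.0, -x.min()))
    if shift:
        x = x + shift
    x = np.clip(x, 0.0, None)  # guard against -0.0 / roundoff
    return (
        ExpressionMatrix(
            pd.DataFrame(x, index=m.gene_ids, columns=a.sample_ids)
        ),
        shift,
    )


def generate_phenotypes(
    design: Sequence[SampleMeta],
    n_phenotypes: int,
    truth: PlantedTruth,
    noise_sd: float = 0.05,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> PhenotypeTable:
    """Phenotype panel with planted convergent/divergent/neutral trajectories.

    Convergent phenotypes have widely dispersed per-strain WT means and
    tightly clustered EP means; divergent phenotypes the reverse; neutral
    phenotypes equal dispersion at both stages. A configured fraction of
    the convergent phenotypes additionally tracks the flask growth rate
    (value ~ beta * growth + residual), mirroring the observation that
    most convergent phenotypes are growth-correlated: the strain-specific
    wild-type growth rates then supply the wide WT dispersion while the
    shared plateau supplies the tight EP clustering.
    """
    cfg = config or SimulationConfig()
    labelled = (
        len(truth.convergent_phenotypes)
        + len(truth.divergent_phenotypes)
        + len(truth.neutral_phenotypes)
    )
    if n_phenotypes < labelled:
        raise ValidationError(
            f"n_phenotypes ({n_phenotypes}) < planted labels ({labelled})"
        )
    rng = np.random.default_rng(seed)
    strains = sorted({m.strain for m in design})
    growth: dict[tuple[str, str], float] = {}
    for m in design:
        growth[(m.strain, m.stage)] = m.growth_rate
    units = ["abs", "rel", "phys"]
    rows = []
    n_coupled = round(cfg.phenotype_growth_fraction * len(truth.convergent_phenotypes))
    coupled = set(truth.convergent_phenotypes[:n_coupled])
    all_ids = (
        list(truth.convergent_phenotypes)
        + list(truth.divergent_phenotypes)
        + list(truth.neutral_phenotypes)
    )
    for i, pid in enumerate(all_ids):
        mu = float(rng.normal(0, 5))
        beta = 0.0
        if pid in coupled:
            beta = cfg.phenotype_growth_beta * float(rng.choice([-1.0, 1.0]))
            wt_sd, ep_sd = cfg.phenotype_wide_sd, cfg.phenotype_tight_sd
        elif pid in truth.convergent_phenotypes:
            wt_sd, ep_sd = cfg.phenotype_wide_sd, cfg.phenotype_tight_sd
        elif pid in truth.divergent_phenotypes:
            wt_sd, ep_sd = cfg.phenotype_tight_sd, cfg.phenotype_wide_sd
        else:
            wt_sd = ep_sd = cfg.phenotype_neutral_sd
        for stage, sd in (("WT", wt_sd), ("EP", ep_sd)):
            for s in strains:
                g = growth.get((s, stage), float("nan"))
                trend = beta * (g - 0.85) if beta and np.isfinite(g) else 0.0
                value = (
                    mu + trend
                    + float(rng.normal(0, sd))
                    + float(rng.normal(0, noise_sd))
                )
                rows.append(
                    {
                        "phenotype_id": pid,
                        "unit": units[i % 3],
                        "strain": s,
                        "stage": stage,
                        "value": value,
                        "stdev": noise_sd,
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


def generate_mutations(
    design: Sequence[SampleMeta],
    truth: PlantedTruth,
    background_rate: float = 1.0,
    seed: int = 0,
) -> tuple[list[MutationEvent], dict[str, list[tuple[str, int]]]]:
    """Mutation events gained at jumps, causal loci first.

    Each causal locus is gained in two or three randomly chosen jumps
    (possibly in different strains) so that its binary jump feature is
    testable; background loci are placed uniformly at random jumps, two
    placements each, scaled by ``background_rate``. Returns the events and
    the placement map locus -> [(strain, to_flask), ...] used to couple
    the targeted flux or activity.
    """
    rng = np.random.default_rng(seed)
    grid = _flask_grid(design)
    by_strain: dict[str, list[int]] = {}
    for s, f, _, _ in grid:
        by_strain.setdefault(s, []).append(f)
    jumps = [
        (s, sorted(flasks)[i + 1])
        for s, flasks in sorted(by_strain.items())
        for i in range(len(flasks) - 1)
    ]
    types = ("SNP", "indel", "mobile_element", "large_deletion")
    events: list[MutationEvent] = []
    placements: dict[str, list[tuple[str, int]]] = {}

    def place(locus: str, n: int) -> None:
        idx = rng.choice(len(jumps), size=min(n, len(jumps)), replace=False)
        placements[locus] = [jumps[i] for i in sorted(idx)]
        for strain, to_flask in placements[locus]:
            events.append(
                MutationEvent(
                    strain=strain,
                    replicate_id="r1",
                    locus=locus,
                    nucleotide_id=f"{locus}:{int(rng.integers(1, 2000))}",
                    mutation_type=types[int(rng.integers(len(types)))],
                    observed_flask=to_flask,
                )
            )

    for locus in truth.causal_mutations:
        place(locus, int(rng.integers(2, 4)))
    n_background = max(0, round(background_rate * len(BACKGROUND_LOCI)))
    for locus in BACKGROUND_LOCI[:n_background]:
        place(locus, 2)
    return events, placements


def generate_fluxes(
    design: Sequence[SampleMeta],
    truth: PlantedTruth,
    placements: Mapping[str, Sequence[tuple[str, int]]],
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> list[FluxRecord]:
    """Per (reaction, strain, flask) flux estimates with 95% CIs.

    Baselines are reaction- and strain-specific; flux-targeting causal
    mutations shift the targeted reaction from the gaining flask onward.
    Forward/backward components and CI bounds are constructed to satisfy
    the net/exchange identities and CI coverage exactly.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    grid = _flask_grid(design)
    strains = sorted({s for s, *_ in grid})
    base = {
        (r, s): float(rng.uniform(2, 10)) for r in FLUX_REACTIONS for s in strains
    }
    shifts: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for locus, placed in placements.items():
        kind, target, effect = truth.causal_mutations.get(locus, (None, None, 0.0))
        if kind != "flux":
            continue
        for strain, to_flask in placed:
            shifts.setdefault((target, strain), []).append((to_flask, effect))
    records = []
    for rxn in FLUX_REACTIONS:
        for s, f, _, _ in grid:
            v = base[(rxn, s)] + float(rng.normal(0, cfg.flux_noise_sd))
            for to_flask, effect in shifts.get((rxn, s), []):
                if f >= to_flask:
                    v += effect
            exch = abs(float(rng.normal(0, 0.5)))
            vb = exch + max(0.0, -v)
            vf = v + vb
            se = abs(float(rng.normal(0.3, 0.05))) + 1e-3
            records.append(
                FluxRecord(
                    reaction_id=rxn,
                    strain=s,
                    flask_index=f,
                    v_forward=vf,
                    v_backward=vb,
                    ci_lower=v - 2 * se,
                    ci_upper=v + 2 * se,
                    unit="abs",
                )
            )
    return records


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """One complete synthetic multi-omics dataset plus its planted truth."""

    config: SimulationConfig
    meta: list[SampleMeta]
    model: IModulonModel
    activities: ActivityMatrix
    expression: ExpressionMatrix
    expression_shift: float
    phenotypes: PhenotypeTable
    fluxes: list[FluxRecord]
    mutations: list[MutationEvent]
    truth: PlantedTruth

    @property
    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for m in self.meta:
            groups.setdefault(f"{m.strain}:{m.flask_index}", []).append(m.sample_id)
        return groups


def generate_dataset(
    seed: int = 0, config: SimulationConfig | None = None
) -> SyntheticDataset:
    """Generate the full six-strain dataset; fully determined by one seed."""
    cfg = config or SimulationConfig()
    root = np.random.default_rng(seed)
    sub = root.integers(0, 2**31 - 1, size=6)
    design = generate_design(
        n_strains=len(cfg.strains),
        flasks_per_strain=cfg.flasks_per_strain,
        replicates=cfg.replicates,
        strains=cfg.strains,
        seed=int(sub[0]),
    )
    truth = default_truth(cfg)
    model = generate_imodulon_model(
        cfg.n_genes, cfg.n_imodulons, cfg.sparsity, seed=int(sub[1]),
        names=cfg.imodulon_names, categories=cfg.categories,
    )
    mutations, placements = generate_mutations(
        design, truth, background_rate=cfg.background_rate, seed=int(sub[2])
    )
    activities = generate_activities(
        design, truth,
        replicate_noise=(cfg.replicate_mu, cfg.replicate_sigma),
        seed=int(sub[3]), config=cfg, mutation_jumps=placements,
    )
    expression, shift = generate_expression(
        model, activities, noise_sd=cfg.expression_noise_sd, seed=int(sub[4])
    )
    phenotypes = generate_phenotypes(
        design, cfg.n_phenotypes, truth, noise_sd=cfg.phenotype_noise_sd,
        seed=int(sub[5]), config=cfg,
    )
    fluxes = generate_fluxes(design, truth, placements, seed=int(sub[5]), config=cfg)
    return SyntheticDataset(
        config=cfg,
        meta=design,
        model=model,
        activities=activities,
        expression=expression,
        expression_shift=shift,
        phenotypes=phenotypes,
        fluxes=fluxes,
        mutations=mutations,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> None:
    """Write every table in the standard CSV schemas plus truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    aio.write_metadata(ds.meta, d / "metadata.csv")
    aio.write_expression(ds.expression, d / "expression.csv")
    aio.write_imodulon_model(ds.model, d / "imodulon_model.csv")
    aio.write_activities(ds.activities, d / "activities.csv")
    aio.write_phenotypes(ds.phenotypes, d / "phenotypes.csv")
    aio.write_fluxes(ds.fluxes, d / "fluxes.csv")
    aio.write_mutations(ds.mutations, d / "mutations.csv")
    with open(d / "truth.json", "w") as fh:
        json.dump(ds.truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(d / "categories.json", "w") as fh:
        json.dump(ds.config.categories, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth(directory: str | Path) -> PlantedTruth:
    with open(Path(directory) / "truth.json") as fh:
        return PlantedTruth.from_json(json.load(fh))
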