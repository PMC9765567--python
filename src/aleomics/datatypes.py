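"""Core domain types for multi-strain ALE multi-omics data.

The central objects mirror the supplementary-data layouts of a six-strain
adaptive-laboratory-evolution (ALE) study: a gene-expression matrix in
log2(TPM+1), a fixed iModulon gene-weight basis M (genes x iModulons), the
projected activity matrix A (iModulons x samples), a phenotype panel of
per-strain per-stage means, flux records with 95% confidence intervals, and
gene- or nucleotide-level mutation events.

"Flask" counts evolutionary time within a strain's trajectory (flask 0 is
the preculture); "WT" and "EP" denote the wild-type starting flask and the
evolved endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("WT", "intermediate", "EP")

MUTATION_TYPES = ("SNP", "indel", "mobile_element", "large_deletion")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq (or physiology) sample.

    ``flask_index`` is the position along the strain's evolutionary
    trajectory; within a strain the assayed flask indices form a totally
    ordered chain. ``growth_rate`` is in 1/h and may be NaN when not
    measured.
    """

    sample_id: str
    strain: str
    flask_index: int
    replicate_id: str
    stage: str
    growth_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(
                f"stage {self.stage!r} for sample {self.sample_id!r} "
                f"not in {STAGES}"
            )
        if self.flask_index < 0:
            raise ValidationError(
                f"flask_index must be >= 0, got {self.flask_index}"
            )
        if not math.isnan(self.growth_rate) and self.growth_rate <= 0:
            raise ValidationError(
                f"growth_rate must be > 0 when present, got {self.growth_rate}"
            )


def validate_metadata(samples: Sequence[SampleMeta]) -> None:
    """Check uniqueness invariants across a metadata table."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id(s): {dups}")
    keys = [(s.strain, s.flask_index, s.replicate_id) for s in samples]
    if len(set(keys)) != len(keys):
        dups = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(
            f"duplicate (strain, flask_index, replicate_id): {dups}"
        )


def _check_matrix(df: pd.DataFrame, what: str, nonneg: bool = False) -> None:
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate {what} row ids: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValidationError(f"duplicate {what} column ids: {dups}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError(f"{what} contains non-finite values")
    if nonneg and (values < 0).any():
        raise ValidationError(f"{what} contains negative values")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(TPM+1) expression values."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        _check_matrix(self.data, "expression", nonneg=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class IModulonModel:
    """Fixed iModulon basis: genes x iModulons gene-weight matrix M.

    Each column is an independently modulated gene set obtained by ICA of a
    reference transcriptome compendium; ``category`` optionally maps each
    iModulon to a functional-category label (stress response, translation,
    carbon metabolism, ...).
    """

    weights: pd.DataFrame  # index: gene ids, columns: iModulon names
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_matrix(self.weights, "iModulon weights")
        col_nonzero = (self.weights.to_numpy() != 0).any(axis=0)
        if not col_nonzero.all():
            empty = [
                name
                for name, nz in zip(self.weights.columns, col_nonzero)
                if not nz
            ]
            raise ValidationError(f"all-zero iModulon column(s): {empty}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def imodulon_names(self) -> list[str]:
        return list(self.weights.columns)

    def category_of(self, imodulon: str) -> str:
        return self.category.get(imodulon, "unknown")


@dataclass
class ActivityMatrix:
    """iModulons x samples matrix of activities A (or jump differences)."""

    data: pd.DataFrame  # index: iModulon names, columns: sample ids

    def __post_init__(self) -> None:
        _check_matrix(self.data, "activity")

    @property
    def imodulon_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class PhenotypeTable:
    """Long-form phenotype panel: one mean value per (phenotype, strain, stage).

    ``unit`` distinguishes absolute flux (mmol/gDW/h, "abs"), relative flux
    (mol/mol glucose, "rel"), and physiological measurements ("phys").
    ``stdev`` is optional (NaN when absent).
    """

    data: pd.DataFrame  # columns: phenotype_id, unit, strain, stage, value, stdev

    REQUIRED = ("phenotype_id", "unit", "strain", "stage", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table missing column(s): {missing}")
        if "stdev" not in self.data.columns:
            self.data = self.data.assign(stdev=float("nan"))
        key = self.data[["phenotype_id", "strain", "stage"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(
                f"duplicate (phenotype, strain, stage) rows: {dups[:5]}"
            )
        if not np.isfinite(self.data["value"].to_numpy(dtype=float)).all():
            raise ValidationError("phenotype values must be finite")
        bad = set(self.data["stage"]) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage label(s): {sorted(bad)}")

    @property
    def phenotype_ids(self) -> list[str]:
        return list(pd.unique(self.data["phenotype_id"]))

    def stage_means(self, phenotype_id: str, stage: str) -> pd.Series:
        """Per-strain mean values of one phenotype at one stage."""
        sub = self.data[
            (self.data["phenotype_id"] == phenotype_id)
            & (self.data["stage"] == stage)
        ]
        return pd.Series(
            sub["value"].to_numpy(dtype=float), index=list(sub["strain"])
        )


_FLUX_TOL = 1e-6


@dataclass
class FluxRecord:
    """One estimated reaction flux with 95% confidence bounds.

    Reversible reactions are modelled as separate forward and backward
    fluxes; the net flux is v_net = v_f - v_b and the exchange flux is
    v_exch = min(v_f, v_b). Flux precision (stdev) is a quarter of the 95%
    confidence-interval width.
    """

    reaction_id: str
    strain: str
    flask_index: int
    v_forward: float
    v_backward: float
    unit: str = "abs"
    v_net: float = field(default=float("nan"))
    v_exchange: float = field(default=float("nan"))
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")

    def __post_init__(self) -> None:
        if self.v_forward < 0 or self.v_backward < 0:
            raise ValidationError(
                f"{self.reaction_id}: v_forward/v_backward must be >= 0"
            )
        net = self.v_forward - self.v_backward
        exch = min(self.v_forward, self.v_backward)
        if math.isnan(self.v_net):
            self.v_net = net
        if math.isnan(self.v_exchange):
            self.v_exchange = exch
        if abs(self.v_net - net) > _FLUX_TOL or abs(self.v_exchange - exch) > _FLUX_TOL:
            import warnings

            warnings.warn(
                f"{self.reaction_id}: stored net/exchange fluxes violate "
                f"v_net=v_f-v_b / v_exch=min(v_f,v_b); recomputed",
                stacklevel=2,
            )
            self.v_net = net
            self.v_exchange = exch
        if self.has_ci and not (
            self.ci_lower - _FLUX_TOL <= self.v_net <= self.ci_upper + _FLUX_TOL
        ):
            raise ValidationError(
                f"{self.reaction_id}: v_net {self.v_net} outside 95% CI "
                f"[{self.ci_lower}, {self.ci_upper}]"
            )

    @property
    def has_ci(self) -> bool:
        return not (math.isnan(self.ci_lower) or math.isnan(self.ci_upper))

    @property
    def precision_stdev(self) -> float:
        """Flux precision: (95% upper bound - 95% lower bound) / 4."""
        if not self.has_ci:
            return float("nan")
        return (self.ci_upper - self.ci_lower) / 4.0


@dataclass(frozen=True)
class MutationEvent:
    """One selected mutation observed along an ALE lineage.

    ``locus`` is a gene symbol, or for intergenic events the flanking gene
    pair rendered "geneA/geneB". ``observed_flask`` is the first flask at
    which the mutation was observed.
    """

    strain: str
    replicate_id: str
    locus: str
    mutation_type: str
    observed_flask: int
    nucleotide_id: str | None = None

    def __post_init__(self) -> None:
        if not self.locus:
            raise ValidationError("mutation locus must be non-empty")
        if self.locus.count("/") > 1:
            raise ValidationError(
                f"intergenic locus must contain exactly one '/': {self.locus!r}"
            )
        if self.mutation_type not in MUTATION_TYPES:
            raise ValidationError(
                f"mutation_type {self.mutation_type!r} not in {MUTATION_TYPES}"
            )

    @property
    def is_intergenic(self) -> bool:
        return "/" in self.locus

    @property
    def gene_pair(self) -> tuple[str, str] | None:
        if not self.is_intergenic:
            return None
        a, b = self.locus.split("/")
        return a, b


@dataclass
class TestResult:
    """Generic per-target hypothesis-test result with BH-adjusted q."""

    target_id: str
    statistic: float
    p: float
    q: float
    label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("q", self.q)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


def metadata_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabulate SampleMeta records (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "strain": s.strain,
                "flask_index": s.flask_index,
                "replicate_id": s.replicate_id,
                "stage": s.stage,
                "growth_rate": s.growth_rate,
            }
            for s in samples
        ]
    )


def assayed_flasks(samples: Sequence[SampleMeta]) -> dict[str, list[int]]:
    """Sorted assayed flask indices per strain."""
    out: dict[str, list[int]] = {}
    for s in samples:
        out.setdefault(s.strain, [])
        if s.flask_index not in out[s.strain]:
            out[s.strain].append(s.flask_index)
    return {k: sorted(v) for k, v in out.items()}
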