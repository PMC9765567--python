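"""Delimited-text readers/writers and quality-control filters.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal separator. Gene and sample identifiers are opaque, case-sensitive
strings. Empty cells are missing values; no operation imputes silently.

Schemas
-------
expression : gene_id + one column per sample_id (log2(TPM+1))
metadata   : sample_id, strain, flask_index, replicate_id, stage, growth_rate
mutations  : strain, replicate_id, locus, nucleotide_id, mutation_type,
             observed_flask
fluxes     : reaction_id, strain, flask_index, v_forward, v_backward, v_net,
             v_exchange, ci_lower, ci_upper, unit (abs|rel)
phenotypes : phenotype_id, unit, strain, stage, value, stdev
imodulons  : gene_id + one column per iModulon name (gene weights)
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ActivityMatrix,
    ExpressionMatrix,
    FluxRecord,
    IModulonModel,
    MutationEvent,
    PhenotypeTable,
    SampleMeta,
    ValidationError,
    metadata_frame,
    validate_metadata,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def _read_csv(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric_matrix(df: pd.DataFrame, path: str | Path, id_col: str) -> pd.DataFrame:
    """Parse all non-id columns as floats, reporting the offending cell."""
    ids = df[id_col]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate {id_col}(s): {dups}")
    out = df.set_index(id_col)
    for col in out.columns:
        try:
            out[col] = out[col].astype(float)
        except (TypeError, ValueError):
            bad = out[col][pd.to_numeric(out[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ValidationError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            ) from None
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = None
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2(TPM+1) matrix (gene_id first column)."""
    df = _read_csv(path, required=["gene_id"])
    return ExpressionMatrix(_numeric_matrix(df, path, "gene_id"))


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    x.data.to_csv(path, index_label="gene_id", float_format=FLOAT_FORMAT)


def read_imodulon_model(
    path: str | Path, categories: Mapping[str, str] | None = None
) -> IModulonModel:
    """Read the iModulon gene-weight matrix M (gene_id first column)."""
    df = _read_csv(path, required=["gene_id"])
    return IModulonModel(_numeric_matrix(df, path, "gene_id"), dict(categories or {}))


def write_imodulon_model(m: IModulonModel, path: str | Path) -> None:
    m.weights.to_csv(path, index_label="gene_id", float_format=FLOAT_FORMAT)


def read_activities(path: str | Path) -> ActivityMatrix:
    df = _read_csv(path, required=["imodulon"])
    return ActivityMatrix(_numeric_matrix(df, path, "imodulon"))


def write_activities(a: ActivityMatrix, path: str | Path) -> None:
    a.data.to_csv(path, index_label="imodulon", float_format=FLOAT_FORMAT)


_META_COLS = ["sample_id", "strain", "flask_index", "replicate_id", "stage", "growth_rate"]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = _read_csv(path, required=_META_COLS)
    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            strain=str(r.strain),
            flask_index=int(r.flask_index),
            replicate_id=str(r.replicate_id),
            stage=str(r.stage),
            growth_rate=(
                float(r.growth_rate)
                if isinstance(r.growth_rate, str) and r.growth_rate != ""
                else float("nan")
            ),
        )
        for r in df.itertuples()
    ]
    validate_metadata(samples)
    return samples


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    metadata_frame(samples).to_csv(path, index=False, float_format=FLOAT_FORMAT)


_MUT_COLS = ["strain", "replicate_id", "locus", "nucleotide_id", "mutation_type", "observed_flask"]


def read_mutations(path: str | Path) -> list[MutationEvent]:
    df = _read_csv(path, required=_MUT_COLS)
    return [
        MutationEvent(
            strain=str(r.strain),
            replicate_id=str(r.replicate_id),
            locus=str(r.locus),
            nucleotide_id=(
                str(r.nucleotide_id)
                if isinstance(r.nucleotide_id, str) and r.nucleotide_id != ""
                else None
            ),
            mutation_type=str(r.mutation_type),
            observed_flask=int(r.observed_flask),
        )
        for r in df.itertuples()
    ]


def write_mutations(events: Sequence[MutationEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "strain": e.strain,
                "replicate_id": e.replicate_id,
                "locus": e.locus,
                "nucleotide_id": e.nucleotide_id or "",
                "mutation_type": e.mutation_type,
                "observed_flask": e.observed_flask,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


_FLUX_COLS = [
    "reaction_id", "strain", "flask_index", "v_forward", "v_backward",
    "v_net", "v_exchange", "ci_lower", "ci_upper", "unit",
]


def read_fluxes(path: str | Path) -> list[FluxRecord]:
    """Read flux records; net/exchange identities are re-checked on load."""
    df = _read_csv(path, required=_FLUX_COLS)

    def _f(v: object) -> float:
        return float(v) if isinstance(v, str) and v != "" else float("nan")

    return [
        FluxRecord(
            reaction_id=str(r.reaction_id),
            strain=str(r.strain),
            flask_index=int(r.flask_index),
            v_forward=_f(r.v_forward),
            v_backward=_f(r.v_backward),
            v_net=_f(r.v_net),
            v_exchange=_f(r.v_exchange),
            ci_lower=_f(r.ci_lower),
            ci_upper=_f(r.ci_upper),
            unit=str(r.unit),
        )
        for r in df.itertuples()
    ]


def write_fluxes(records: Sequence[FluxRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "reaction_id": f.reaction_id,
                "strain": f.strain,
                "flask_index": f.flask_index,
                "v_forward": f.v_forward,
                "v_backward": f.v_backward,
                "v_net": f.v_net,
                "v_exchange": f.v_exchange,
                "ci_lower": f.ci_lower,
                "ci_upper": f.ci_upper,
                "unit": f.unit,
            }
            for f in records
        ]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_csv(path, required=list(PhenotypeTable.REQUIRED))
    df = df.assign(
        value=df["value"].astype(float),
        stdev=(
            df["stdev"].astype(float)
            if "stdev" in df.columns
            else float("nan")
        ),
    )
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# QC filters


def filter_genes(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float] | pd.Series,
    min_length: float = 100.0,
    min_fpm: float = 10.0,
) -> list[str]:
    """Compendium QC: drop short genes and genes weakly detected anywhere.

    A gene is kept iff its length is >= ``min_length`` nucleotides AND its
    fragments-per-million (FPM) is >= ``min_fpm`` in every sample. FPM is
    computed per sample over the mapped fragments present in ``counts``:
    count / (sample total / 1e6).
    """
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = sorted(lengths.index[lengths.isna()])
        raise ValidationError(f"missing gene length(s): {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    c = counts.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValidationError("fragment counts must be >= 0")
    totals = c.sum(axis=0)
    zero = [col for col, t in zip(counts.columns, totals) if t == 0]
    if zero:
        raise ValidationError(f"all-zero sample(s), FPM undefined: {zero}")
    fpm = c / (totals / 1e6)
    keep = (lengths.to_numpy() >= min_length) & (fpm >= min_fpm).all(axis=1)
    kept = [g for g, k in zip(counts.index, keep) if k]
    log.info("filter_genes: kept %d / %d genes", len(kept), len(counts.index))
    return kept


def replicate_qc(
    x: ExpressionMatrix,
    replicate_groups: Mapping[str, Sequence[str]],
    r2_min: float = 0.9,
) -> list[str]:
    """Remove discordant biological replicates by pairwise log-TPM R^2.

    Within each replicate group, every sample pair with squared Pearson
    correlation below ``r2_min`` is flagged. In groups of two, both members
    of a failing pair are removed (no arbiter exists). In groups of three or
    more, the sample with the lowest mean pairwise R^2 is removed repeatedly
    until all remaining pairs pass.

    Returns the kept sample ids (original column order).
    """
    removed: set[str] = set()
    for group, members in replicate_groups.items():
        members = list(members)
        if len(members) < 2:
            raise ValidationError(
                f"replicate group {group!r} has fewer than 2 samples"
            )
        for m in members:
            if m not in x.data.columns:
                raise ValidationError(f"sample {m!r} not in expression matrix")
            if np.std(x.data[m].to_numpy(dtype=float)) == 0:
                raise ValidationError(
                    f"sample {m!r} has constant expression; R^2 undefined"
                )

        def r2(a: str, b: str) -> float:
            r = np.corrcoef(x.data[a], x.data[b])[0, 1]
            return float(r * r)

        current = list(members)
        while True:
            failing = [
                (a, b) for a, b in combinations(current, 2) if r2(a, b) < r2_min
            ]
            if not failing:
                break
            if len(current) == 2:
                removed.update(current)
                log.info("replicate_qc: group %s removed entirely", group)
                break
            mean_r2 = {
                m: float(
                    np.mean([r2(m, o) for o in current if o != m])
                )
                for m in current
            }
            worst = min(sorted(mean_r2), key=lambda m: mean_r2[m])
            current.remove(worst)
            removed.add(worst)
            log.info("replicate_qc: removed %s from group %s", worst, group)
    return [s for s in x.data.columns if s not in removed]


# ---------------------------------------------------------------------------
# small transforms


def log_tpm_transform(tpm: np.ndarray | float) -> np.ndarray | float:
    """log2(TPM + 1); 0 maps to 0 and the transform is monotone."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValidationError("TPM values must be >= 0")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(tpm) or out.ndim == 0 else out


def od_to_gdw(od600: np.ndarray | float) -> np.ndarray | float:
    """Convert optical density to dry-weight concentration: 0.32 gDW/L per OD600."""
    arr = np.asarray(od600, dtype=float)
    if (arr < 0).any():
        raise ValidationError("OD600 must be >= 0")
    out = 0.32 * arr
    return float(out) if np.isscalar(od600) or out.ndim == 0 else out
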