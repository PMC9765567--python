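"""End-to-end orchestration of the ALE multi-omics analysis.

Stage order follows the analysis workflow: simulate (or load) -> replicate
QC -> activity projection -> phenotype convergence and growth screens ->
replicate-null fitting and differential activation -> WT-discriminating
and growth-correlated iModulon screens -> jump differencing -> trade-off
detection -> mutation-correlate screening -> summary report. Every stage
logs input shapes, dropped-record counts and the thresholds used; the
report is written both as human-readable text and as structured JSON, and
is byte-identical across reruns with a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as aio
from .activity import (
    dima_screen,
    explained_variance,
    fit_replicate_null,
    growth_correlated_imodulons,
    project_activities,
    wt_discriminating,
)
from .convergence import classify_convergence, growth_correlation_screen
from .datatypes import FluxRecord, SampleMeta, ValidationError
from .mutations import build_features, screen_correlates
from .simulate import SimulationConfig, generate_dataset, write_dataset
from .tradeoffs import detect_tradeoffs, jump_pca, select_candidates
from .trajectory import Jump, collapse_replicates, compute_jumps

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run."""

    seed: int = 0
    input_dir: str | None = None  # None -> simulate
    fdr_convergence: float = 0.05
    fdr_growth: float = 0.05
    fdr_wt: float = 0.005
    fdr_tradeoff: float = 0.05
    fdr_mutation: float = 0.05
    dima_min_change: float = 5.0
    dima_alpha: float = 0.05
    growth_r_min: float = 0.75
    growth_p_max: float = 0.05
    pca_weight_min: float = 0.10
    pca_ev_min: float = 0.05
    ancova_r2_min: float = 0.95
    replicate_r2_min: float = 0.9
    pca_exclusions: list[tuple[str, str]] = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name in (
            "fdr_convergence", "fdr_growth", "fdr_wt", "fdr_tradeoff",
            "fdr_mutation", "dima_alpha", "growth_p_max",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name}={v} outside (0, 1]")
        for name in ("growth_r_min", "ancova_r2_min", "replicate_r2_min",
                     "pca_ev_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.dima_min_change < 0 or self.pca_weight_min < 0:
            raise ValidationError("thresholds must be non-negative")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")


def flux_jump_deltas(
    fluxes: Sequence[FluxRecord], jumps: Sequence[Jump]
) -> pd.DataFrame:
    """Jump x reaction net-flux differences aligned on jump ids."""
    flask_net: dict[tuple[str, int, str], float] = {}
    for f in fluxes:
        flask_net[(f.strain, f.flask_index, f.reaction_id)] = f.v_net
    reactions = sorted({f.reaction_id for f in fluxes})
    rows = {}
    for j in jumps:
        row = {}
        for r in reactions:
            hi = flask_net.get((j.strain, j.to_flask, r))
            lo = flask_net.get((j.strain, j.from_flask, r))
            row[r] = (hi - lo) if hi is not None and lo is not None else np.nan
        rows[j.jump_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")[reactions]


def _phenotype_growth_inputs(
    table, meta: Sequence[SampleMeta]
) -> tuple[pd.DataFrame, pd.Series]:
    """Phenotype x (strain, stage) value matrix with matched growth rates."""
    growth: dict[tuple[str, str], list[float]] = {}
    for m in meta:
        growth.setdefault((m.strain, m.stage), []).append(m.growth_rate)
    g = {k: float(np.nanmean(v)) for k, v in growth.items()}
    df = table.data
    cols: dict[str, list] = {}
    gs = {}
    for (strain, stage), rate in sorted(g.items()):
        if stage not in ("WT", "EP"):
            continue
        key = f"{strain}:{stage}"
        sub = df[(df["strain"] == strain) & (df["stage"] == stage)]
        cols[key] = sub.set_index("phenotype_id")["value"]
        gs[key] = rate
    values = pd.DataFrame(cols)
    return values, pd.Series(gs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; write per-stage CSVs and the summary report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/load"
    try:
        if config.input_dir is None:
            ds = generate_dataset(seed=config.seed, config=config.simulation)
            write_dataset(ds, out / "dataset")
            meta, model = ds.meta, ds.model
            expression, phenotypes = ds.expression, ds.phenotypes
            fluxes, mutations = ds.fluxes, ds.mutations
            categories = ds.config.categories
        else:
            d = Path(config.input_dir)
            meta = aio.read_metadata(d / "metadata.csv")
            expression = aio.read_expression(d / "expression.csv")
            cats_path = d / "categories.json"
            categories = (
                json.loads(cats_path.read_text()) if cats_path.exists() else {}
            )
            model = aio.read_imodulon_model(d / "imodulon_model.csv", categories)
            phenotypes = aio.read_phenotypes(d / "phenotypes.csv")
            fluxes = aio.read_fluxes(d / "fluxes.csv")
            mutations = aio.read_mutations(d / "mutations.csv")

        stage = "qc"
        groups = {}
        for m in meta:
            groups.setdefault(f"{m.strain}:{m.flask_index}", []).append(m.sample_id)
        kept = aio.replicate_qc(expression, groups, r2_min=config.replicate_r2_min)
        dropped = sorted(set(expression.sample_ids) - set(kept))
        if dropped:
            log.info("qc: dropped replicate sample(s) %s", dropped)
            expression.data = expression.data[kept]
            meta = [m for m in meta if m.sample_id in set(kept)]
            groups = {
                k: [s for s in v if s in set(kept)] for k, v in groups.items()
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}

        stage = "project"
        activities = project_activities(model, expression)
        ev = explained_variance(model, activities, expression)
        aio.write_activities(activities, out / "activities_projected.csv")

        stage = "converge"
        conv = classify_convergence(phenotypes, fdr=config.fdr_convergence)
        conv.to_csv(out / "convergence.csv", index=False, float_format="%.10g")
        values, gseries = _phenotype_growth_inputs(phenotypes, meta)
        convergent_ids = conv.loc[conv["label"] == "convergent", "phenotype_id"]
        growth_phen = growth_correlation_screen(
            values, gseries, fdr=config.fdr_growth
        )
        growth_phen.to_csv(
            out / "phenotype_growth_correlation.csv", index=False,
            float_format="%.10g",
        )
        conv_set = set(convergent_ids)
        sig_growth = set(growth_phen.loc[growth_phen["significant"], "target"])
        n_conv_growth = len(conv_set & sig_growth)

        stage = "dima"
        null = fit_replicate_null(activities, groups)
        screens = dima_screen(
            activities, meta, null, categories=categories,
            min_change=config.dima_min_change, alpha=config.dima_alpha,
        )
        screens["wt_ep"].to_csv(out / "dima_wt_ep.csv", index=False, float_format="%.10g")
        screens["jumps"].to_csv(out / "dima_jumps.csv", index=False, float_format="%.10g")
        screens["category_counts"].to_csv(
            out / "dima_category_counts.csv", index=False
        )
        wt_ep = screens["wt_ep"]
        n_dima_imodulons = (
            wt_ep.loc[wt_ep["significant"], "imodulon"].nunique()
            if len(wt_ep) else 0
        )

        stage = "wt_discriminating"
        wt_table = wt_discriminating(activities, meta, fdr=config.fdr_wt)
        wt_table.to_csv(out / "wt_discriminating.csv", index=False, float_format="%.10g")

        stage = "growth_correlated_imodulons"
        growth_im = growth_correlated_imodulons(
            activities, meta, r_min=config.growth_r_min, p_max=config.growth_p_max
        )
        growth_im.to_csv(out / "growth_correlated_imodulons.csv", index=False,
                         float_format="%.10g")

        stage = "jumps"
        delta_a, jumps = compute_jumps(activities.data, meta, mutations)
        jump_table = pd.DataFrame(
            [
                {
                    "jump_id": j.jump_id,
                    "strain": j.strain,
                    "from_flask": j.from_flask,
                    "to_flask": j.to_flask,
                    "delta_growth": j.delta_growth,
                    "gained_mutations": ";".join(sorted(j.gained_mutations)),
                }
                for j in jumps
            ]
        )
        jump_table.to_csv(out / "jumps.csv", index=False, float_format="%.10g")
        delta_a.to_csv(out / "jump_delta_activities.csv", float_format="%.10g")

        stage = "tradeoffs"
        _, ev_ratios, loadings = jump_pca(delta_a, exclusions=config.pca_exclusions)
        candidates = select_candidates(
            loadings, ev_ratios,
            weight_min=config.pca_weight_min, ev_min=config.pca_ev_min,
        )
        flask_a, _ = collapse_replicates(activities.data, meta)
        pairs, pair_table = detect_tradeoffs(
            flask_a, meta, candidates,
            r2_min=config.ancova_r2_min, fdr=config.fdr_tradeoff,
            categories=categories,
        )
        pair_table.to_csv(out / "tradeoff_tests.csv", index=False, float_format="%.10g")
        pd.DataFrame(
            [
                {
                    "imodulon_a": p.imodulon_a, "imodulon_b": p.imodulon_b,
                    "pearson_r": p.pearson_r, "ancova_r2": p.ancova_r2,
                    "slope": p.slope, "q": p.q, "group": p.group,
                }
                for p in pairs
            ]
        ).to_csv(out / "tradeoff_pairs.csv", index=False, float_format="%.10g")

        stage = "mutcorr"
        features = build_features(mutations, jumps)
        delta_flux = flux_jump_deltas(fluxes, jumps)
        correlates, corr_table = screen_correlates(
            features, delta_flux, delta_a, fdr=config.fdr_mutation,
        )
        corr_table.to_csv(out / "mutation_tests.csv", index=False, float_format="%.10g")
        pd.DataFrame(
            [
                {
                    "feature": c.feature, "target": c.target,
                    "target_kind": c.target_kind, "statistic": c.statistic,
                    "p": c.p, "q": c.q,
                    "n_jumps_with_feature": c.n_jumps_with_feature,
                }
                for c in correlates
            ]
        ).to_csv(out / "mutation_correlates.csv", index=False, float_format="%.10g")
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    labels = conv["label"].value_counts()
    report = {
        "parameters": {
            "seed": config.seed,
            "fdr_convergence": config.fdr_convergence,
            "fdr_growth": config.fdr_growth,
            "fdr_wt": config.fdr_wt,
            "fdr_tradeoff": config.fdr_tradeoff,
            "fdr_mutation": config.fdr_mutation,
            "dima_min_change": config.dima_min_change,
            "dima_alpha": config.dima_alpha,
            "growth_r_min": config.growth_r_min,
            "growth_p_max": config.growth_p_max,
            "pca_weight_min": config.pca_weight_min,
            "pca_ev_min": config.pca_ev_min,
            "ancova_r2_min": config.ancova_r2_min,
            "replicate_r2_min": config.replicate_r2_min,
        },
        "n_samples": len(meta),
        "n_flasks": len({(m.strain, m.flask_index) for m in meta}),
        "n_jumps": len(jumps),
        "dropped_replicates": dropped,
        "explained_variance": round(ev, 6),
        "n_convergent": int(labels.get("convergent", 0)),
        "n_divergent": int(labels.get("divergent", 0)),
        "n_neither": int(labels.get("neither", 0)),
        "n_convergent_growth_correlated": n_conv_growth,
        "n_wt_discriminating": int(wt_table["significant"].sum()),
        "n_dima_imodulons_wt_ep": int(n_dima_imodulons),
        "dima_category_counts": {
            f"{r.category}|{r.direction}": int(r.count)
            for r in screens["category_counts"].itertuples()
        },
        "n_growth_correlated_imodulons": int(growth_im["selected"].sum()),
        "growth_correlated_imodulons": {
            r.imodulon: int(r.sign)
            for r in growth_im[growth_im["selected"]].itertuples()
        },
        "n_pca_candidates": len(candidates),
        "pca_ev_ratios": [round(float(v), 6) for v in ev_ratios[:5]],
        "n_tradeoff_pairs": len(pairs),
        "tradeoff_pairs": [[p.imodulon_a, p.imodulon_b] for p in pairs],
        "n_mutation_correlates_flux": sum(
            1 for c in correlates if c.target_kind == "flux"
        ),
        "n_mutation_correlates_imodulon": sum(
            1 for c in correlates if c.target_kind == "imodulon"
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["ALE multi-omics pipeline summary", "=" * 34]
    for k, v in report.items():
        if k in ("parameters",):
            continue
        lines.append(f"{k}: {v}")
    lines.append("parameters: " + json.dumps(report["parameters"], sort_keys=True))
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
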