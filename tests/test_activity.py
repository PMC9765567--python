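"""Activity projection, explained variance, and DIMA machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aleomics.activity import (
    LogNormalNull,
    dima,
    dima_screen,
    explained_variance,
    fit_replicate_null,
    growth_correlated_imodulons,
    project_activities,
    wt_discriminating,
)
from aleomics.datatypes import (
    ActivityMatrix,
    ExpressionMatrix,
    IModulonModel,
    SampleMeta,
    ValidationError,
)
from aleomics.simulate import (
    PlantedTruth,
    SimulationConfig,
    default_truth,
    generate_activities,
    generate_design,
)


def _model(w, genes=None, names=None):
    genes = genes or [f"g{i}" for i in range(w.shape[0])]
    names = names or [f"I{i}" for i in range(w.shape[1])]
    return IModulonModel(pd.DataFrame(w, index=genes, columns=names))


def _expr(x, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    samples = samples or [f"s{i}" for i in range(x.shape[1])]
    return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))


class TestProjection:
    def test_identity_basis_returns_expression(self):
        x = _expr(np.array([[1.0, 2.0], [3.0, 4.0]]))
        a = project_activities(_model(np.eye(2)), x)
        assert np.allclose(a.values, x.values)

    def test_recovers_activities_when_exact(self, rng):
        m = rng.normal(size=(40, 5))
        a0 = rng.normal(size=(5, 7))
        x = m @ a0
        x -= x.min()  # keep log-TPM non-negative without touching the fit
        a = project_activities(_model(m), _expr(x))
        shift_effect = np.linalg.pinv(m) @ np.full((40, 1), -(m @ a0).min())
        assert np.max(np.abs(a.values - (a0 + shift_effect))) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        m = rng.normal(size=(30, 4))
        x = np.abs(rng.normal(size=(30, 6)))
        a = project_activities(_model(m), _expr(x))
        oracle = np.linalg.solve(m.T @ m, m.T @ x)
        assert np.allclose(a.values, oracle, atol=1e-8)

    def test_rank_deficient_restriction_errors(self):
        w = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 1.0]])
        m = _model(w)
        # only the first two genes are shared -> duplicate columns, rank 1
        x = _expr(np.abs(np.random.default_rng(0).normal(size=(2, 3))),
                  genes=["g0", "g1"])
        with pytest.raises(ValidationError, match="rank deficient"):
            project_activities(m, x, min_gene_fraction=0.5)

    def test_refuses_small_gene_overlap(self, rng):
        m = _model(rng.normal(size=(10, 2)))
        x = _expr(np.abs(rng.normal(size=(3, 2))), genes=["g0", "g1", "g2"])
        with pytest.raises(ValidationError, match="basis genes"):
            project_activities(m, x, min_gene_fraction=0.5)


class TestExplainedVariance:
    def test_exact_reconstruction_is_one(self, rng):
        m = rng.normal(size=(30, 4))
        a0 = rng.normal(size=(4, 6))
        x = m @ a0
        x -= x.min()
        xm = _expr(x)
        mm = _model(m)
        a = project_activities(mm, xm)
        assert explained_variance(mm, a, xm) == pytest.approx(1.0, abs=1e-10)

    def test_zero_activities_give_zero_centered(self, rng):
        m = rng.normal(size=(30, 4))
        x = np.abs(rng.normal(size=(30, 6)))
        a = ActivityMatrix(
            pd.DataFrame(np.zeros((4, 6)), index=[f"I{i}" for i in range(4)],
                         columns=[f"s{i}" for i in range(6)])
        )
        assert explained_variance(_model(m), a, _expr(x)) == pytest.approx(0.0)

    def test_decreases_with_noise(self, rng):
        m = rng.normal(size=(80, 5))
        a0 = rng.normal(size=(5, 10))
        fracs = []
        for sd in (0.1, 1.0, 3.0):
            x = m @ a0 + rng.normal(0, sd, size=(80, 10))
            x -= x.min()
            xm, mm = _expr(x), _model(m)
            a = project_activities(mm, xm)
            fracs.append(explained_variance(mm, a, xm))
        assert fracs[0] > fracs[1] > fracs[2]

    def test_never_exceeds_one(self, dataset):
        a = project_activities(dataset.model, dataset.expression)
        ev = explained_variance(dataset.model, a, dataset.expression)
        assert 0.0 <= ev <= 1.0


class TestReplicateNull:
    def test_recovers_lognormal_parameters(self, rng):
        mu, sigma, n = 0.3, 0.5, 500
        diffs = rng.lognormal(mu, sigma, size=n)
        # two "samples" whose difference is exactly the drawn magnitudes
        a = ActivityMatrix(
            pd.DataFrame({"r1": np.zeros(n), "r2": diffs})
        )
        null = fit_replicate_null(a, {"g": ["r1", "r2"]})
        assert abs(null.mu - mu) < 0.1
        assert abs(null.sigma - sigma) < 0.1

    def test_identical_replicates_error(self):
        a = ActivityMatrix(pd.DataFrame({"r1": [1.0, 2.0], "r2": [1.0, 2.0]}))
        with pytest.raises(ValidationError, match="zero"):
            fit_replicate_null(a, {"g": ["r1", "r2"]})

    def test_scaling_shifts_mu_not_sigma(self, rng):
        diffs = rng.lognormal(0, 0.4, size=200)
        a1 = ActivityMatrix(pd.DataFrame({"r1": np.zeros(200), "r2": diffs}))
        a2 = ActivityMatrix(pd.DataFrame({"r1": np.zeros(200), "r2": 3 * diffs}))
        n1 = fit_replicate_null(a1, {"g": ["r1", "r2"]})
        n2 = fit_replicate_null(a2, {"g": ["r1", "r2"]})
        assert n2.mu == pytest.approx(n1.mu + np.log(3), abs=1e-9)
        assert n2.sigma == pytest.approx(n1.sigma, abs=1e-9)


NULL = LogNormalNull(mu=0.0, sigma=0.5, n_fit=100)


def _activities(values, samples):
    return ActivityMatrix(
        pd.DataFrame(values, index=[f"I{i}" for i in range(len(values))],
                     columns=samples)
    )


class TestDima:
    def test_zero_delta_not_significant(self):
        a = _activities([[1.0, 1.0, 1.0, 1.0]], ["a1", "a2", "b1", "b2"])
        res = dima(a, (["a1", "a2"], ["b1", "b2"]), NULL)
        assert res[0].p == 1.0 and not res[0].significant

    def test_threshold_blocks_small_change(self):
        # |delta| = 4.9 is below the minimum-change rule even at q ~ 0
        a = _activities([[0.0, 0.0, 4.9, 4.9]], ["a1", "a2", "b1", "b2"])
        res = dima(a, (["a1", "a2"], ["b1", "b2"]), NULL)
        assert res[0].q < 0.01 and not res[0].significant
        # just above the threshold it becomes significant
        a2 = _activities([[0.0, 0.0, 5.1, 5.1]], ["a1", "a2", "b1", "b2"])
        assert dima(a2, (["a1", "a2"], ["b1", "b2"]), NULL)[0].significant

    def test_antisymmetric_in_pair_order(self, rng):
        vals = rng.normal(0, 3, size=(5, 4))
        a = _activities(list(vals), ["a1", "a2", "b1", "b2"])
        fwd = dima(a, (["a1", "a2"], ["b1", "b2"]), NULL)
        rev = dima(a, (["b1", "b2"], ["a1", "a2"]), NULL)
        for f, r in zip(fwd, rev):
            assert f.delta_activity == pytest.approx(-r.delta_activity)
            assert f.p == pytest.approx(r.p)

    def test_power_and_type_i_error(self):
        # planted shift of 10 against LogNormal(0, 0.5): detected >= 95% of
        # 100 seeds; unshifted iModulons flagged at most alpha after BH
        n_seeds, alpha = 100, 0.05
        detected, false_flags, total_null = 0, 0, 0
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            base = r.normal(0, 1, size=20)
            d = r.lognormal(0, 0.5, size=(20, 2))
            sign = r.choice([-1, 1], size=(20, 2))
            cond1 = base[:, None] + sign * d / 2
            base2 = base.copy()
            base2[0] += 10.0  # the planted shift
            d2 = r.lognormal(0, 0.5, size=(20, 2))
            sign2 = r.choice([-1, 1], size=(20, 2))
            cond2 = base2[:, None] + sign2 * d2 / 2
            a = _activities(
                list(np.hstack([cond1, cond2])), ["a1", "a2", "b1", "b2"]
            )
            res = dima(a, (["a1", "a2"], ["b1", "b2"]), NULL, alpha=alpha)
            detected += res[0].significant
            false_flags += sum(r_.significant for r_ in res[1:])
            total_null += len(res) - 1
        assert detected / n_seeds >= 0.95
        rate = false_flags / total_null
        se = np.sqrt(alpha * (1 - alpha) / total_null)
        assert rate <= alpha + 2 * se

    def test_unknown_imodulon_errors(self):
        a = _activities([[1.0, 2.0]], ["a1", "b1"])
        with pytest.raises(ValidationError):
            dima(a, (["a1"], ["missing"]), NULL)


class TestDimaScreen:
    def test_category_counts_match_brute_recount(self, dataset):
        a = dataset.activities
        null = fit_replicate_null(a, dataset.replicate_groups)
        out = dima_screen(
            a, dataset.meta, null, categories=dataset.config.categories
        )
        sig = out["wt_ep"][out["wt_ep"]["significant"]]
        recount = sig.groupby(["category", "direction"]).size()
        table = out["category_counts"].set_index(["category", "direction"])["count"]
        assert table.sort_index().tolist() == recount.sort_index().tolist()

    def test_planted_wt_ep_shift_counted_per_strain(self):
        design = generate_design(n_strains=2, flasks_per_strain=[2, 2], seed=0)
        ids = [m.sample_id for m in design]
        vals = np.zeros((3, len(ids)))
        for i, m in enumerate(design):
            if m.stage == "EP":
                vals[0, i] = 10.0  # iModulon I0 shifts in every strain
        a = _activities(list(vals), ids)
        out = dima_screen(a, design, NULL, categories={"I0": "stress response"})
        sig = out["wt_ep"][out["wt_ep"]["significant"]]
        assert (sig["imodulon"] == "I0").all()
        assert len(sig) == 2  # once per strain
        counts = out["category_counts"]
        assert counts.loc[0, "category"] == "stress response"
        assert counts.loc[0, "count"] == 2


class TestWtDiscriminating:
    def test_recovers_exactly_planted_offsets(self):
        # truth with ONLY WT offsets and no strain baselines: nothing else
        # separates the strains at the WT stage
        cfg = SimulationConfig(strain_baseline_sd=0.0)
        design = generate_design(seed=2)
        base = default_truth(cfg)
        truth = PlantedTruth(
            convergent_phenotypes=base.convergent_phenotypes,
            divergent_phenotypes=base.divergent_phenotypes,
            neutral_phenotypes=base.neutral_phenotypes,
            growth_correlated_imodulons={},
            tradeoff_pairs=[],
            wt_offset_imodulons=base.wt_offset_imodulons,
            causal_mutations={},
        )
        a = generate_activities(design, truth, seed=2, config=cfg)
        out = wt_discriminating(a, design)
        found = set(out.loc[out["significant"], "imodulon"])
        planted = {
            im for offs in truth.wt_offset_imodulons.values() for im in offs
        }
        assert found == planted

    def test_no_offsets_mostly_empty(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            design = generate_design(n_strains=3, flasks_per_strain=[2, 2, 2],
                                     seed=seed)
            ids = [m.sample_id for m in design]
            a = _activities(list(r.normal(0, 1, size=(10, len(ids)))), ids)
            out = wt_discriminating(a, design, fdr=0.005)
            hits += out["significant"].any()
        assert hits / 20 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 20)

    def test_single_strain_errors(self):
        design = [m for m in generate_design(seed=0) if m.strain == "MG1655"]
        ids = [m.sample_id for m in design]
        a = _activities([np.zeros(len(ids))], ids)
        with pytest.raises(ValidationError):
            wt_discriminating(a, design)


class TestGrowthCorrelatedImodulons:
    def test_exact_growth_tracking_selected_positive(self):
        design = generate_design(seed=4)
        ids = [m.sample_id for m in design]
        g = np.array([m.growth_rate for m in design])
        a = _activities([50 * g, np.linspace(0, 1, len(ids))], ids)
        out = growth_correlated_imodulons(a, design)
        row = out[out["imodulon"] == "I0"].iloc[0]
        assert row["selected"] and row["sign"] == 1

    def test_planted_signs_recovered(self, dataset):
        out = growth_correlated_imodulons(dataset.activities, dataset.meta)
        selected = {
            r.imodulon: r.sign for r in out[out["selected"]].itertuples()
        }
        planted = dataset.truth.growth_correlated_imodulons
        # every planted coupling is found with the correct sign
        assert {k: selected.get(k) for k in planted} == planted
        # near-constant iModulons are never selected
        flat = {
            im for offs in dataset.truth.wt_offset_imodulons.values()
            for im in offs
        }
        assert not flat & set(selected)

    def test_independent_noise_rarely_selected(self):
        hits, n = 0, 20
        for seed in range(n):
            r = np.random.default_rng(300 + seed)
            design = generate_design(seed=seed)
            ids = [m.sample_id for m in design]
            a = _activities(list(r.normal(0, 2, size=(8, len(ids)))), ids)
            out = growth_correlated_imodulons(a, design)
            hits += out["selected"].any()
        assert hits / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
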