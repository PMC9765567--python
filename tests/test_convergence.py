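"""Distance-transform Mann-Whitney convergence test and shared screens."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aleomics.convergence import (
    anova_f_strain,
    bh_fdr,
    classify_convergence,
    growth_correlation_screen,
    mwu_normal_p,
    mwu_u,
    pairwise_distances,
)
from aleomics.datatypes import PhenotypeTable, ValidationError


class TestPairwiseDistances:
    def test_six_strains_give_fifteen(self):
        assert len(pairwise_distances(np.arange(6.0))) == 15

    def test_identical_values_all_zero(self):
        assert pairwise_distances([2.0] * 4) == pytest.approx(np.zeros(6))

    def test_small_example(self):
        assert sorted(pairwise_distances([0.0, 1.0, 3.0])) == [1.0, 2.0, 3.0]

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValidationError):
            pairwise_distances([1.0])


class TestMwuU:
    def test_fully_separated(self):
        assert mwu_u([1, 2, 3], [4, 5, 6]) == 9.0

    def test_all_ties_half_square(self):
        assert mwu_u([1, 1, 1], [1, 1, 1]) == 4.5

    def test_matches_brute_force_pair_count(self, rng):
        xs, ys = rng.normal(size=5), rng.normal(size=5)
        brute = sum(
            1.0 if x < y else (0.5 if x == y else 0.0) for x in xs for y in ys
        )
        assert mwu_u(xs, ys) == brute

    def test_agrees_with_scipy_statistic(self, rng):
        # scipy's U counts (x > y); ours counts (x < y): U + U' = n1*n2
        xs, ys = rng.normal(size=8), rng.normal(size=6)
        u_scipy = stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic
        assert mwu_u(xs, ys) == 48 - u_scipy


def exact_u_cdf(n1, n2):
    """Exact null CDF of U by full enumeration of rank arrangements."""
    total = n1 + n2
    counts = {}
    for xs in combinations(range(total), n1):
        xset = set(xs)
        u = sum(1 for x in xs for y in range(total) if y not in xset and x < y)
        counts[u] = counts.get(u, 0) + 1
    norm = sum(counts.values())
    return lambda u: sum(v for k, v in counts.items() if k <= u) / norm


class TestMwuNormalP:
    def test_reproduces_divergent_phenotype_p(self):
        # U = 19 with 15 vs 15 distances, lower tail, continuity corrected
        p = mwu_normal_p(19, 15, 15, alternative="less")
        assert f"{p:.1e}" == "5.7e-05"

    def test_continuity_off_shifts_third_figure(self):
        p = mwu_normal_p(19, 15, 15, alternative="less", continuity=False)
        assert f"{p:.1e}" == "5.3e-05"

    def test_center_is_near_half(self):
        p = mwu_normal_p(112.5, 15, 15, alternative="less")
        assert abs(p - 0.5) < 0.01

    def test_small_sample_close_to_exact(self):
        # n1 = n2 = 3, U = 0: exact p = 1/C(6,3) = 0.05
        cdf = exact_u_cdf(3, 3)
        assert cdf(0) == pytest.approx(0.05)
        assert abs(mwu_normal_p(0, 3, 3, "less") - 0.05) < 0.02

    def test_reflection_symmetry(self):
        for u in [0, 19, 50, 100]:
            assert mwu_normal_p(u, 15, 15, "less") == pytest.approx(
                mwu_normal_p(225 - u, 15, 15, "greater")
            )

    def test_degenerate_variance_returns_one(self):
        with pytest.warns(UserWarning, match="tied"):
            # tie term for 2n fully tied values kills the variance
            n = 3
            tie = (2 * n) ** 3 - 2 * n
            assert mwu_normal_p(4.5, n, n, "less", tie_term=tie) == 1.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # ranks 1..4: p*n/rank = (.04, .04, .04, .04) after monotone step-up
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_step_up(self, ps):
        ps = np.array(ps)
        n = len(ps)
        order = np.argsort(ps, kind="stable")
        q = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * n / rank)
            q[i] = running
        assert bh_fdr(ps) == pytest.approx(q)

    def test_q_dominates_p(self, rng):
        ps = rng.uniform(size=20)
        assert (np.sort(bh_fdr(ps)) >= np.sort(ps) - 1e-12).all()


def _panel(rows):
    return PhenotypeTable(pd.DataFrame(rows))


def _phen_rows(pid, wt_values, ep_values, strains=None):
    strains = strains or [f"S{i}" for i in range(len(wt_values))]
    rows = []
    for stage, vals in (("WT", wt_values), ("EP", ep_values)):
        for s, v in zip(strains, vals):
            rows.append(
                {"phenotype_id": pid, "unit": "abs", "strain": s,
                 "stage": stage, "value": float(v), "stdev": np.nan}
            )
    return rows


class TestClassifyConvergence:
    def test_collapsed_endpoint_is_convergent(self):
        table = _panel(
            _phen_rows("p1", [0, 2, 5, 9, 14, 20], [1, 1, 1, 1, 1, 1])
        )
        out = classify_convergence(table)
        assert out.loc[0, "label"] == "convergent"

    def test_identical_stages_neither(self):
        vals = [0, 2, 5, 9, 14, 20]
        out = classify_convergence(_panel(_phen_rows("p1", vals, vals)))
        assert out.loc[0, "label"] == "neither"

    def test_spread_endpoint_is_divergent(self):
        table = _panel(
            _phen_rows("p1", [1, 1, 1, 1, 1, 1], [0, 3, 7, 12, 18, 25])
        )
        out = classify_convergence(table)
        assert out.loc[0, "label"] == "divergent"

    def test_affine_rescaling_invariance(self, rng):
        wt = rng.normal(0, 3, 6)
        ep = rng.normal(0, 0.2, 6)
        t1 = _panel(_phen_rows("p1", wt, ep))
        t2 = _panel(_phen_rows("p1", 7.5 * wt - 2, 7.5 * ep - 2))
        r1, r2 = classify_convergence(t1), classify_convergence(t2)
        assert r1.loc[0, "U"] == r2.loc[0, "U"]
        assert r1.loc[0, "p_convergent"] == pytest.approx(r2.loc[0, "p_convergent"])

    def test_missing_stage_skipped_with_warning(self):
        rows = _phen_rows("ok", [1, 5, 9], [2, 2, 2])
        rows += [
            {"phenotype_id": "lonely", "unit": "abs", "strain": "S0",
             "stage": "WT", "value": 1.0, "stdev": np.nan}
        ]
        with pytest.warns(UserWarning, match="lonely"):
            out = classify_convergence(_panel(rows))
        assert list(out["phenotype_id"]) == ["ok"]


class TestGrowthCorrelationScreen:
    def test_exact_affine_target_detected(self, rng):
        g = pd.Series(rng.uniform(0.5, 1.1, 10), index=[f"f{i}" for i in range(10)])
        values = pd.DataFrame(
            {c: [3 * g[c] - 1, rng.normal()] for c in g.index},
            index=["coupled", "noise"],
        )
        out = growth_correlation_screen(values, g)
        coupled = out[out["target"] == "coupled"].iloc[0]
        assert coupled["r"] == pytest.approx(1.0)
        assert coupled["significant"]

    def test_pearson_matches_closed_form(self):
        g = pd.Series([0.5, 0.7, 0.8, 1.0, 1.1], index=list("abcde"))
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        values = pd.DataFrame([y], index=["t"], columns=g.index)
        gm, ym = g.to_numpy().mean(), y.mean()
        r_hand = ((g - gm) * (y - ym)).sum() / np.sqrt(
            ((g - gm) ** 2).sum() * ((y - ym) ** 2).sum()
        )
        out = growth_correlation_screen(values, g)
        assert out.loc[0, "r"] == pytest.approx(r_hand)

    def test_null_rejection_rate_near_alpha(self):
        # raw p < 0.05 frequency for an independent-noise target
        rng = np.random.default_rng(11)
        g = pd.Series(rng.uniform(0.5, 1.1, 12), index=[f"f{i}" for i in range(12)])
        rejections = 0
        n_seeds = 200
        for _ in range(n_seeds):
            y = rng.normal(size=12)
            out = growth_correlation_screen(
                pd.DataFrame([y], index=["t"], columns=g.index), g
            )
            rejections += out.loc[0, "p"] < 0.05
        rate = rejections / n_seeds
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rate - 0.05) <= 3 * se

    def test_constant_target_never_significant(self):
        g = pd.Series([0.5, 0.7, 0.9], index=list("abc"))
        values = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"], columns=g.index)
        out = growth_correlation_screen(values, g)
        assert out.loc[0, "p"] == 1.0 and not out.loc[0, "significant"]


class TestAnovaFStrain:
    def test_matches_hand_computed_mean_squares(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [2.0, 3.0, 4.0]]
        f, p = anova_f_strain(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(3 * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_hand)
        assert p == pytest.approx(stats.f.sf(f_hand, 2, 6))

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        f, p = anova_f_strain(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_separated_means_tiny_p(self, rng):
        groups = [rng.normal(0, 0.01, 4), rng.normal(10, 0.01, 4)]
        _, p = anova_f_strain(groups)
        assert p < 1e-6

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            pooled = rng.normal(size=12)
            groups = [pooled[:4], pooled[4:8], pooled[8:]]
            ps.append(anova_f_strain(groups)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_within_variance_convention(self):
        with pytest.warns(UserWarning, match="inf"):
            f, p = anova_f_strain([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f) and p == 0.0
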