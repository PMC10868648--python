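"""Rarefaction, Shannon, Spearman (exact-permutation oracle), mixed model,
Bray-Curtis, and PERMANOVA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from skinmb import diversity as dv


class TestRarefy:
    def test_below_depth_dropped_and_totals_exact(self, toy_table):
        out = dv.rarefy(toy_table, depth=1000, seed=0)
        assert "s4" not in out.index or toy_table.loc["s4"].sum() >= 1000
        assert set(out.index) == {"s1", "s2", "s3", "s4"} - {
            s for s in toy_table.index if toy_table.loc[s].sum() < 1000}
        assert (out.sum(axis=1) == 1000).all()

    def test_determinism_and_sample_independence(self, toy_table):
        a = dv.rarefy(toy_table, 900, seed=3)
        b = dv.rarefy(toy_table, 900, seed=3)
        pd.testing.assert_frame_equal(a, b)
        # a sample's draw does not depend on which other samples are present
        solo = dv.rarefy(toy_table.loc[["s2"]], 900, seed=3)
        pd.testing.assert_frame_equal(a.loc[["s2"]], solo)

    def test_subsample_never_exceeds_original(self, toy_table):
        out = dv.rarefy(toy_table, 900, seed=1)
        assert (out.to_numpy() <= toy_table.loc[out.index].to_numpy()).all()

    def test_invalid_depth(self, toy_table):
        with pytest.raises(ValueError):
            dv.rarefy(toy_table, 0, seed=0)


class TestShannon:
    def test_closed_forms(self, toy_table):
        h = dv.shannon_diversity(toy_table.loc[["s1", "s2", "s3"]])
        assert h["s1"] == pytest.approx(2.0)  # uniform over 4
        assert h["s2"] == pytest.approx(1.75)  # 500/250/125/125
        assert h["s3"] == pytest.approx(0.0)  # single feature

    def test_all_zero_sample_named(self):
        t = pd.DataFrame([[0, 0]], index=["empty"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            dv.shannon_diversity(t)

    def test_scale_and_permutation_invariance(self, toy_table):
        h1 = dv.shannon_diversity(toy_table.loc[["s1", "s2"]])
        h2 = dv.shannon_diversity(toy_table.loc[["s1", "s2"]] * 7)
        h3 = dv.shannon_diversity(toy_table.loc[["s1", "s2"]].iloc[:, ::-1])
        assert np.allclose(h1, h2) and np.allclose(h1, h3)

    def test_upper_bound_log2_richness(self, toy_table):
        h = dv.shannon_diversity(toy_table.loc[["s1", "s2", "s3"]])
        richness = (toy_table.loc[h.index] > 0).sum(axis=1)
        assert (h <= np.log2(richness) + 1e-12).all()


def brute_force_spearman(x, y):
    """Independent oracle: rho on mid-ranks and two-sided p by full
    enumeration of all n! orderings."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)

    def rho_of(a, b):
        a = a - a.mean(); b = b - b.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        return float((a * b).sum() / den)

    rho = rho_of(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.array(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


class TestSpearman:
    def test_monotone_and_antitone(self):
        up = dv.spearman_association([1, 2, 3], [10, 20, 30])
        assert up.estimate == pytest.approx(1.0)
        down = dv.spearman_association([1, 2, 3], [30, 20, 10])
        assert down.estimate == pytest.approx(-1.0)

    @pytest.mark.parametrize("y", [
        [3, 1, 4, 1, 5, 9, 2],     # with a tie
        [2, 2, 3, 3, 1, 5, 4],     # heavier ties
        [7, 6, 5, 4, 3, 2, 1],
    ])
    def test_exact_p_matches_enumeration_n7(self, y):
        x = [1, 2, 3, 4, 5, 6, 7]
        res = dv.spearman_association(x, y)
        rho_ref, p_ref = brute_force_spearman(np.array(x, float), np.array(y, float))
        assert res.estimate == pytest.approx(rho_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = dv.spearman_association(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_pairs_removed_and_min_n(self):
        res = dv.spearman_association([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert res.n == 3
        with pytest.raises(ValueError):
            dv.spearman_association([1, np.nan, 3], [1, 2, np.nan])


class TestLMM:
    def test_constant_response_no_signal(self):
        g = ["a"] * 10 + ["b"] * 10
        res = dv.lmm_association([5.0] * 20, list(range(20)), g)
        assert abs(res.estimate) < 1e-8
        assert res.p_value > 0.9

    def test_recovers_common_slope_across_offset_groups(self):
        """Within-group centering oracle: y = 2x + group offset."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        g = np.repeat(["a", "b", "c"], 40)
        offs = {"a": 4.0, "b": -1.0, "c": 9.0}
        y = 2 * x + np.array([offs[k] for k in g]) + rng.normal(0, 1e-4, 120)
        res = dv.lmm_association(y, x, g)
        # oracle: pooled slope of within-group-centered data
        xc = x - pd.Series(x).groupby(g).transform("mean").to_numpy()
        yc = y - pd.Series(y).groupby(g).transform("mean").to_numpy()
        slope = float(xc @ yc / (xc @ xc))
        assert res.estimate == pytest.approx(slope, abs=1e-3)
        assert res.estimate == pytest.approx(2.0, abs=1e-3)
        assert res.p_value < 1e-6

    def test_group_shift_leaves_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        g = np.repeat(["a", "b"], 30)
        y = 1.5 * x + rng.normal(0, 0.1, 60)
        base = dv.lmm_association(y, x, g).estimate
        y2 = y + np.where(g == "a", 100.0, 0.0)
        shifted = dv.lmm_association(y2, x, g).estimate
        assert abs(base - shifted) < 1e-6

    def test_single_group_falls_back_to_ols(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 3 * x + rng.normal(0, 0.1, 30)
        res = dv.lmm_association(y, x, ["only"] * 30)
        ols = scipy.stats.linregress(x, y)
        assert res.estimate == pytest.approx(ols.slope, abs=1e-9)


class TestBrayCurtis:
    def test_closed_forms(self):
        t = pd.DataFrame([[2, 0, 2], [1, 1, 0], [2, 0, 2], [0, 3, 0]],
                         index=list("abcd"))
        dm = dv.bray_curtis_distance(t)
        assert dm["a", "b"] == pytest.approx(2 / 3)
        assert dm["a", "c"] == pytest.approx(0.0)
        assert dm["a", "d"] == pytest.approx(1.0)  # disjoint

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.integers(0, 30, (6, 10)).astype(float) + 1)
        dm = dv.bray_curtis_distance(t)
        ref = scipy.spatial.distance.pdist(t.to_numpy(), "braycurtis")
        assert np.allclose(dm.condensed_form(), ref)


def gower_oracle_r2_f(D, x):
    """Hand-evaluated single-df Gower decomposition for a continuous x."""
    n = len(x)
    A = -0.5 * D ** 2
    C = np.eye(n) - 1 / n
    G = C @ A @ C
    xc = x - x.mean()
    H = np.outer(xc, xc) / (xc @ xc)
    ss_model = np.trace(H @ G)
    ss_total = np.trace(G)
    f = (ss_model / 1) / ((ss_total - ss_model) / (n - 2))
    return ss_model / ss_total, f


class TestPermanova:
    def _two_group_dm(self):
        # two tight pairs far apart
        D = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        from skbio import DistanceMatrix
        return DistanceMatrix(D, ids=list("abcd"))

    def test_r2_matches_hand_evaluated_decomposition(self):
        dm = self._two_group_dm()
        x = np.array([0.0, 0.0, 1.0, 1.0])
        res = dv.permanova(dm, x, n_permutations=99, seed=0)
        r2_ref, f_ref = gower_oracle_r2_f(dm.data, x)
        assert res.r_squared == pytest.approx(r2_ref, abs=1e-12)
        assert res.pseudo_f == pytest.approx(f_ref, abs=1e-10)

    def test_categorical_matches_skbio(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.integers(1, 40, (12, 8)), index=[f"s{i}" for i in range(12)])
        dm = dv.bray_curtis_distance(t)
        grp = ["g1"] * 6 + ["g2"] * 6
        mine = dv.permanova(dm, pd.Series(grp), n_permutations=99, seed=0)
        from skbio.stats.distance import permanova as sk_permanova
        ref = sk_permanova(dm, pd.DataFrame({"g": grp}, index=dm.ids), column="g",
                           permutations=99)
        assert mine.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_minimum_attainable_p(self):
        dm = self._two_group_dm()
        res = dv.permanova(dm, np.array([0.0, 0.0, 1.0, 1.0]), n_permutations=999, seed=1)
        assert res.p_value >= 1 / (999 + 1)

    def test_relabeling_invariance_and_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.integers(1, 40, (10, 6)), index=[f"s{i}" for i in range(10)])
        x = rng.normal(size=10)
        dm = dv.bray_curtis_distance(t)
        a = dv.permanova(dm, x, 199, seed=9)
        t2 = t.set_axis([f"renamed{i}" for i in range(10)], axis=0)
        b = dv.permanova(dv.bray_curtis_distance(t2), x, 199, seed=9)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)
        assert a.p_value == b.p_value

    def test_single_level_variable_rejected(self):
        dm = self._two_group_dm()
        with pytest.raises(ValueError, match="single unique value"):
            dv.permanova(dm, pd.Series(["g"] * 4), 99, 0)


@settings(deadline=None, max_examples=20)
@given(st.lists(st.integers(0, 200), min_size=4, max_size=10).filter(lambda v: sum(v) > 0))
def test_shannon_nonnegative_property(counts):
    t = pd.DataFrame([counts], index=["s"])
    h = dv.shannon_diversity(t)
    assert h["s"] >= -1e-12
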