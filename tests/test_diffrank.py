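"""Prevalence filter, design construction, the NB sampler, R-hat, and
feature ranking."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import skinmb
from skinmb import diffrank as dr


class TestPrevalenceFilter:
    def _table(self, prevalences, n=100):
        cols = {}
        for i, p in enumerate(prevalences):
            col = np.zeros(n, dtype=int)
            col[:p] = 1
            cols[f"f{i}"] = col
        return pd.DataFrame(cols, index=[f"s{j}" for j in range(n)])

    def test_boundary_14_removed_15_retained(self):
        t = self._table([14, 15, 16])
        out = dr.prevalence_filter(t, 15)
        assert list(out.columns) == ["f1", "f2"]

    def test_threshold_one_is_noop_without_empty_features(self):
        t = self._table([5, 9])
        pd.testing.assert_frame_equal(dr.prevalence_filter(t, 1), t)

    def test_threshold_above_sample_count_rejected(self):
        t = self._table([5], n=10)
        with pytest.raises(ValueError):
            dr.prevalence_filter(t, 11)


class TestBuildDesign:
    def _meta(self):
        return pd.DataFrame({
            "study_id": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "age": [20, 30, 40, 50, 25, 35, 45, 55, 22, 33, 44, 60.0],
            "gcfw": [1, 2, 3, 4, 1, 2, 3, 4, 2, 3, 4, np.nan],
        }, index=[f"s{i}" for i in range(12)])

    def test_reference_coded_dummies(self):
        d = dr.build_design(self._meta(), ["study_id", "age"])
        study_cols = [c for c in d.X.columns if c.startswith("study_id")]
        assert len(study_cols) == 2  # 3 studies -> 2 dummies + intercept
        assert "Intercept" in d.X.columns

    def test_continuous_standardized(self):
        d = dr.build_design(self._meta(), ["study_id", "age"])
        assert abs(d.X["age"].mean()) < 1e-9
        assert d.X["age"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        mean, sd = d.scaling["age"]
        back = d.X["age"] * sd + mean
        assert np.allclose(back, self._meta()["age"])

    def test_missing_covariate_rows_dropped(self):
        d = dr.build_design(self._meta(), ["study_id", "age", "gcfw"])
        assert d.n_dropped == 1
        assert "s11" not in d.sample_ids

    def test_collinear_design_named(self):
        m = self._meta()
        m["age2"] = m["age"] * 2
        with pytest.raises(ValueError, match="age"):
            dr.build_design(m, ["age", "age2"])

    def test_absent_field_named(self):
        with pytest.raises(KeyError, match="tewl"):
            dr.build_design(self._meta(), ["study_id", "tewl"])


class TestRhat:
    def test_identical_chains_closed_form(self):
        # B = 0, n = 4 -> sqrt((n-1)/n) = sqrt(3/4)
        val = dr.compute_rhat([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert val == pytest.approx(np.sqrt(3 / 4), abs=1e-12)

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 1000))
        assert dr.compute_rhat(chains) < 1.05

    def test_offset_chains_large(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert dr.compute_rhat(chains) > 1.1

    def test_constant_chains_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(dr.compute_rhat([[1.0, 1.0], [1.0, 1.0]]))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            dr.compute_rhat([[1.0, 2.0]])


class TestModelSpec:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            dr.NBModelSpec(chains=1)


def _tiny_fit(seed=0, scale_sample=None, **spec_kw):
    """Small planted dataset + fit, optionally scaling one sample's counts."""
    cfg = skinmb.SyntheticConfig(
        n_studies=2, samples_per_study=30, n_features=20,
        n_signature_pos=3, n_signature_neg=3, effect_size=2.0,
        duplicate_fraction=0.0,
        phenotype_studies={"gcfw": (0, 1), "tewl": (0, 1), "corneometer": (0, 1)},
        seed=7,
    )
    table, meta, _, truth = skinmb.generate_multistudy(cfg)
    if scale_sample is not None:
        table.loc[table.index[0]] *= scale_sample
    design = dr.build_design(meta, ["study_id", "age", "gcfw"])
    spec = dr.NBModelSpec(num_iter=100, num_warmup=40, chains=2, seed=seed, **spec_kw)
    filt = dr.prevalence_filter(table.loc[design.sample_ids], 10)
    res = dr.fit_nb_differentials(filt, design, spec)
    return res, truth


class TestFit:
    def test_determinism(self):
        a, _ = _tiny_fit(seed=3)
        b, _ = _tiny_fit(seed=3)
        pd.testing.assert_frame_equal(a.differentials, b.differentials)
        pd.testing.assert_frame_equal(a.r_hat, b.r_hat)
        assert a.lppd == b.lppd

    def test_depth_offset_makes_differentials_scale_invariant(self):
        """Multiplying all counts of one sample by a constant moves its
        offset, not the differentials."""
        a, _ = _tiny_fit(seed=3)
        b, _ = _tiny_fit(seed=3, scale_sample=10)
        diff = (a.differentials - b.differentials).abs().to_numpy().max()
        # identical seeds, MAP-initialised chains: small numeric drift only
        assert diff < 0.05

    def test_signature_features_rank_at_extremes(self):
        res, truth = _tiny_fit(seed=1)
        ranked = dr.rank_features(res, "gcfw")
        top = set(ranked[:3])
        bottom = set(ranked[-3:])
        assert len(top & truth.signature_pos) >= 2
        assert len(bottom & truth.signature_neg) >= 2

    def test_differentials_mean_centered(self):
        res, _ = _tiny_fit(seed=2)
        assert np.allclose(res.differentials.mean(axis=0), 0.0, atol=1e-8)

    def test_ppc_and_lppd_sane(self):
        res, _ = _tiny_fit(seed=2)
        assert 0.8 <= res.ppc_coverage <= 1.0
        assert np.isfinite(res.lppd) and res.lppd < 0

    def test_non_integer_counts_rejected(self):
        t = pd.DataFrame([[1.5, 2.0]] * 6, index=[f"s{i}" for i in range(6)],
                         columns=["f1", "f2"])
        meta = pd.DataFrame({"study_id": ["a", "a", "a", "b", "b", "b"],
                             "age": [1.0, 2, 3, 4, 5, 6]}, index=t.index)
        design = dr.build_design(meta, ["study_id", "age"])
        with pytest.raises(ValueError, match="integer"):
            dr.fit_nb_differentials(t, design, dr.NBModelSpec(num_iter=5, num_warmup=2))


class TestRanking:
    def _result(self, values):
        idx = pd.Index(sorted(values), name="feature_id")
        df = pd.DataFrame({"gcfw": pd.Series(values)}).loc[idx]
        zeros = df * 0
        return dr.DifferentialResult(df, zeros, zeros, zeros + 1.0, 0.0, 1.0)

    def test_descending_order(self):
        res = self._result({"A": 1.0, "B": -0.5, "C": 0.2})
        assert dr.rank_features(res, "gcfw") == ["A", "C", "B"]

    def test_tie_break_lexicographic(self):
        res = self._result({"B": 0.5, "A": 0.5, "C": 1.0})
        assert dr.rank_features(res, "gcfw") == ["C", "A", "B"]

    def test_permutation_of_input(self):
        vals = {f"f{i}": float(np.sin(i)) for i in range(9)}
        res = self._result(vals)
        assert sorted(dr.rank_features(res, "gcfw")) == sorted(vals)

    def test_unknown_covariate(self):
        res = self._result({"A": 1.0, "B": 0.0})
        with pytest.raises(KeyError):
            dr.rank_features(res, "tewl")
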