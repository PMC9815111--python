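"""Tests of the twin variance models: likelihood, fitting, correlations,
model selection and the covariate-adjusted means model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycanclock import (
    TwinPairDataset,
    TwinVarianceModel,
    fit_model,
    heritability_with_covariate,
    intrapair_correlations,
    pair_loglik,
    select_model,
    simulate_ace_phenotype,
)
from glycanclock.datasets import ValidationError
from glycanclock.twin import VarianceModelSpec

from oracles import dense_pair_loglik

LOG2PI = np.log(2 * np.pi)


class TestIntrapairCorrelations:
    def test_identical_members_give_unit_correlations(self):
        y = np.random.default_rng(0).normal(size=20)
        d = TwinPairDataset(y, y.copy(), np.array(["MZ"] * 10 + ["DZ"] * 10,
                                                  dtype=object))
        r = intrapair_correlations(d)
        assert r["rMZ"] == pytest.approx(1.0)
        assert r["rDZ"] == pytest.approx(1.0)

    def test_independent_members_near_zero(self):
        # ±0.03 is ~4 SE at 20000 pairs per group
        rng = np.random.default_rng(1)
        d = TwinPairDataset(rng.normal(size=40000), rng.normal(size=40000),
                            np.array(["MZ"] * 20000 + ["DZ"] * 20000,
                                     dtype=object))
        r = intrapair_correlations(d)
        assert abs(r["rMZ"]) < 0.03 and abs(r["rDZ"]) < 0.03

    def test_ace_structure_recovered(self):
        d = simulate_ace_phenotype(20000, 20000, 0.4, 0.45, 0.15, 0.0,
                                   seed=99)
        r = intrapair_correlations(d)
        assert r["rMZ"] == pytest.approx(0.85, abs=0.02)
        assert r["rDZ"] == pytest.approx(0.65, abs=0.02)

    def test_double_entry_is_label_invariant(self, small_ace_data):
        d = small_ace_data
        swapped = TwinPairDataset(d.y2, d.y1, d.zygosity)
        assert intrapair_correlations(d) == intrapair_correlations(swapped)

    def test_tiny_group_rejected(self):
        d = TwinPairDataset([1.0, 2.0, 3.0], [1.1, 2.1, 3.1],
                            np.array(["MZ", "MZ", "DZ"], dtype=object))
        with pytest.raises(ValidationError, match="DZ"):
            intrapair_correlations(d)


class TestPairLoglik:
    def test_standard_bivariate_normal_at_origin(self):
        d = TwinPairDataset([0.0], [0.0], np.array(["MZ"], dtype=object))
        ll = pair_loglik({"e": 1.0, "beta": [0.0]}, d,
                         VarianceModelSpec(("E",)))
        assert ll == pytest.approx(-LOG2PI, abs=1e-12)
        assert ll == pytest.approx(-1.837877, abs=1e-6)

    def test_zero_e_rejected(self):
        d = TwinPairDataset([0.0], [0.0], np.array(["MZ"], dtype=object))
        with pytest.raises(ValidationError, match="singular"):
            pair_loglik({"a": 0.5, "e": 0.0, "beta": [0.0]}, d)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_swap_invariance_to_the_last_bit(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        d = simulate_ace_phenotype(10, 10, 0.3, 0.3, 0.4, 0.0, seed=seed)
        swapped = TwinPairDataset(d.y2, d.y1, d.zygosity)
        params = {"a": rng.uniform(0.1, 1), "c": rng.uniform(0.1, 1),
                  "e": rng.uniform(0.1, 1), "beta": [rng.normal()]}
        assert pair_loglik(params, d) == pair_loglik(params, swapped)

    def test_matches_dense_matrix_oracle(self):
        """Vectorized likelihood equals a naive per-pair 2×2 inversion on
        100 random datasets."""
        rng = np.random.default_rng(55)
        for _ in range(100):
            n_mz, n_dz = rng.integers(2, 15, size=2)
            d = simulate_ace_phenotype(int(n_mz), int(n_dz), 0.5, 0.3, 0.2,
                                       rng.normal(), seed=int(rng.integers(1e6)))
            a, c, e = rng.uniform(0.2, 1.2, size=3)
            mu = rng.normal()
            ll = pair_loglik({"a": a, "c": c, "e": e, "beta": [mu]}, d)
            expected = dense_pair_loglik(d.y1, d.y2, d.zygosity,
                                         a**2, c**2, e**2, mu)
            assert ll == pytest.approx(expected, abs=1e-10)


class TestFitModel:
    def test_e_only_model_closed_form(self, small_ace_data):
        """The E-only fit is iid-normal ML: ê² = sample variance with
        divisor n, and the log-likelihood matches the normal formula."""
        d = small_ace_data
        res = fit_model(d, ("E",))
        y = np.concatenate([d.y1, d.y2])
        var_ml = y.var()
        assert res.e2 == pytest.approx(var_ml, abs=1e-8)
        assert res.beta[0] == pytest.approx(y.mean(), abs=1e-8)
        expected_ll = -0.5 * len(y) * (LOG2PI + np.log(var_ml) + 1.0)
        assert res.llf == pytest.approx(expected_ll, abs=1e-8)

    def test_pure_c_world_keeps_a_near_boundary(self):
        # with rMZ = rDZ in truth, â² is a boundary-censored estimate with
        # sampling SD ≈ 0.026 at this size; 0.08 is a ~3 SD bound
        d = simulate_ace_phenotype(5000, 5000, 0.0, 0.6, 0.4, 0.0, seed=3)
        res = fit_model(d, ("A", "C", "E"))
        assert res.a2 < 0.08
        assert res.c2 == pytest.approx(0.6, abs=0.05)

    def test_standardized_components_sum_to_one(self, small_ace_data):
        for comps in (("A", "C", "E"), ("A", "E"), ("C", "E"), ("E",)):
            res = fit_model(small_ace_data, comps)
            assert res.h2 + res.c2_std + res.e2_std == pytest.approx(1.0,
                                                                     abs=1e-10)
            assert min(res.a2, res.c2, res.e2) >= 0

    def test_aic_identity(self, small_ace_data):
        res = fit_model(small_ace_data, ("A", "C", "E"))
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.llf,
                                        abs=1e-10)
        assert res.n_params == 4  # three paths + intercept

    def test_nesting_monotonicity(self):
        for seed in range(5):
            d = simulate_ace_phenotype(150, 250, 0.4, 0.3, 0.3, 1.0,
                                       seed=seed)
            ll = {c: fit_model(d, c).llf
                  for c in (("A", "C", "E"), ("A", "E"), ("C", "E"), ("E",))}
            full = ll[("A", "C", "E")]
            assert full >= ll[("A", "E")] - 1e-6
            assert full >= ll[("C", "E")] - 1e-6
            assert ll[("A", "E")] >= ll[("E",)] - 1e-6
            assert ll[("C", "E")] >= ll[("E",)] - 1e-6

    def test_single_zygosity_group_rejected_for_ace(self):
        rng = np.random.default_rng(0)
        d = TwinPairDataset(rng.normal(size=30), rng.normal(size=30),
                            np.array(["MZ"] * 30, dtype=object))
        with pytest.raises(ValidationError, match="identifiable"):
            fit_model(d, ("A", "C", "E"))
        fit_model(d, ("E",))  # E-only is fine with one group

    def test_falconer_agreement_for_interior_estimates(self):
        d = simulate_ace_phenotype(10000, 10000, 0.4, 0.35, 0.25, 0.0,
                                   seed=17)
        res = fit_model(d)
        r = intrapair_correlations(d)
        falconer_h2 = 2 * (r["rMZ"] - r["rDZ"])
        assert abs(res.h2 - falconer_h2) <= 0.05

    def test_summary_mentions_components_and_counts(self, small_ace_data):
        res = fit_model(small_ace_data)
        text = res.summary()
        assert "ACE" in text and "MZ 80" in text and "AIC" in text


class TestModelSelection:
    def test_lrt_table_and_best_model_bookkeeping(self, small_ace_data):
        sel = select_model(small_ace_data)
        assert set(sel.fits) == {"ACE", "AE", "CE", "E"}
        for label, df in (("AE", 1), ("CE", 1), ("E", 2)):
            stat, dof, p = sel.lrt[label]
            assert dof == df and stat >= 0 and 0 <= p <= 1
        # best model is min-AIC among ACE and non-rejected reductions
        candidates = ["ACE"] + [l for l in ("AE", "CE", "E")
                                if sel.lrt[l][2] > sel.alpha]
        assert sel.best == min(candidates, key=lambda l: sel.fits[l].aic)

    def test_ae_truth_selects_ae(self):
        d = simulate_ace_phenotype(549, 1201, 0.7, 0.0, 0.3, 0.0, seed=2)
        sel = select_model(d, seed=2)
        assert sel.best == "AE"

    def test_ace_truth_selects_ace(self):
        d = simulate_ace_phenotype(479, 1193, 0.39, 0.45, 0.16, 0.0, seed=2)
        sel = select_model(d, seed=2)
        assert sel.best == "ACE"

    def test_selection_result_serializes(self, small_ace_data):
        sel = select_model(small_ace_data)
        d = sel.to_dict()
        assert d["best"] == sel.best
        assert "statistic" in d["lrt"]["AE"]
        assert "ACE" in sel.summary()


def _aged_dataset(n_mz, n_dz, beta_age, c2, seed, age_as_c=False):
    """ACE data plus a shared-age effect on the mean."""
    rng = np.random.default_rng(seed)
    d = simulate_ace_phenotype(n_mz, n_dz, 0.4, c2, 0.2, 0.0, seed=seed)
    age = rng.uniform(30, 70, d.n_pairs)
    y1 = d.y1 + beta_age * age
    y2 = d.y2 + beta_age * age
    return TwinPairDataset(y1, y2, d.zygosity, age[:, None], age[:, None],
                           ("age",))


class TestCovariateAdjustment:
    def test_age_coefficient_recovered(self):
        d = _aged_dataset(300, 500, beta_age=0.9, c2=0.3, seed=4)
        model = TwinVarianceModel(d, covariates=("age",))
        res = model.fit()
        # SE of the age slope from the delta-method machinery is not
        # exposed; 3·(rough OLS SE) bounds the ML estimate comfortably
        y = np.concatenate([d.y1, d.y2])
        X = np.column_stack([np.ones(2 * d.n_pairs),
                             np.concatenate([d.X1[:, 0], d.X2[:, 0]])])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        se = np.sqrt(resid.var() / ((X[:, 1] - X[:, 1].mean()) ** 2).sum())
        assert abs(res.beta[1] - 0.9) <= 3 * se

    def test_age_shared_similarity_moves_out_of_c(self):
        """When pair similarity is age-driven, adjusting for age drops C
        more often than the unadjusted analysis."""
        drops_adj = drops_unadj = 0
        for seed in range(10):
            d = _aged_dataset(200, 400, beta_age=0.12, c2=0.0, seed=seed)
            unadj = select_model(d, seed=seed)
            adj = heritability_with_covariate(d, "age", seed=seed)
            drops_unadj += "C" not in unadj.best
            drops_adj += "C" not in adj.best
        assert drops_adj >= drops_unadj
        assert drops_adj >= 7  # age explains all C-like similarity

    def test_null_covariate_leaves_h2_unchanged(self):
        d = _aged_dataset(479, 1193, beta_age=0.0, c2=0.35, seed=6)
        unadj = fit_model(d)
        adj = TwinVarianceModel(d, covariates=("age",)).fit()
        assert abs(adj.h2 - unadj.h2) <= 0.03

    def test_missing_covariate_rejected(self, small_ace_data):
        with pytest.raises(ValidationError, match="age"):
            heritability_with_covariate(small_ace_data, "age")


class TestDatasetConstruction:
    def test_from_dataframe_pivots_pairs(self):
        df = pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "pair_id": ["a", "a", "b", "b"],
            "zygosity": ["MZ", "MZ", "DZ", "DZ"],
            "glycan_age": [50.0, 51.0, 60.0, 58.0],
            "age": [40.0, 40.0, 55.0, 55.0],
        })
        d = TwinPairDataset.from_dataframe(df, "glycan_age",
                                           covariates=("age",))
        assert d.n_pairs == 2
        assert d.counts() == {"MZ": 1, "DZ": 1}

    def test_incomplete_pair_rejected(self):
        df = pd.DataFrame({
            "sample_id": ["a1", "a2", "b1"],
            "pair_id": ["a", "a", "b"],
            "zygosity": ["MZ", "MZ", "DZ"],
            "glycan_age": [50.0, 51.0, 60.0],
        })
        with pytest.raises(ValidationError, match="singleton"):
            TwinPairDataset.from_dataframe(df, "glycan_age")

    def test_conf_int_clipped_to_unit_interval(self, small_ace_data):
        ci = fit_model(small_ace_data).conf_int()
        for lo, hi in ci.values():
            assert 0.0 <= lo <= hi <= 1.0
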