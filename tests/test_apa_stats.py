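import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apatwinscan.apa_stats import (
    DispersionEstimate,
    call_significant_shifts,
    estimate_dispersion,
    estimate_qvalues,
    interaction_design,
    log2_ratio_change,
    lrt_interaction_test,
    tmm_factors,
)
from apatwinscan.apa_stats import test_apa_shifts as run_apa_shifts
from apatwinscan.datamodel import DataError, ShiftTest, design_frame
from apatwinscan.synthetic import SimulationConfig, make_design, simulate_counts

from tests.oracles import grid_search_lrt


def null_counts(design_df, rng, n_genes=10, mean=100.0, phi=0.1):
    rows, idx = [], []
    for g in range(n_genes):
        for label in ("P", "D"):
            mu = mean * rng.uniform(0.5, 1.5)
            rows.append(rng.negative_binomial(1 / phi, 1 / (1 + phi * mu),
                                              size=len(design_df)))
            idx.append(f"g{g}|{label}")
    return pd.DataFrame(rows, index=idx, columns=design_df.index)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=200)
        counts = pd.DataFrame({"s1": col, "s2": col},
                              index=[f"g{i}|P" for i in range(200)])
        nf = tmm_factors(counts)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        """Column B = 2 x column A is pure depth: with library sizes from
        column sums the M values vanish and both factors are 1.
        Hand computation on the 10-row table: M_i = log2((2a_i/2N)/(a_i/N))
        = 0 for every row, so the trimmed weighted mean is 0."""
        a = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        counts = pd.DataFrame({"A": a, "B": 2 * a},
                              index=[f"g{i}|P" for i in range(10)])
        nf = tmm_factors(counts)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-12)

    def test_single_outlier_row_is_trimmed(self):
        """One differing row among 100 equal rows falls in the trimmed M
        tail, leaving factors at 1."""
        a = np.full(100, 50)
        b = a.copy()
        b[0] = 500
        counts = pd.DataFrame({"A": a, "B": b},
                              index=[f"g{i}|P" for i in range(100)])
        lib = pd.Series({"A": 5000.0, "B": 5000.0})
        nf = tmm_factors(counts, library_sizes=lib)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(40, size=(300, 4)),
            index=[f"g{i}|P" for i in range(300)],
            columns=list("abcd"),
        )
        nf = tmm_factors(counts)
        assert np.prod(nf.factors) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_table_warns_factor_one(self):
        counts = pd.DataFrame({"A": [5, 0], "B": [0, 7]},
                              index=["g|P", "g|D"])
        with pytest.warns(UserWarning, match="TMM factor set to 1"):
            nf = tmm_factors(counts)
        np.testing.assert_allclose(nf.factors, 1.0)


class TestDispersion:
    def test_poisson_data_hits_grid_floor(self, small_design_df):
        """Poisson counts (phi -> 0) push the common estimate to the
        bottom of the grid."""
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(n_genes=100, n_shifted=0, n_motif_candidates=0,
                               dispersion=1e-6, batch_effect_sd=0.0, seed=5)
        counts, _ = simulate_counts(cfg)
        ddf = design_frame(make_design(cfg))
        est = estimate_dispersion(counts, ddf)
        assert est.common <= 0.01

    def test_tagwise_with_huge_prior_df_equals_common(self, small_design_df):
        rng = np.random.default_rng(6)
        counts = null_counts(small_design_df, rng, n_genes=20)
        est = estimate_dispersion(counts, small_design_df, mode="tagwise",
                                  prior_df=1e9)
        assert np.allclose(est.tagwise, est.common, rtol=1e-6)

    def test_no_replication_rejected(self):
        cfg = SimulationConfig(n_genes=5, n_shifted=0, n_motif_candidates=0,
                               replicates_per_condition=1, seed=0)
        counts, _ = simulate_counts(cfg)
        ddf = design_frame(make_design(cfg))
        with pytest.raises(DataError, match="fixed dispersion"):
            estimate_dispersion(counts, ddf)


class TestLRT:
    def test_identical_conditions_give_zero_statistic(self, small_design_df):
        y = np.array([30.0, 30, 30, 30, 30, 30, 70, 70, 70, 70, 70, 70])
        nf = tmm_factors(pd.DataFrame(
            {s: [30, 70] for s in small_design_df.index},
            index=["g|P", "g|D"]))
        t = lrt_interaction_test(y, small_design_df, nf, 0.1, gene_id="g")
        assert t.lrt_statistic == pytest.approx(0.0, abs=1e-6)
        assert t.p_value == pytest.approx(1.0, abs=1e-4)

    def test_matches_grid_search_oracle(self, small_design_df):
        """IRLS LRT equals the grid-search likelihood oracle on random
        small genes."""
        rng = np.random.default_rng(11)
        X_full, X_red, _ = interaction_design(small_design_df)
        counts = null_counts(small_design_df, rng, n_genes=4)
        nf = tmm_factors(counts)
        eff = nf.effective_library_sizes.to_numpy(dtype=float)
        offset = np.log(np.concatenate([eff, eff]))
        for g in range(4):
            y = np.concatenate([
                counts.loc[f"g{g}|P"].to_numpy(dtype=float),
                counts.loc[f"g{g}|D"].to_numpy(dtype=float),
            ])
            t = lrt_interaction_test(y, small_design_df, nf, 0.1)
            stat_oracle = grid_search_lrt(y, X_full, X_red, offset, 0.1)
            assert t.lrt_statistic == pytest.approx(stat_oracle, abs=1e-4)

    def test_strong_interaction_detected(self, small_design_df):
        y = np.array([200.0, 180, 210, 1600, 1650, 1580,  # proximal A then B
                      300, 290, 310, 280, 300, 320])  # distal flat
        nf_counts = pd.DataFrame(
            np.vstack([y[:6], y[6:]]), index=["g|P", "g|D"],
            columns=small_design_df.index)
        nf = tmm_factors(nf_counts)
        t = lrt_interaction_test(y, small_design_df, nf, 0.1)
        assert t.p_value < 1e-4
        assert t.interaction_coef > 0

    def test_sample_permutation_invariance(self, small_design_df):
        rng = np.random.default_rng(13)
        counts = null_counts(small_design_df, rng, n_genes=1)
        nf = tmm_factors(counts)
        y = np.concatenate([counts.iloc[0].to_numpy(dtype=float),
                            counts.iloc[1].to_numpy(dtype=float)])
        t1 = lrt_interaction_test(y, small_design_df, nf, 0.1)
        perm = ["B2", "A1", "B3", "A3", "A2", "B1"]
        ddf2 = small_design_df.loc[perm]
        counts2 = counts[perm]
        nf2 = tmm_factors(counts2)
        y2 = np.concatenate([counts2.iloc[0].to_numpy(dtype=float),
                             counts2.iloc[1].to_numpy(dtype=float)])
        t2 = lrt_interaction_test(y2, ddf2, nf2, 0.1)
        assert t1.lrt_statistic == pytest.approx(t2.lrt_statistic, abs=1e-6)

    def test_label_swap_antisymmetry(self, small_design_df):
        """Swapping P/D labels negates the ratio change and preserves the
        statistic."""
        rng = np.random.default_rng(17)
        counts = null_counts(small_design_df, rng, n_genes=1)
        nf = tmm_factors(counts)
        p = counts.iloc[0].astype(float)
        d = counts.iloc[1].astype(float)
        y = np.concatenate([p, d])
        y_sw = np.concatenate([d, p])
        t1 = lrt_interaction_test(y, small_design_df, nf, 0.1)
        t2 = lrt_interaction_test(y_sw, small_design_df, nf, 0.1)
        assert t1.lrt_statistic == pytest.approx(t2.lrt_statistic, abs=1e-5)
        r1 = log2_ratio_change(p, d, small_design_df, nf)
        r2 = log2_ratio_change(d, p, small_design_df, nf)
        assert r1 == pytest.approx(-r2, abs=1e-10)


class TestQvalues:
    def test_bh_closed_form(self):
        q = estimate_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, 0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(estimate_qvalues([1.0] * 5, method="bh"), 1.0)

    def test_storey_pi0_near_one_on_uniform(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=10_000)
        q = estimate_qvalues(p, method="storey")
        # q ~= pi0 * BH-q; on uniform p the max q approximates pi0
        assert 0.9 <= q.max() <= 1.0

    def test_small_m_falls_back_to_bh(self):
        p = np.linspace(0.01, 0.9, 50)
        np.testing.assert_allclose(
            estimate_qvalues(p, method="storey"),
            estimate_qvalues(p, method="bh"),
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            estimate_qvalues([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, pvals):
        q = estimate_qvalues(pvals, method="bh")
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSignificanceRule:
    def _test(self, q, ratio):
        t = ShiftTest("g", 1.0, 0.01, 0.5, math.log2(ratio), q_value=q)
        call_significant_shifts([t])
        return t.significant

    def test_joint_rule_pinned(self):
        """Significance needs both FDR < 0.05 and a >2-fold ratio change."""
        assert self._test(q=0.01, ratio=3.93)
        assert not self._test(q=0.20, ratio=10.0)  # fails FDR gate
        assert not self._test(q=0.001, ratio=1.5)  # fails fold gate
        assert not self._test(q=0.01, ratio=2.0)   # boundary: strictly greater

    def test_ratio_change_pseudocount_arithmetic(self, small_design_df):
        """Pooled A: P=50,D=50; B: P=80,D=20 with pseudo-count 0.5 gives
        (80.5/20.5)/(50.5/50.5) ~= 3.93."""
        nf = tmm_factors(pd.DataFrame(
            {s: [100, 100] for s in small_design_df.index},
            index=["x|P", "x|D"]))
        nf.factors[:] = 1.0
        nf.library_sizes[:] = 1.0  # unit scaling: pooled counts are raw
        p = pd.Series([50, 0, 0, 80, 0, 0], index=small_design_df.index, dtype=float)
        d = pd.Series([50, 0, 0, 20, 0, 0], index=small_design_df.index, dtype=float)
        lrc = log2_ratio_change(p, d, small_design_df, nf, pseudo=0.5)
        assert 2**lrc == pytest.approx((80.5 / 20.5) / (50.5 / 50.5), rel=1e-12)
        assert 2**lrc == pytest.approx(3.927, abs=5e-3)


class TestDriver:
    def test_null_and_shifted_separation(self, small_design_df):
        cfg = SimulationConfig(n_genes=60, n_shifted=10, n_motif_candidates=0,
                               delta_log2=3.0, mean_gene_count=400.0,
                               dispersion=0.05, seed=21)
        counts, truth = simulate_counts(cfg)
        ddf = design_frame(make_design(cfg))
        res = run_apa_shifts(counts, ddf, dispersion="common")
        shifted = truth.index[truth["is_shifted"]]
        nulls = truth.index[~truth["is_shifted"]]
        assert res.loc[shifted, "significant"].mean() >= 0.8
        assert res.loc[nulls, "significant"].mean() <= 0.05
        # directions follow the sign of the planted effect
        called = res.loc[shifted][res.loc[shifted, "significant"]]
        expected = truth.loc[called.index, "delta_log2"].gt(0).map(
            {True: "proximal", False: "distal"})
        assert (called["direction"] == expected).all()
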