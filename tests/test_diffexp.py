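"""Moderated DE: transform, weights, duplicate correlation, GLS fit, calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncstrat.diffexp import (DEModel, call_differential, detected_genes,
                              duplicate_correlation, fit_moderated, logcpm,
                              voom_weights)
from lncstrat.synthetic import TruthSpec, make_annotation, simulate_cohort


def _counts_df(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestLogCPM:
    def test_closed_form_zero_count(self):
        c = _counts_df([[0], [999_999]])
        got = logcpm(c).iloc[0, 0]
        assert got == pytest.approx(np.log2(0.5 / 1e6 * 1e6), abs=1e-9)

    def test_scale_invariance_up_to_offset(self, rng):
        # the +0.5 pseudo-count breaks exact invariance at low counts, so
        # check in the high-count regime where the transform is pure scaling
        c = _counts_df(rng.poisson(100_000, size=(100, 4)))
        doubled = c.copy()
        doubled["s0"] *= 2
        a = logcpm(c)["s0"]
        b = logcpm(doubled)["s0"]
        # doubling every count in a sample moves each gene by ~the same offset
        shifts = (b - a).to_numpy()
        assert np.ptp(shifts) < 1e-6

    def test_monotone_within_sample(self):
        c = _counts_df([[10], [20], [5]])
        y = logcpm(c)
        assert y.iloc[1, 0] > y.iloc[0, 0] > y.iloc[2, 0]

    def test_zero_library_names_sample(self):
        c = _counts_df([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="s0"):
            logcpm(c)


class TestVoomWeights:
    def test_homoscedastic_data_gives_flat_weights(self, rng):
        y = rng.normal(5.0, 1.0, size=(300, 12))
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        w = voom_weights(y, X)
        assert np.isfinite(w).all() and (w > 0).all()
        assert w.std() / w.mean() < 0.2

    def test_planted_trend_weights_increase_with_abundance(self, rng):
        means = np.linspace(2, 10, 400)
        sd = 2.0 / np.sqrt(means)
        y = means[:, None] + rng.normal(0, 1, (400, 12)) * sd[:, None]
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        w = voom_weights(y, X)
        rho = stats.spearmanr(means, w.mean(axis=1)).statistic
        assert rho > 0.8

    def test_too_few_genes_rejected(self, rng):
        y = rng.normal(size=(5, 8))
        with pytest.raises(ValueError, match="10 genes"):
            voom_weights(y, np.ones((8, 1)))


class TestDuplicateCorrelation:
    def _design(self, n):
        return np.column_stack([np.ones(n), np.tile([0, 1], n // 2)])

    def test_null_patient_effect_near_zero(self, rng):
        G, n_pat = 300, 20
        block = np.repeat(np.arange(n_pat), 2)
        y = rng.normal(0, 0.3, (G, 2 * n_pat))
        rho = duplicate_correlation(y, np.ones_like(y), self._design(2 * n_pat), block)
        assert abs(rho) < 0.1

    def test_strong_patient_effect_recovered(self, rng):
        G, n_pat = 300, 20
        block = np.repeat(np.arange(n_pat), 2)
        pe = rng.normal(0, 1.0, (G, n_pat))
        y = pe[:, block] + rng.normal(0, 0.3, (G, 2 * n_pat))
        rho = duplicate_correlation(y, np.ones_like(y), self._design(2 * n_pat), block)
        assert rho > 0.4

    def test_all_singleton_blocks_rejected(self, rng):
        y = rng.normal(size=(50, 8))
        with pytest.raises(ValueError, match="without blocking"):
            duplicate_correlation(y, np.ones_like(y), self._design(8), np.arange(8))

    def test_adding_duplicate_sample_never_decreases_rho(self, rng):
        G, n_pat = 200, 10
        block = np.repeat(np.arange(n_pat), 2)
        pe = rng.normal(0, 0.5, (G, n_pat))
        y = pe[:, block] + rng.normal(0, 0.5, (G, 2 * n_pat))
        X = self._design(2 * n_pat)
        w = np.ones_like(y)
        rho1 = duplicate_correlation(y, w, X, block)
        y2 = np.concatenate([y, y[:, :1]], axis=1)
        X2 = np.vstack([X, X[0]])
        block2 = np.append(block, block[0])
        rho2 = duplicate_correlation(y2, np.ones_like(y2), X2, block2)
        assert rho2 >= rho1


class TestFitModerated:
    def test_hand_example_matches_two_sample_t(self, rng):
        # one gene, two groups of 3, unweighted, rho=0, prior_df=0:
        # the GLS t must equal the textbook pooled two-sample t
        y = np.array([[3.1, 2.7, 3.4, 5.0, 5.3, 4.6]])
        g = np.array([0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), g])
        tab = fit_moderated(y, np.ones_like(y), X, [0, 1], prior_df=0)
        a, b = y[0, :3], y[0, 3:]
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_ref = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert tab["t"].iloc[0] == pytest.approx(t_ref, abs=1e-8)
        assert tab["log2fc"].iloc[0] == pytest.approx(b.mean() - a.mean(), abs=1e-12)
        p_ref = 2 * stats.t.sf(abs(t_ref), 4)
        assert tab["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10)

    def test_prior_df_zero_is_ordinary_gls(self, rng):
        y = rng.normal(size=(50, 10))
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        block = np.repeat(np.arange(5), 2)
        t0 = fit_moderated(y, np.ones_like(y), X, [0, 1], block=block,
                           consensus_rho=0.3, prior_df=0)
        assert np.allclose(t0["s2_post"], t0["s2"], atol=1e-12)

    def test_label_swap_negates_lfc_preserves_p(self, rng):
        y = rng.normal(size=(80, 12))
        g = np.repeat([0, 1], 6)
        X1 = np.column_stack([np.ones(12), g])
        X2 = np.column_stack([np.ones(12), 1 - g])
        w = np.ones_like(y)
        t1 = fit_moderated(y, w, X1, [0, 1])
        t2 = fit_moderated(y, w, X2, [0, 1])
        assert np.allclose(t1["log2fc"], -t2["log2fc"], atol=1e-9)
        assert np.allclose(t1["p"], t2["p"], atol=1e-9)

    def test_variance_shrinkage_moves_toward_prior(self, rng):
        y = rng.normal(size=(200, 10)) * rng.uniform(0.5, 2.0, size=(200, 1))
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        tab = fit_moderated(y, np.ones_like(y), X, [0, 1])
        from lncstrat.diffexp import _squeeze_var

        d0, s0sq, _ = _squeeze_var(tab["s2"].to_numpy(), tab.attrs["df_resid"])
        assert np.all(np.abs(tab["s2_post"] - s0sq) <= np.abs(tab["s2"] - s0sq) + 1e-12)

    def test_invalid_rho_rejected(self, rng):
        y = rng.normal(size=(20, 6))
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        with pytest.raises(ValueError, match="consensus_rho"):
            fit_moderated(y, np.ones_like(y), X, [0, 1], consensus_rho=1.5)

    def test_null_moderated_pvalues_uniform(self, rng):
        y = rng.normal(size=(2000, 16))
        X = np.column_stack([np.ones(16), np.repeat([0, 1], 8)])
        w = voom_weights(y, X)
        tab = fit_moderated(y, w, X, [0, 1])
        assert stats.kstest(tab["p"], "uniform").statistic < 0.05


class TestCallDifferential:
    def _tab(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p"])

    def test_threshold_arithmetic(self):
        tab = self._tab([("a", 0.60, 0.005), ("b", 0.50, 0.005),
                         ("c", 2.0, 0.011), ("d", -0.60, 0.009)])
        out = call_differential(tab)
        assert list(out["gene_id"]) == ["a", "d"]

    def test_empty_input(self):
        out = call_differential(self._tab([]))
        assert out.empty


class TestDEModelCohort:
    def test_detection_filter_drops_undetected(self):
        counts = _counts_df([[0, 0, 0, 0], [5, 1, 2, 1], [100, 90, 80, 110]])
        fpkm = counts / 1.0
        kept = detected_genes(counts, fpkm, min_total=10)
        assert list(kept) == ["g2"]

    def test_relapse_mode_requires_both_timepoints(self):
        spec = TruthSpec(n_patients=8, paired_fraction=0.0,
                         subtype_labels=(("A", 4), ("B", 4)), n_lnc=15, n_pc=30,
                         seed=2)
        cohort = simulate_cohort(spec, make_annotation(spec))
        sub = cohort.samples.copy()
        sub.loc[sub["subtype"] == "A", "timepoint"] = "ID"
        with pytest.raises(ValueError, match="timepoint"):
            DEModel.from_cohort(cohort.counts, sub, "relapse", "A")

    def test_rank_deficient_design_rejected(self):
        counts = _counts_df(np.full((12, 4), 10))
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            DEModel(counts, X, [0, 1])

    def test_planted_effect_estimated_on_log2_scale(self):
        spec = TruthSpec(n_patients=12, paired_fraction=1.0,
                         subtype_labels=(("A", 6), ("B", 6)), n_lnc=100, n_pc=100,
                         planted_subtype_de=(("PC0010", "A", 2.0),
                                             ("PC0011", "A", -1.5)), seed=4)
        cohort = simulate_cohort(spec, make_annotation(spec))
        res = DEModel.from_cohort(cohort.counts, cohort.samples, "subtype", "A",
                                  fpkm=cohort.fpkm).fit()
        tab = res.table.set_index("gene_id")
        assert tab.loc["PC0010", "log2fc"] == pytest.approx(2.0, abs=0.6)
        assert tab.loc["PC0011", "log2fc"] == pytest.approx(-1.5, abs=0.6)
        called = set(res.called()["gene_id"])
        assert {"PC0010", "PC0011"} <= called

    def test_summary_mentions_rho_and_counts(self, demo_setup):
        res = demo_setup["bundle"]["de"]["DUX4"]
        s = res.summary()
        assert "consensus rho" in s and "genes tested" in s
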