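import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import sleepwave as sw

from conftest import make_dataset


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        # column-sort, row-mean, re-rank: both columns become (1.5, 3.5)
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]], ["A", "B"])
        out = sw.quantile_normalize(ds)
        np.testing.assert_allclose(out.matrix.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        ds = make_dataset([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]], ["A", "B"])
        out = sw.quantile_normalize(ds)
        pd.testing.assert_frame_equal(out.matrix, ds.matrix)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(7, 1, (40, 5)), ["A"] * 3 + ["B"] * 2)
        once = sw.quantile_normalize(ds)
        twice = sw.quantile_normalize(once)
        np.testing.assert_allclose(
            twice.matrix.to_numpy(), once.matrix.to_numpy(), atol=1e-12
        )

    def test_ties_get_mean_of_tied_reference_values(self):
        ds = make_dataset([[1.0, 1.0], [1.0, 2.0], [2.0, 3.0]], ["A", "B"])
        out = sw.quantile_normalize(ds)
        ref = np.sort(ds.matrix.to_numpy(), axis=0).mean(axis=1)  # (1, 1.5, 2.5)
        # first column ties at rank 1.5 -> mean of ref[0], ref[1]
        assert out.matrix.iloc[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.matrix.iloc[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    @given(st.integers(0, 2**31 - 1))
    def test_columns_are_permutations_of_common_vector(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_dataset(rng.normal(0, 1, (15, 4)), ["A", "A", "B", "B"])
        out = sw.quantile_normalize(ds).matrix.to_numpy()
        first = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), first, atol=1e-12)

    def test_single_sample_errors(self):
        ds = make_dataset([[1.0], [2.0]], ["A"])
        with pytest.raises(ValueError, match="2 samples"):
            sw.quantile_normalize(ds)


class TestRUVFit:
    def test_k_zero_is_identity(self, sim_default):
        _, ds, _, controls = sim_default
        for variant in ("replicate_samples", "negative_controls"):
            fit = sw.ruv_fit(
                ds, k=0, variant=variant, control_ids=sorted(controls.negative)
            )
            pd.testing.assert_frame_equal(fit.adjusted.matrix, ds.matrix)

    def test_replicate_variant_recovers_true_factor_span(self):
        config = sw.SimulationConfig(n_genes=2000, seed=29, k_true=2)
        ds, truth, controls = sw.generate(config)
        fit = sw.ruv_fit(
            ds, k=2, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        qh, _ = np.linalg.qr(fit.W.to_numpy())
        qt, _ = np.linalg.qr(truth.W.to_numpy())
        canonical = np.linalg.svd(qh.T @ qt, compute_uv=False)
        assert canonical.min() > 0.9

    def test_negative_control_variant_recovers_true_factor_span(self):
        config = sw.SimulationConfig(n_genes=2000, seed=29, k_true=2)
        ds, truth, controls = sw.generate(config)
        fit = sw.ruv_fit(
            ds, k=2, variant="negative_controls",
            control_ids=sorted(controls.negative),
        )
        qh, _ = np.linalg.qr(fit.W.to_numpy())
        qt, _ = np.linalg.qr(truth.W.to_numpy())
        canonical = np.linalg.svd(qh.T @ qt, compute_uv=False)
        assert canonical.min() > 0.9

    def test_null_pvalues_uniform_after_adjustment(self, sim_default):
        _, ds, truth, controls = sim_default
        fit = sw.ruv_fit(
            ds, k=3, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        de = sw.fit_moderated(ds, sw.PAPER_CONTRASTS[0], covariates=fit.W.to_numpy())
        null_genes = truth.genes.index[truth.genes["cls"] == "null"]
        ks = stats.kstest(de.table.loc[null_genes, "p"].to_numpy(), "uniform").statistic
        assert ks < 0.05

    def test_control_residual_variance_non_increasing_in_k(self, sim_default):
        _, ds, _, controls = sim_default
        neg = sorted(controls.negative)
        prev = np.inf
        for k in range(5):
            fit = sw.ruv_fit(ds, k=k, variant="replicate_samples", control_ids=neg)
            ctrl = fit.adjusted.matrix.loc[neg].to_numpy()
            resid_var = (ctrl - ctrl.mean(axis=1, keepdims=True)).var()
            assert resid_var <= prev + 1e-9
            prev = resid_var

    def test_treatment_signal_preserved_noise_free_orthogonal_w(self):
        # noise-free data where the factor activities are orthogonal to the
        # group structure: adjustment must leave group differences intact
        config = sw.SimulationConfig(
            n_genes=800, seed=31, sigma_noise=0.0, k_true=0, batch_strength=0.0,
            frac_circadian=0.0, n_negative_controls=200, n_positive_controls=10,
        )
        ds, truth, controls = sw.generate(config)
        rng = np.random.default_rng(31)
        X = pd.get_dummies(ds.design["group"], dtype=float).to_numpy()
        W = rng.standard_normal((ds.n_samples, 2))
        W -= X @ np.linalg.lstsq(X, W, rcond=None)[0]  # orthogonalize vs groups
        alpha = rng.standard_normal((2, ds.n_features))
        noisy = ds.with_matrix(ds.matrix + (W @ alpha).T)
        fit = sw.ruv_fit(
            noisy, k=2, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        groups = ds.design["group"]
        affected = truth.genes["cls"].isin(["fast", "slow"])
        strong = affected & (truth.genes["logfc0"].abs() > 0.5)

        def sd_effect(matrix):
            sd = matrix.loc[:, groups[groups == "SD"].index].mean(axis=1)
            cc = matrix.loc[:, groups[groups == "CC6"].index].mean(axis=1)
            return (sd - cc)[strong]

        after = sd_effect(fit.adjusted.matrix)
        rel = np.abs(after - truth.beta.loc[strong, "SD"]) / truth.beta.loc[strong, "SD"].abs()
        assert rel.max() < 0.01

    def test_k_exceeding_rank_errors(self):
        ds = make_dataset(np.arange(12.0).reshape(4, 3), ["A", "A", "B"])
        with pytest.raises(ValueError, match="maximum attainable"):
            sw.ruv_fit(ds, k=3, variant="negative_controls", control_ids=["G0", "G1", "G2", "G3"])

    def test_unknown_variant_errors(self, sim_default):
        _, ds, _, _ = sim_default
        with pytest.raises(ValueError, match="variant"):
            sw.ruv_fit(ds, k=1, variant="bogus")


class TestScanK:
    def test_recommends_true_k(self):
        config = sw.SimulationConfig(n_genes=4000, seed=37, k_true=3, batch_strength=1.5)
        ds, truth, controls = sw.generate(config)
        scan = sw.scan_k(
            ds, controls, list(sw.PAPER_CONTRASTS[:2]), k_max=6,
            control_ids=sorted(controls.negative),
        )
        assert scan.recommended_k == 3

    def test_recommends_zero_without_unwanted_variation(self):
        config = sw.SimulationConfig(
            n_genes=3000, seed=38, k_true=0, batch_strength=0.0,
        )
        ds, truth, controls = sw.generate(config)
        scan = sw.scan_k(
            ds, controls, list(sw.PAPER_CONTRASTS[:2]), k_max=3,
            control_ids=sorted(controls.negative),
        )
        assert scan.recommended_k == 0

    def test_k_zero_row_matches_unadjusted_analysis(self, sim_default):
        _, ds, _, controls = sim_default
        contrasts = [sw.PAPER_CONTRASTS[0]]
        scan = sw.scan_k(
            ds, controls, contrasts, k_max=1,
            control_ids=sorted(controls.negative),
        )
        de = sw.fit_moderated(ds, contrasts[0])
        pos = [g for g in controls.positive[contrasts[0].name] if g in de.table.index]
        recall = (de.table.loc[pos, "fdr"] < 0.01).mean()
        assert scan.table.loc[0, "positive_recall"] == pytest.approx(recall)
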