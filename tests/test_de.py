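import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import sleepwave as sw
from sleepwave.de import LinearFit, trigamma_inverse

from conftest import make_dataset


def brute_force_pooled_t(values, n_a):
    """Two-sample t with pooled variance, computed longhand per gene."""
    a, b = values[:, :n_a], values[:, n_a:]
    na, nb = a.shape[1], b.shape[1]
    diff = b.mean(axis=1) - a.mean(axis=1)
    pooled = (
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (na + nb - 2)
    return diff / np.sqrt(pooled * (1 / na + 1 / nb))


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(41)
        values = rng.normal(7, 1, (50, 10))
        ds = make_dataset(values, ["A"] * 5 + ["B"] * 5)
        de = sw.fit_moderated(ds, sw.Contrast("c", "B", "A"), prior_df=0)
        expected = brute_force_pooled_t(values, 5)
        np.testing.assert_allclose(de.table["t"].to_numpy(), expected, atol=1e-10)

    def test_d0_infinite_shrinks_all_variances_to_prior(self):
        rng = np.random.default_rng(42)
        ds = make_dataset(rng.normal(7, 1, (40, 8)), ["A"] * 4 + ["B"] * 4)
        de = sw.fit_moderated(ds, sw.Contrast("c", "B", "A"), prior_df=np.inf)
        assert np.allclose(de.posterior_var, de.prior_var)

    def test_constant_gene_has_zero_logfc(self):
        rng = np.random.default_rng(43)
        values = rng.normal(7, 1, (20, 8))
        values[0] = 5.0
        ds = make_dataset(values, ["A"] * 4 + ["B"] * 4)
        de = sw.fit_moderated(ds, sw.Contrast("c", "B", "A"))
        assert de.table["logFC"].iloc[0] == 0.0

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(44)
        sig2 = 0.05 * 4 / rng.chisquare(4, 200)
        values = rng.normal(0, 1, (200, 10)) * np.sqrt(sig2)[:, None] + 7
        ds = make_dataset(values, ["A"] * 5 + ["B"] * 5)
        de = sw.fit_moderated(ds, sw.Contrast("c", "B", "A"))
        fit = LinearFit(ds)
        lo = np.minimum(fit.s2, de.prior_var)
        hi = np.maximum(fit.s2, de.prior_var)
        assert ((de.posterior_var >= lo - 1e-12) & (de.posterior_var <= hi + 1e-12)).all()

    def test_saturated_design_errors(self):
        ds = make_dataset(np.ones((3, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            sw.fit_moderated(ds, sw.Contrast("c", "B", "A"))

    def test_missing_group_errors(self):
        ds = make_dataset(np.ones((3, 4)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="'C'"):
            sw.fit_moderated(ds, sw.Contrast("c", "C", "A"))

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in (1e-3, 0.1, 1.0, 10.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_matches_limma_on_heteroscedastic_fixture(self, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation."""
        rng = np.random.default_rng(7)
        sig2 = 0.04 * 5 / rng.chisquare(5, 300)
        values = rng.normal(0, 1, (300, 12)) * np.sqrt(sig2)[:, None] + 7
        values[:50, 6:] += rng.uniform(0.5, 1.5, 50)[:, None]
        ds = make_dataset(values, ["A"] * 6 + ["B"] * 6)
        ds.matrix.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            Y <- as.matrix(read.delim("mat.tsv", row.names=1))
            groups <- factor(rep(c("A","B"), each=6), levels=c("A","B"))
            design <- model.matrix(~0+groups)
            colnames(design) <- c("A","B")
            fit <- eBayes(contrasts.fit(lmFit(Y, design),
                                        makeContrasts(B-A, levels=design)))
            out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior)
            write.table(out, "limma.tsv", sep="\\t", quote=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True
        )
        lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        de = sw.fit_moderated(ds, sw.Contrast("c", "B", "A"))
        assert de.prior_df == pytest.approx(lim["d0"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(de.table["t"].to_numpy(), lim["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(de.table["p"].to_numpy(), lim["p"].to_numpy(), atol=1e-8)


class TestBHAdjust:
    def test_hand_computed_example(self):
        # p*m/i with the monotone step-up correction
        np.testing.assert_allclose(
            sw.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert np.all(sw.bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_single_p(self):
        assert sw.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sw.bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            sw.bh_adjust([-0.1])

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(sw.bh_adjust(p)[perm], sw.bh_adjust(p[perm]))


class TestEvaluate:
    def test_full_recall_when_all_positives_significant(self, sim_default):
        _, ds, truth, controls = sim_default
        fit = sw.ruv_fit(
            ds, k=3, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        de = sw.fit_moderated(ds, sw.PAPER_CONTRASTS[0], covariates=fit.W.to_numpy())
        diag = sw.evaluate(de, controls)
        assert diag.recall == 1.0
        assert diag.n_up > 0 and diag.n_down > 0
        assert diag.hist_counts.sum() == ds.n_features

    def test_recall_undefined_without_positives(self, sim_null):
        _, ds, _, _ = sim_null
        de = sw.fit_moderated(ds, sw.PAPER_CONTRASTS[0])
        with pytest.warns(UserWarning, match="no positive controls"):
            diag = sw.evaluate(de, sw.ControlGeneSets())
        assert np.isnan(diag.recall)

    def test_uniform_pvalues_give_small_ks(self, sim_null):
        _, ds, _, _ = sim_null
        de = sw.fit_moderated(ds, sw.PAPER_CONTRASTS[0])
        diag = sw.evaluate(de, sw.ControlGeneSets())
        assert diag.ks_statistic < 0.05


class TestCircadianContrasts:
    def test_sensitivity_and_specificity(self, sim_default):
        _, ds, truth, controls = sim_default
        fit = sw.ruv_fit(
            ds, k=3, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        flags = sw.circadian_contrasts(ds, covariates=fit.W.to_numpy())
        circ = truth.genes["is_circadian"]
        sensitivity = flags[circ].mean()
        false_rate = flags[~circ & (truth.genes["cls"] == "null")].mean()
        assert sensitivity >= 0.9
        assert false_rate <= 0.01

    def test_missing_control_groups_warn_and_return_empty(self):
        ds = make_dataset(np.random.default_rng(0).normal(7, 1, (10, 4)),
                          ["SD", "SD", "CC6", "CC6"])
        with pytest.warns(UserWarning, match="circadian"):
            flags = sw.circadian_contrasts(ds)
        assert not flags.any()
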