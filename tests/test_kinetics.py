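import numpy as np
import pandas as pd
import pytest

import sleepwave as sw
from sleepwave.de import Contrast, DEResult
from sleepwave.kinetics import ClusterAssignment, TrajectoryMatrix

TIMES = np.array([0.0, 1.0, 2.0, 3.0, 6.0])


def fake_de(group, logfc, fdr):
    """Wrap per-gene logFC/FDR vectors as a DEResult for one contrast."""
    genes = [f"G{i}" for i in range(len(logfc))]
    table = pd.DataFrame(
        {"logFC": logfc, "t": 0.0, "p": fdr, "fdr": fdr}, index=genes
    )
    return DEResult(
        contrast=Contrast(group, group, "CC"), table=table,
        df_residual=10.0, prior_df=4.0, prior_var=0.04,
    )


def de_set(logfc_by_time, fdr_by_time):
    groups = ["SD", "RS1", "RS2", "RS3", "RS6"]
    return {
        g: fake_de(g, logfc_by_time[:, j], fdr_by_time[:, j])
        for j, g in enumerate(groups)
    }


def make_tm(logfc, sig=None):
    genes = [f"G{i}" for i in range(len(logfc))]
    logfc = pd.DataFrame(logfc, index=genes, columns=TIMES)
    if sig is None:
        sig = pd.DataFrame(True, index=genes, columns=TIMES)
    else:
        sig = pd.DataFrame(sig, index=genes, columns=TIMES)
    return TrajectoryMatrix(
        logfc=logfc, significant=sig, times=TIMES,
        circadian=pd.Series(False, index=genes), fdr=0.01,
    )


class TestBuildTrajectories:
    def test_gene_significant_only_at_sd_is_included(self):
        logfc = np.array([[1.0, 0.5, 0.2, 0.1, 0.0], [0.1, 0.1, 0.1, 0.1, 0.1]])
        fdr = np.array([[0.001, 0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5, 0.5]])
        tm = sw.build_trajectories(de_set(logfc, fdr))
        assert list(tm.logfc.index) == ["G0"]
        assert tm.logfc.shape == (1, 5)
        np.testing.assert_allclose(tm.logfc.loc["G0"].to_numpy(), logfc[0])

    def test_no_significant_genes_warns(self):
        logfc = np.zeros((3, 5))
        fdr = np.full((3, 5), 0.9)
        with pytest.warns(UserWarning, match="no genes significant"):
            tm = sw.build_trajectories(de_set(logfc, fdr))
        assert len(tm.logfc) == 0

    def test_missing_contrast_errors(self):
        logfc = np.zeros((2, 5))
        fdr = np.full((2, 5), 0.001)
        des = de_set(logfc, fdr)
        del des["RS2"]
        with pytest.raises(ValueError, match="RS2"):
            sw.build_trajectories(des)

    def test_recovers_most_true_affected_genes(self, sim_default):
        _, ds, truth, controls = sim_default
        fit = sw.ruv_fit(
            ds, k=3, variant="replicate_samples",
            control_ids=sorted(controls.negative),
        )
        des = sw.fit_contrasts(ds, list(sw.PAPER_CONTRASTS), covariates=fit.W.to_numpy())
        tm = sw.build_trajectories({c.treatment: d for c, d in zip(sw.PAPER_CONTRASTS, des)})
        affected = set(truth.genes.index[truth.genes["cls"].isin(["fast", "slow"])])
        assert len(affected & set(tm.logfc.index)) / len(affected) >= 0.95


class TestClusterTrajectories:
    def test_two_archetypes_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        fast = 1.5 * np.exp(-TIMES / 1.0)
        late = np.array([0.0, 0.0, 0.0, 0.0, 1.5])
        logfc = np.vstack(
            [fast + rng.normal(0, 0.02, 5) for _ in range(20)]
            + [late + rng.normal(0, 0.02, 5) for _ in range(20)]
        )
        tm = make_tm(logfc)
        ca = sw.cluster_trajectories(tm, n_clusters=2)
        truth_labels = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth_labels, ca.labels.to_numpy()) == 1.0

    def test_duplicate_trajectories_co_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (6, 5))
        logfc = np.vstack([base, base[0]])  # G6 duplicates G0
        tm = make_tm(logfc)
        ca = sw.cluster_trajectories(tm, n_clusters=3)
        assert ca.labels["G6"] == ca.labels["G0"]

    def test_n_clusters_equal_genes_gives_singletons(self):
        rng = np.random.default_rng(2)
        tm = make_tm(rng.normal(0, 1, (5, 5)))
        ca = sw.cluster_trajectories(tm, n_clusters=5)
        assert sorted(ca.labels.value_counts()) == [1] * 5

    def test_too_few_clusters_errors(self):
        tm = make_tm(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="n_clusters"):
            sw.cluster_trajectories(tm, n_clusters=1)

    def test_more_clusters_than_genes_errors(self):
        tm = make_tm(np.ones((3, 5)))
        with pytest.raises(ValueError, match="3 genes"):
            sw.cluster_trajectories(tm, n_clusters=4)


class TestClassifyClusters:
    def _single_cluster(self, mean_traj, sig_rows):
        n = len(sig_rows)
        logfc = np.tile(np.asarray(mean_traj), (n, 1))
        tm = make_tm(logfc, sig=np.asarray(sig_rows))
        labels = pd.Series(1, index=tm.logfc.index)
        ca = ClusterAssignment(
            labels=labels,
            means=tm.logfc.groupby(labels).mean(),
            sds=tm.logfc.groupby(labels).std(ddof=0),
        )
        return sw.classify_clusters(ca, tm)[1]

    def test_fast_cluster(self):
        # recovered by t=3 (5% of initial), significance lost at t=2
        sig = [[True, True, False, False, False]] * 4
        assert self._single_cluster([1.0, 0.4, 0.2, 0.05, 0.0], sig) == "fast"

    def test_slow_cluster(self):
        sig = [[True, True, True, True, False]] * 4
        assert self._single_cluster([1.0, 0.95, 0.9, 0.8, 0.1], sig) == "slow"

    def test_late_induced_cluster(self):
        sig = [[False, False, False, False, True]] * 4
        assert self._single_cluster([0.0, 0.05, 0.0, 0.1, 0.9], sig) == "late_induced"

    def test_sign_flip_invariance(self):
        sig = [[True, True, False, False, False]] * 4
        up = self._single_cluster([1.0, 0.4, 0.2, 0.05, 0.0], sig)
        down = self._single_cluster([-1.0, -0.4, -0.2, -0.05, 0.0], sig)
        assert up == down == "fast"


class TestFitDecay:
    def test_exact_recovery_from_noise_free_equation(self):
        y = 0.0 + (1.0 - 0.0) * np.exp(-TIMES / 2.0)
        fit = sw.fit_decay(y, TIMES, la=0.0)
        assert fit.converged
        assert fit.tau == pytest.approx(2.0, abs=1e-6)

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(55)
        y = 1.2 * np.exp(-TIMES / 1.7) + rng.normal(0, 0.05, 5)
        fit = sw.fit_decay(y, TIMES)
        la, y0 = min(y), y[0]
        taus = np.arange(0.1, 12.0, 1e-3)
        rss = [
            (((y - (la + (y0 - la) * np.exp(-TIMES / t)))) ** 2).sum() for t in taus
        ]
        best = taus[int(np.argmin(rss))]
        assert fit.tau == pytest.approx(best, abs=1e-3)

    @pytest.mark.parametrize("c", [0.25, 1.0, 3.7])
    def test_scale_equivariance(self, c):
        y = np.array([1.0, 0.52, 0.28, 0.16, 0.03])
        base = sw.fit_decay(y, TIMES)
        scaled = sw.fit_decay(c * y, TIMES)
        assert scaled.tau == pytest.approx(base.tau, rel=1e-6)
        assert scaled.logfc0 == pytest.approx(c * base.logfc0)
        assert scaled.la == pytest.approx(c * base.la)

    def test_downregulated_cluster_negated_before_fitting(self):
        y = np.exp(-TIMES / 2.0)
        up = sw.fit_decay(y, TIMES, la=0.0)
        down = sw.fit_decay(-y, TIMES, la=0.0)
        assert down.orientation == -1
        assert down.tau == pytest.approx(up.tau, abs=1e-9)
        assert down.logfc0 == pytest.approx(-1.0)

    def test_flat_trajectory_degenerate(self):
        fit = sw.fit_decay(np.full(5, 0.7), TIMES)
        assert fit.degenerate and not fit.converged
        assert np.isnan(fit.tau)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="3 time points"):
            sw.fit_decay([1.0, 0.5], [0.0, 1.0])


class TestSummarize:
    def test_class_average(self):
        fits = {
            1: sw.DecayFit(1.0, 0.0, 1.0, 0.0, True),
            2: sw.DecayFit(1.0, 0.0, 1.6, 0.0, True),
            3: sw.DecayFit(1.0, 0.0, 4.0, 0.0, True),
        }
        classes = {1: "fast", 2: "fast", 3: "slow"}
        out = sw.summarize_kinetics(fits, classes)
        assert out["fast"] == pytest.approx(1.3)
        assert out["slow"] == pytest.approx(4.0)

    def test_degenerate_fit_excluded(self):
        fits = {
            1: sw.DecayFit(1.0, 0.0, 1.0, 0.0, True),
            2: sw.DecayFit(0.0, 0.0, float("nan"), float("nan"), False, degenerate=True),
        }
        out = sw.summarize_kinetics(fits, {1: "fast", 2: "fast"})
        assert out["fast"] == pytest.approx(1.0)

    def test_min_size_filter(self):
        fits = {
            1: sw.DecayFit(1.0, 0.0, 1.2, 0.0, True),
            2: sw.DecayFit(1.0, 0.0, 9.0, 0.0, True),
        }
        classes = {1: "fast", 2: "fast"}
        out = sw.summarize_kinetics(fits, classes, sizes={1: 100, 2: 3}, min_size=25)
        assert out["fast"] == pytest.approx(1.2)

    def test_no_converged_fits_warns(self):
        fits = {1: sw.DecayFit(0.0, 0.0, float("nan"), float("nan"), False, degenerate=True)}
        with pytest.warns(UserWarning, match="no converged"):
            out = sw.summarize_kinetics(fits, {1: "fast"})
        assert out == {}
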