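"""Per-gene linear models with empirical-Bayes moderated t statistics.

Each gene is fitted by ordinary least squares on a cell-means design over
the experimental groups (optionally augmented with unwanted-variation
covariates W). Residual variances s2_g with d_g degrees of freedom are
shrunk toward a common prior: the prior degrees of freedom d0 and prior
variance s0^2 are estimated by moment matching of the log sample
variances to a scaled-F / log-chi-square system (closed form via digamma
and trigamma inversion), and the posterior variance is

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g).

The moderated t is logFC / (s~_g * sqrt(v_g)) on d0 + d_g degrees of
freedom. Multiple testing is controlled with Benjamini-Hochberg FDR;
significance is called at FDR < 0.01 throughout the pipeline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ControlGeneSets, ExpressionDataset

__all__ = [
    "Contrast",
    "DEResult",
    "DiagnosticsReport",
    "PAPER_CONTRASTS",
    "fit_moderated",
    "fit_contrasts",
    "bh_adjust",
    "evaluate",
    "circadian_contrasts",
]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: treatment versus (time-matched) control."""

    name: str
    treatment: str
    control: str


#: The study's contrast set: each deprivation / recovery group against the
#: undisturbed control sacrificed at the matching time of day (the 3-hour
#: recovery group is compared against the ZT8 control, as designed).
PAPER_CONTRASTS = (
    Contrast("SD_vs_CC6", "SD", "CC6"),
    Contrast("RS1_vs_CC7", "RS1", "CC7"),
    Contrast("RS2_vs_CC8", "RS2", "CC8"),
    Contrast("RS3_vs_CC8", "RS3", "CC8"),
    Contrast("RS6_vs_CC11", "RS6", "CC11"),
)


@dataclass
class DEResult:
    """Moderated differential expression for one contrast.

    ``table`` (indexed by gene) has columns ``logFC`` (log2), ``t``
    (moderated), ``p`` (two-sided) and ``fdr``; the hyperparameters of the
    variance prior are carried for diagnostics.
    """

    contrast: Contrast
    table: pd.DataFrame
    df_residual: float
    prior_df: float
    prior_var: float
    posterior_var: np.ndarray = field(repr=False, default=None)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _estimate_prior(s2: np.ndarray, df: float):
    """Moment-matching fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0^2); d0 = inf when the log-variance spread is no larger
    than expected from sampling alone (all variances shrunk to s0^2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("not enough positive residual variances to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


class LinearFit:
    """OLS fit of all genes on one design matrix, with EB moderation."""

    def __init__(self, dataset: ExpressionDataset, covariates=None, prior_df=None):
        Y = dataset.matrix.to_numpy(float)  # genes x samples
        groups = dataset.design["group"]
        self.group_levels = list(pd.unique(groups))
        X = pd.get_dummies(groups, dtype=float)[self.group_levels].to_numpy()
        if covariates is not None:
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
            C = C - C.mean(axis=0, keepdims=True)
            X = np.hstack([X, C])
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        self.df_residual = n - rank
        if self.df_residual <= 0:
            raise ValueError("zero residual degrees of freedom: design saturates the samples")
        self.xtx_inv = np.linalg.pinv(X.T @ X)
        self.beta = Y @ X @ self.xtx_inv.T  # genes x p
        resid = Y - self.beta @ X.T
        self.s2 = (resid**2).sum(axis=1) / self.df_residual
        self.genes = dataset.matrix.index
        if prior_df is None:
            self.prior_df, self.prior_var = _estimate_prior(self.s2, self.df_residual)
        elif prior_df == 0:
            self.prior_df, self.prior_var = 0.0, float(np.median(self.s2))
        elif np.isinf(prior_df):
            self.prior_df, self.prior_var = _estimate_prior(self.s2, self.df_residual)
            self.prior_df = np.inf
        else:
            self.prior_df = float(prior_df)
            _, self.prior_var = _estimate_prior(self.s2, self.df_residual)
        if np.isinf(self.prior_df):
            self.post_var = np.full_like(self.s2, self.prior_var)
            self.df_total = 1e6 + self.df_residual
        else:
            self.post_var = (
                self.prior_df * self.prior_var + self.df_residual * self.s2
            ) / (self.prior_df + self.df_residual)
            self.df_total = self.prior_df + self.df_residual

    def contrast(self, contrast: Contrast) -> DEResult:
        for g in (contrast.treatment, contrast.control):
            if g not in self.group_levels:
                raise ValueError(f"group {g!r} not present in the design")
        c = np.zeros(self.xtx_inv.shape[0])
        c[self.group_levels.index(contrast.treatment)] = 1.0
        c[self.group_levels.index(contrast.control)] = -1.0
        logfc = self.beta @ c
        v = float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / np.sqrt(self.post_var * v)
        t = np.where(np.isfinite(t), t, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), self.df_total)
        table = pd.DataFrame(
            {"logFC": logfc, "t": t, "p": p, "fdr": bh_adjust(p)}, index=self.genes
        )
        return DEResult(
            contrast=contrast,
            table=table,
            df_residual=self.df_residual,
            prior_df=self.prior_df,
            prior_var=self.prior_var,
            posterior_var=self.post_var,
        )


def fit_moderated(
    dataset: ExpressionDataset,
    contrast: Contrast,
    covariates=None,
    prior_df=None,
) -> DEResult:
    """Fit the group design and extract one moderated contrast.

    ``covariates`` may carry estimated unwanted factors (samples x k) to
    be included in the design instead of pre-subtracting them.
    ``prior_df`` overrides the estimated prior degrees of freedom: 0 gives
    the ordinary (unmoderated) t, ``numpy.inf`` fully shrinks every
    variance to the prior.
    """
    counts = dataset.design["group"].value_counts()
    for g in (contrast.treatment, contrast.control):
        if counts.get(g, 0) < 2:
            raise ValueError(f"contrast group {g!r} has fewer than 2 samples")
    fit = LinearFit(dataset, covariates=covariates, prior_df=prior_df)
    return fit.contrast(contrast)


def fit_contrasts(dataset: ExpressionDataset, contrasts, covariates=None, prior_df=None):
    """Fit the design once and extract several contrasts."""
    fit = LinearFit(dataset, covariates=covariates, prior_df=prior_df)
    return [fit.contrast(c) for c in contrasts]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiagnosticsReport:
    """Evaluation of one DE result against control genes.

    ``recall`` is the fraction of positive controls detected at the FDR
    cutoff (NaN when no positives are present); the histogram and KS
    statistic describe the raw p-value distribution over all genes.
    """

    contrast: str
    recall: float
    n_positive: int
    n_up: int
    n_down: int
    ks_statistic: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    volcano: pd.DataFrame


def evaluate(de: DEResult, controls: ControlGeneSets, fdr: float = 0.01) -> DiagnosticsReport:
    """Positive-control recall, significance counts and p-value diagnostics."""
    table = de.table
    pos = controls.positive.get(de.contrast.name, controls.positive.get("*", set()))
    pos = [g for g in pos if g in table.index]
    if pos:
        recall = float((table.loc[pos, "fdr"] < fdr).mean())
    else:
        warnings.warn(
            f"no positive controls present for contrast {de.contrast.name}; "
            "recall undefined",
            stacklevel=2,
        )
        recall = float("nan")
    sig = table["fdr"] < fdr
    counts, edges = np.histogram(table["p"], bins=20, range=(0.0, 1.0))
    ks = stats.kstest(table["p"].to_numpy(), "uniform").statistic
    neg = set(controls.negative)
    pos_set = set(pos)
    control_flag = [
        "positive" if g in pos_set else ("negative" if g in neg else "")
        for g in table.index
    ]
    volcano = pd.DataFrame(
        {
            "logFC": table["logFC"],
            "neg_log10_p": -np.log10(np.clip(table["p"], 1e-300, None)),
            "significant": sig,
            "control": control_flag,
        },
        index=table.index,
    )
    return DiagnosticsReport(
        contrast=de.contrast.name,
        recall=recall,
        n_positive=len(pos),
        n_up=int((sig & (table["logFC"] > 0)).sum()),
        n_down=int((sig & (table["logFC"] < 0)).sum()),
        ks_statistic=float(ks),
        hist_counts=counts,
        hist_edges=edges,
        volcano=volcano,
    )


def circadian_contrasts(
    dataset: ExpressionDataset,
    control_groups=("CC0", "CC6", "CC11"),
    fdr: float = 0.01,
    covariates=None,
) -> pd.Series:
    """Flag genes with time-of-day expression differences.

    Runs moderated pairwise contrasts among the undisturbed control groups
    present in the design; a gene is flagged when any pair reaches the FDR
    cutoff. Returns an all-False flag vector (with a warning) when fewer
    than two control groups are available.
    """
    present = [g for g in control_groups if (dataset.design["group"] == g).sum() >= 2]
    flags = pd.Series(False, index=dataset.feature_ids, name="time_of_day")
    if len(present) < 2:
        warnings.warn(
            f"need >= 2 of {control_groups} to test circadian changes; "
            f"found {present} - returning empty flags",
            stacklevel=2,
        )
        return flags
    fit = LinearFit(dataset, covariates=covariates)
    for a, b in itertools.combinations(present, 2):
        de = fit.contrast(Contrast(f"{a}_vs_{b}", a, b))
        flags |= de.table["fdr"] < fdr
    return flags
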