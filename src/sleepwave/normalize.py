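"""Quantile normalization and removal of unwanted variation (RUV).

RUV assumes the observed log expression follows a linear factor model
Y = X beta + W alpha + eps, where X carries the biology of interest and
W holds k latent unwanted factors (batch, day, scanner...). The factors
are estimated either from negative-control genes (features assumed
unaffected by the biology, here called the ``negative_controls`` variant)
or from differences between biological replicates (``replicate_samples``),
where any systematic difference must be unwanted by construction. The
estimated component W alpha-hat is subtracted from the matrix.

``scan_k`` runs the adjustment and downstream differential expression for
each candidate number of factors and recommends the smallest k at which
positive-control recall plateaus while negative-control p-values look
uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ControlGeneSets, ExpressionDataset

__all__ = ["RUVFit", "KScanReport", "quantile_normalize", "ruv_fit", "scan_k"]


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every sample to share one reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column is mapped onto it by rank, ties receiving the mean of the tied
    reference values. Idempotent, and every output column is a permutation
    of the reference vector.
    """
    if dataset.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = dataset.matrix.to_numpy(float)
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    matrix = pd.DataFrame(out, index=dataset.matrix.index, columns=dataset.matrix.columns)
    return dataset.with_matrix(matrix)


@dataclass
class RUVFit:
    """Result of one RUV adjustment.

    ``W`` (samples x k) spans the estimated unwanted factors, ``alpha``
    (k x genes) their loadings; ``adjusted`` is the input with W alpha-hat
    subtracted. ``k = 0`` leaves the data untouched.
    """

    k: int
    W: pd.DataFrame
    alpha: pd.DataFrame
    adjusted: ExpressionDataset
    variant: str
    control_ids: tuple


def _center_genes(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def ruv_fit(
    dataset: ExpressionDataset,
    k: int,
    variant: str = "replicate_samples",
    control_ids=None,
) -> RUVFit:
    """Estimate and remove ``k`` factors of unwanted variation.

    negative_controls
        Factor analysis (SVD) of the sample-centered control-gene
        submatrix: W = first k left singular vectors scaled by their
        singular values; loadings for all genes by least squares on W.
    replicate_samples
        Within each replicate group the group mean is subtracted from
        every sample, cancelling biology; loadings alpha are the top k
        right singular vectors of the stacked differences (restricted to
        ``control_ids`` when given, all genes otherwise), and each
        sample's factor activity is recovered by regressing its centered
        control-gene values on alpha.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    Y = dataset.matrix.to_numpy(float)  # genes x samples
    genes = dataset.matrix.index
    samples = dataset.matrix.columns
    if k == 0:
        return RUVFit(
            k=0,
            W=pd.DataFrame(index=samples),
            alpha=pd.DataFrame(columns=genes),
            adjusted=dataset.with_matrix(dataset.matrix.copy()),
            variant=variant,
            control_ids=tuple(control_ids) if control_ids is not None else tuple(),
        )

    if variant == "negative_controls":
        if control_ids is None:
            raise ValueError("negative_controls variant requires control_ids")
        control_ids = [g for g in control_ids if g in set(genes)]
        if len(control_ids) < k:
            raise ValueError(
                f"need at least k={k} control genes, got {len(control_ids)}"
            )
        Yc = _center_genes(dataset.matrix.loc[control_ids].to_numpy(float)).T  # samples x ctrl
        U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
        rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
        if k > rank:
            raise ValueError(
                f"k={k} exceeds the rank of the control submatrix (maximum attainable {rank})"
            )
        W = U[:, :k] * s[:k]
    elif variant == "replicate_samples":
        rep = dataset.design["replicate_group"]
        counts = rep.value_counts()
        usable = counts[counts >= 2].index
        if len(usable) == 0:
            raise ValueError(
                "replicate_samples variant requires at least one replicate group "
                "with >= 2 samples"
            )
        if control_ids is None:
            control_idx = np.arange(len(genes))
        else:
            gene_pos = {g: i for i, g in enumerate(genes)}
            control_idx = np.array([gene_pos[g] for g in control_ids if g in gene_pos])
            if control_idx.size < k:
                raise ValueError(f"need at least k={k} control genes, got {control_idx.size}")
        diffs = []
        for group in usable:
            cols = np.flatnonzero((rep == group).to_numpy())
            block = Y[:, cols]
            diffs.append((block - block.mean(axis=1, keepdims=True)).T)  # samples x genes
        D = np.vstack(diffs)[:, control_idx]
        U, s, Vt = np.linalg.svd(D, full_matrices=False)
        rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
        if k > rank:
            raise ValueError(
                f"k={k} exceeds the rank of the replicate-difference matrix "
                f"(maximum attainable {rank})"
            )
        alpha_c = Vt[:k]  # k x n_controls
        Yc = _center_genes(Y[control_idx]).T  # samples x n_controls
        W, *_ = np.linalg.lstsq(alpha_c.T, Yc.T, rcond=None)
        W = W.T  # samples x k
    else:
        raise ValueError(f"unknown RUV variant: {variant!r}")

    W = W - W.mean(axis=0, keepdims=True)
    Yt_centered = _center_genes(Y).T  # samples x genes
    alpha, *_ = np.linalg.lstsq(W, Yt_centered, rcond=None)  # k x genes
    adjusted_values = Y - (W @ alpha).T
    adjusted = dataset.with_matrix(
        pd.DataFrame(adjusted_values, index=genes, columns=samples)
    )
    return RUVFit(
        k=k,
        W=pd.DataFrame(W, index=samples, columns=[f"W{j+1}" for j in range(k)]),
        alpha=pd.DataFrame(alpha, index=[f"W{j+1}" for j in range(k)], columns=genes),
        adjusted=adjusted,
        variant=variant,
        control_ids=tuple(control_ids) if control_ids is not None else tuple(),
    )


@dataclass
class KScanReport:
    """Diagnostics per candidate k and the recommended choice.

    ``table`` has one row per k with mean positive-control recall at the
    FDR cutoff, the Kolmogorov-Smirnov statistic of negative-control
    p-values against uniformity, and the fraction of leading-PC score
    variance explained by the experimental groups.
    """

    table: pd.DataFrame
    recommended_k: int
    fdr: float


def scan_k(
    dataset: ExpressionDataset,
    controls: ControlGeneSets,
    contrasts,
    k_max: int = 6,
    variant: str = "replicate_samples",
    control_ids=None,
    fdr: float = 0.01,
    ks_threshold: float = 0.1,
    use_w_covariates: bool = True,
) -> KScanReport:
    """Run RUV + differential expression for k = 0..k_max and pick k.

    The recommendation is the smallest k whose mean positive-control
    recall is within one control gene of the maximum over the scan and
    whose negative-control p-values pass the uniformity check
    (KS statistic < ``ks_threshold``). With ``use_w_covariates`` the
    estimated factors enter the DE design; otherwise DE runs on the
    subtracted matrix.
    """
    from .de import fit_contrasts  # local import to avoid a cycle
    from .integrate import pca_report

    if not controls.positive or not controls.negative:
        raise ValueError("scan_k requires both positive and negative controls")
    controls = controls.restrict_to(dataset.feature_ids)
    neg = sorted(controls.negative)
    rows = []
    for k in range(k_max + 1):
        fit = ruv_fit(dataset, k=k, variant=variant, control_ids=control_ids)
        if use_w_covariates and k > 0:
            de_results = fit_contrasts(dataset, contrasts, covariates=fit.W.to_numpy())
        else:
            de_results = fit_contrasts(fit.adjusted, contrasts)
        recalls, neg_pvals, n_pos = [], [], []
        for contrast, de in zip(contrasts, de_results):
            pos = controls.positive.get(contrast.name, controls.positive.get("*", set()))
            pos = [g for g in pos if g in de.table.index]
            if pos:
                recalls.append((de.table.loc[pos, "fdr"] < fdr).mean())
                n_pos.append(len(pos))
            neg_pvals.append(de.table.loc[neg, "p"].to_numpy())
        ks_stat = stats.kstest(np.concatenate(neg_pvals), "uniform").statistic
        pca = pca_report(fit.adjusted, n_components=2)
        sep = pca.associations.loc["group", ["PC1", "PC2"]].mean()
        rows.append(
            {
                "k": k,
                "positive_recall": float(np.mean(recalls)) if recalls else np.nan,
                "negative_ks": float(ks_stat),
                "group_pc_separation": float(sep),
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    tol = 1.0 / max(min(n_pos), 1) if n_pos else 0.0
    max_recall = table["positive_recall"].max()
    ok = (table["positive_recall"] >= max_recall - tol) & (
        table["negative_ks"] < ks_threshold
    )
    if ok.any():
        recommended = int(table.index[ok.to_numpy()][0])
    else:
        warnings.warn(
            "no k satisfied both the recall plateau and the uniformity check; "
            "recommending the k with maximal recall",
            stacklevel=2,
        )
        recommended = int(table["positive_recall"].idxmax())
    return KScanReport(table=table, recommended_k=recommended, fdr=fdr)
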