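"""Cross-platform and cross-study integration.

Probeset ids are harmonized to a shared gene namespace through a two-column
mapping table; ambiguous features are excluded in both directions (a
probeset hitting more than one gene, and a gene hit by more than one
probeset within a platform). Studies are then inner-joined on the shared
genes, filtered for expressed features, and summarized by PCA on
gene-centered log expression with per-component variance fractions and the
design variable that best separates each component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset, ValidationError

__all__ = [
    "PCAReport",
    "load_mapping",
    "harmonize",
    "filter_expressed",
    "pca_report",
]


def load_mapping(path) -> pd.DataFrame:
    """Load a two-column probeset_id -> gene_id TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: mapping table needs 2 columns")
    df = df.iloc[:, :2]
    df.columns = ["probeset_id", "gene_id"]
    return df.drop_duplicates()


def harmonize(datasets, mapping: pd.DataFrame) -> ExpressionDataset:
    """Map features to gene ids and inner-join >= 2 datasets.

    Probesets mapping to more than one gene are dropped everywhere; genes
    hit by more than one surviving probeset within a dataset are dropped
    from that dataset (both directions of "multiple mapping"). Surviving
    features are renamed to gene ids, datasets are joined on the shared
    genes and design tables concatenated.
    """
    if len(datasets) < 2:
        raise ValueError("harmonize needs at least 2 datasets")
    mapping = mapping.drop_duplicates()
    per_gene_counts = mapping.groupby("probeset_id")["gene_id"].nunique()
    multi_probesets = set(per_gene_counts[per_gene_counts > 1].index)
    clean = mapping[~mapping["probeset_id"].isin(multi_probesets)]
    ps_to_gene = dict(zip(clean["probeset_id"], clean["gene_id"]))

    renamed = []
    for ds in datasets:
        keep = [p for p in ds.feature_ids if p in ps_to_gene]
        sub = ds.matrix.loc[keep]
        gene_ids = pd.Series([ps_to_gene[p] for p in keep], index=keep)
        hits = gene_ids.value_counts()
        multi_genes = set(hits[hits > 1].index)
        keep2 = [p for p in keep if gene_ids[p] not in multi_genes]
        sub = sub.loc[keep2]
        sub.index = pd.Index([ps_to_gene[p] for p in keep2], name="gene_id")
        renamed.append((sub, ds.design))

    shared = renamed[0][0].index
    for sub, _ in renamed[1:]:
        shared = shared.intersection(sub.index)
    if len(shared) == 0:
        raise ValueError("no genes shared across datasets after harmonization")
    shared = shared.sort_values()
    matrix = pd.concat([sub.loc[shared] for sub, _ in renamed], axis=1)
    design = pd.concat([d for _, d in renamed])
    return ExpressionDataset(matrix=matrix, design=design)


def filter_expressed(
    dataset: ExpressionDataset, threshold: float = 4.0, fraction: float = 0.5
) -> ExpressionDataset:
    """Keep features expressed above ``threshold`` in more than ``fraction``
    of samples (both comparisons strict)."""
    frac_above = (dataset.matrix.to_numpy(float) > threshold).mean(axis=1)
    keep = dataset.feature_ids[frac_above > fraction]
    if len(keep) == 0:
        warnings.warn("expression filter removed every feature", stacklevel=2)
    return ExpressionDataset(
        matrix=dataset.matrix.loc[keep], design=dataset.design.copy()
    )


@dataclass
class PCAReport:
    """PCA of gene-centered log expression.

    ``variance_fraction`` holds sigma_i^2 / sum(sigma^2) per component,
    ``scores`` the per-sample coordinates, and ``associations`` the
    one-way variance ratio of each component's scores grouped by each
    design variable, adjusted for the number of levels (the adjusted-R^2
    correction) so fine-grained variables such as replicate_group do not
    win by level count alone. ``best_covariate`` names the variable with
    the highest adjusted ratio per component.
    """

    variance_fraction: pd.Series
    scores: pd.DataFrame
    associations: pd.DataFrame
    best_covariate: pd.Series


def _variance_ratio(scores: np.ndarray, labels: pd.Series) -> float:
    s = pd.Series(scores, index=labels.index)
    total = float(((s - s.mean()) ** 2).sum())
    if total == 0:
        return 0.0
    grp = s.groupby(labels, observed=True)
    between = float((grp.size() * (grp.mean() - s.mean()) ** 2).sum())
    r2 = between / total
    n, g = len(s), grp.ngroups
    if g >= n:
        return 0.0
    # adjusted R^2: penalize the number of levels
    return max(0.0, 1.0 - (1.0 - r2) * (n - 1) / (n - g))


def pca_report(dataset: ExpressionDataset, n_components: int = 10) -> PCAReport:
    """Gene-centered SVD of the sample x gene matrix with diagnostics."""
    if dataset.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = dataset.matrix.to_numpy(float)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
    if not np.any(Xc):
        raise ValueError("constant matrix: no variance to decompose")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    n_components = min(n_components, int((s > s[0] * 1e-12).sum()))
    comps = [f"PC{i+1}" for i in range(n_components)]
    variance_fraction = pd.Series((s[:n_components] ** 2) / total, index=comps)
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=dataset.sample_ids, columns=comps
    )
    variables = ["group", "replicate_group", "study", "platform"]
    assoc = pd.DataFrame(index=variables, columns=comps, dtype=float)
    for var in variables:
        labels = dataset.design[var]
        for c in comps:
            assoc.loc[var, c] = _variance_ratio(scores[c].to_numpy(), labels)
    best = assoc.idxmax(axis=0)
    return PCAReport(
        variance_fraction=variance_fraction,
        scores=scores,
        associations=assoc,
        best_covariate=best,
    )
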