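"""Local functional-enrichment scoring with term clustering.

Enrichment of a gene list against annotation terms (GMT gene sets) is
scored with the EASE statistic: a jackknifed one-sided Fisher exact test
in which the overlap count is reduced by one before taking the
hypergeometric upper tail, making the test conservative for small
overlaps (an overlap of one gene is never significant). Enriched terms
(EASE p < 0.05) are then grouped by the similarity of their gene
membership — Cohen's kappa between binary membership vectors — using
single linkage at a similarity threshold, and each group of terms is
summarized by an enrichment score, -log10 of the geometric mean of member
p-values; groups scoring above 1.5 (mean p below ~0.03) form the headline
report. The background is the set of all genes present on the array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "TermCluster",
    "ease_test",
    "kappa_matrix",
    "cluster_terms",
    "enrich",
]


def ease_test(gene_list, term_set, background) -> float:
    """Jackknifed one-sided hypergeometric (EASE) enrichment p-value.

    The 2x2 table is built from ``gene_list`` and ``term_set`` inside
    ``background`` and the overlap count a is reduced by one; the p-value
    is P(X >= a - 1). Overlaps of zero or one gene give p = 1.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_list = set(gene_list)
    outside = gene_list - background
    if outside:
        warnings.warn(
            f"{len(outside)} list genes absent from background were dropped",
            stacklevel=2,
        )
        gene_list &= background
    term_eff = set(term_set) & background
    a = len(gene_list & term_eff)
    if a <= 1:
        return 1.0
    N, K, n = len(background), len(term_eff), len(gene_list)
    # P(X >= a-1) for X ~ Hypergeom(N, K, n); sf(k) = P(X > k)
    return float(stats.hypergeom.sf(a - 2, N, K, n))


def _cohen_kappa(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    po = float((x == y).mean())
    px, py = x.mean(), y.mean()
    pe = px * py + (1 - px) * (1 - py)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_matrix(terms: dict, universe) -> pd.DataFrame:
    """Pairwise Cohen's kappa between term membership vectors.

    ``terms`` maps term id -> gene set; membership vectors are binary over
    ``universe``. Terms with no genes in the universe are excluded with a
    warning.
    """
    universe = sorted(set(universe))
    if len(terms) < 2:
        raise ValueError("kappa matrix needs at least 2 terms")
    vectors = {}
    for term, genes in terms.items():
        v = np.fromiter((g in genes for g in universe), dtype=bool, count=len(universe))
        if not v.any():
            warnings.warn(f"term {term!r} has no genes in the universe; excluded", stacklevel=2)
            continue
        vectors[term] = v
    names = list(vectors)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = _cohen_kappa(vectors[a], vectors[b])
            out.loc[a, b] = out.loc[b, a] = k
    return out


@dataclass
class TermCluster:
    members: tuple
    score: float


@dataclass
class EnrichmentResult:
    """Per-term EASE statistics and kappa-based term clusters.

    ``clusters`` holds groups of >= ``group_membership`` related terms with
    enrichment score above the cutoff; ``minor_clusters`` those that scored
    below it; ``singletons`` enriched terms that clustered with nothing.
    """

    term_table: pd.DataFrame
    clusters: list = field(default_factory=list)
    minor_clusters: list = field(default_factory=list)
    singletons: list = field(default_factory=list)


def cluster_terms(
    term_pvalues: dict,
    kappa: pd.DataFrame,
    similarity_threshold: float = 0.2,
    group_membership: int = 2,
    score_cutoff: float = 1.5,
):
    """Group enriched terms by kappa similarity and score the groups.

    Single-linkage grouping at ``similarity_threshold``: two terms join the
    same cluster when connected by a chain of pairwise kappa values at or
    above the threshold. Groups smaller than ``group_membership`` are
    reported as singletons. Each group's enrichment score is -log10 of the
    geometric mean of its members' p-values; groups at or below
    ``score_cutoff`` are kept out of the headline list.

    Returns ``(clusters, minor_clusters, singletons)``.
    """
    terms = [t for t in kappa.index if t in term_pvalues]
    if not terms:
        return [], [], []
    K = kappa.loc[terms, terms].to_numpy()
    adj = csr_matrix((K >= similarity_threshold).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    clusters, minor, singles = [], [], []
    for comp in range(n_comp):
        members = tuple(terms[i] for i in np.flatnonzero(labels == comp))
        if len(members) < group_membership:
            singles.extend(members)
            continue
        pvals = np.array([term_pvalues[t] for t in members], float)
        score = float(-np.log10(stats.gmean(np.clip(pvals, 1e-300, None))))
        tc = TermCluster(members=members, score=score)
        (clusters if score > score_cutoff else minor).append(tc)
    clusters.sort(key=lambda c: -c.score)
    minor.sort(key=lambda c: -c.score)
    return clusters, minor, sorted(singles)


def enrich(
    gene_list,
    background,
    collection: GeneSetCollection,
    ease_cutoff: float = 0.05,
    similarity_threshold: float = 0.2,
    group_membership: int = 2,
    score_cutoff: float = 1.5,
) -> EnrichmentResult:
    """EASE enrichment of ``gene_list`` over a gene-set collection,
    followed by kappa term clustering of the enriched terms."""
    background = set(background)
    gene_list = set(gene_list) & background
    rows = []
    for term, (desc, genes) in collection.sets.items():
        eff = genes & background
        if not eff:
            continue
        a = len(gene_list & eff)
        p = ease_test(gene_list, genes, background)
        rows.append(
            {
                "term": term,
                "description": desc,
                "overlap": a,
                "list_size": len(gene_list),
                "term_size": len(eff),
                "background_size": len(background),
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["description", "overlap", "list_size", "term_size", "background_size", "p"]
    )
    enriched = table.index[table["p"] < ease_cutoff] if len(table) else []
    result = EnrichmentResult(term_table=table)
    if len(enriched) >= 2:
        terms = {t: collection.sets[t][1] & gene_list for t in enriched}
        kappa = kappa_matrix(terms, universe=gene_list)
        pvals = {t: float(table.loc[t, "p"]) for t in enriched}
        result.clusters, result.minor_clusters, result.singletons = cluster_terms(
            pvals,
            kappa,
            similarity_threshold=similarity_threshold,
            group_membership=group_membership,
            score_cutoff=score_cutoff,
        )
    elif len(enriched) == 1:
        result.singletons = [enriched[0]]
    return result
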