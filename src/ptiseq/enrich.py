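"""Hypergeometric over-representation of gene categories within clusters.

For a cluster of n genes drawn from a universe of N genes of which K carry
a category (a GO term, a TF family, or presence of a promoter
cis-element), the over-representation p-value is the upper tail

    p = sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n)

with k the observed overlap. One-sided (over-representation) only, per
the study design; heatmaps report -log10 of the raw p while BH-adjusted
q-values are carried alongside in the results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import adjust_bh

log = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed in log space.

    Arguments follow the gene-set convention: overlap k, cluster size n,
    category size K, universe size N. Bounds are validated and violations
    name the offending argument.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N:
        raise ValueError(f"n={n} exceeds the universe size N={N}")
    if K > N:
        raise ValueError(f"K={K} exceeds the universe size N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k < max(0, n + K - N):
        raise ValueError(f"k={k} below the support floor max(0, n+K-N)={max(0, n + K - N)}")
    # scipy's sf is computed from log-space binomial coefficients
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentCell:
    """One (cluster, category) over-representation test."""

    cluster_id: object
    category_id: str
    category_class: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float = np.nan


class AnnotationMap:
    """category_id -> gene set, with a category class label.

    Built from a two-column (gene_id, category_id) table or a mapping.
    Empty categories are dropped.
    """

    def __init__(self, categories: dict, category_class: str = "GO"):
        self.categories = {c: set(g) for c, g in categories.items() if len(g) > 0}
        self.category_class = category_class

    @classmethod
    def from_frame(cls, df: pd.DataFrame, category_class: str = "GO") -> "AnnotationMap":
        gcol, ccol = df.columns[:2]
        cats: dict = {}
        for g, c in zip(df[gcol], df[ccol]):
            cats.setdefault(c, set()).add(g)
        return cls(cats, category_class)

    @classmethod
    def read_tsv(cls, path, category_class: str = "GO") -> "AnnotationMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"), category_class)

    @classmethod
    def from_presence(cls, table: pd.DataFrame, category_class: str = "motif") -> "AnnotationMap":
        """From a gene × category boolean presence matrix."""
        return cls(
            {c: set(table.index[table[c].astype(bool)]) for c in table.columns},
            category_class,
        )

    def genes(self) -> set:
        out: set = set()
        for g in self.categories.values():
            out |= g
        return out

    def __len__(self) -> int:
        return len(self.categories)


class ClusterEnrichment:
    """Over-representation model for a clustering against one annotation map.

    Parameters
    ----------
    clusters : mapping/Series gene_id -> cluster label
    annotations : AnnotationMap
    universe : iterable of gene_ids, optional
        Defaults to every gene in the annotation input (genome-wide
        background). Genes annotated outside the universe are dropped
        from their categories with a logged count; cluster members
        outside the universe are ignored likewise.
    """

    def __init__(self, clusters, annotations: AnnotationMap, universe=None):
        labels = clusters.labels if hasattr(clusters, "labels") else pd.Series(dict(clusters))
        self.labels = labels
        self.annotations = annotations
        if universe is None:
            universe = annotations.genes()
        self.universe = set(universe)
        if not self.universe:
            raise ValueError("empty gene universe")

    def fit(self) -> "EnrichmentResults":
        N = len(self.universe)
        dropped = 0
        cats = {}
        for cid, genes in self.annotations.categories.items():
            inside = genes & self.universe
            dropped += len(genes) - len(inside)
            if inside:
                cats[cid] = inside
        if dropped:
            log.info("dropped %d annotated genes outside the universe", dropped)
        outside = (~self.labels.index.isin(self.universe)).sum()
        if outside:
            log.info("ignored %d clustered genes outside the universe", outside)
        cells = []
        cluster_ids = sorted(self.labels.unique())
        for c in cluster_ids:
            members = set(self.labels.index[self.labels == c]) & self.universe
            n = len(members)
            for cid, genes in cats.items():
                K = len(genes)
                k = len(members & genes)
                p = hypergeom_upper_tail(k, n, K, N)
                cells.append(
                    EnrichmentCell(c, cid, self.annotations.category_class, k, n, K, N, p)
                )
        # BH within the category class across all (cluster, category) tests
        if cells:
            q = adjust_bh([c.p for c in cells])
            cells = [
                EnrichmentCell(c.cluster_id, c.category_id, c.category_class,
                               c.k, c.n, c.K, c.N, c.p, float(qi))
                for c, qi in zip(cells, q)
            ]
        return EnrichmentResults(self, cells)


class EnrichmentResults:
    """Fitted enrichment cells with table and heatmap accessors."""

    def __init__(self, model: ClusterEnrichment, cells: list):
        self.model = model
        self.cells = cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.cluster_id, c.category_id, c.category_class, c.k, c.n, c.K, c.N, c.p, c.q)
                for c in self.cells
            ],
            columns=["cluster", "category", "class", "k", "n", "K", "N", "p", "q"],
        )

    def heatmap_matrix(self, clusters=None, categories=None) -> pd.DataFrame:
        return heatmap_matrix(self.cells, clusters, categories)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Cells significant at BH-adjusted q < alpha, most enriched first."""
        df = self.to_frame()
        return df[df["q"] < alpha].sort_values("p").reset_index(drop=True)


def cluster_enrichment(clusters, annotations: AnnotationMap, universe=None) -> list:
    """Functional wrapper returning the list of EnrichmentCell."""
    return ClusterEnrichment(clusters, annotations, universe).fit().cells


def heatmap_matrix(cells, clusters=None, categories=None) -> pd.DataFrame:
    """categories × clusters matrix of -log10(p), ordered as given.

    Missing (cluster, category) pairs are 0 (p = 1); darker cells in the
    rendered heatmap mean stronger over-representation.
    """
    by_pair = {(c.cluster_id, c.category_id): c.p for c in cells}
    if clusters is None:
        clusters = sorted({c.cluster_id for c in cells})
    if categories is None:
        seen = []
        for c in cells:
            if c.category_id not in seen:
                seen.append(c.category_id)
        categories = seen
    mat = pd.DataFrame(0.0, index=list(categories), columns=list(clusters))
    for cat in categories:
        for cl in clusters:
            p = by_pair.get((cl, cat))
            if p is not None:
                mat.at[cat, cl] = -np.log10(p)
    mat.index.name = "category"
    mat.columns.name = "cluster"
    return mat
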