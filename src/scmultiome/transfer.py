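"""Reference-atlas label transfer via k-nearest-neighbour mode voting.

Query cells are placed into a shared linear embedding with the reference
(log-normalization per dataset with mean-one library-size factors, highly
variable gene selection, then a single PCA fitted on the concatenated
matrices), and each query cell receives the modal cell-type label of its k
nearest reference cells.  Ties between equally frequent labels are resolved
in favour of the label carried by the single closest reference cell among
the tied labels' members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "lognormalize",
    "select_hvgs",
    "fit_pca",
    "joint_embed",
    "knn_transfer",
    "JointEmbedding",
    "TransferResult",
    "LabelTransfer",
]


def lognormalize(counts, size_factors=None):
    """ln(count / size_factor + 1) with size factors scaled to mean one.

    ``counts`` is features x cells (dense or sparse).  Default size factors
    are library sizes divided by the mean library size, so equal libraries
    give factors of exactly one.
    """
    lib = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if size_factors is None:
        if np.any(lib == 0):
            raise ValueError("cannot normalize: cell with zero library size")
        sf = lib / lib.mean()
    else:
        sf = np.asarray(size_factors, dtype=float)
        if np.any(sf <= 0):
            raise ValueError("size factors must be positive")
        sf = sf / sf.mean()
    if sparse.issparse(counts):
        out = counts.tocsr().astype(float)
        out = out @ sparse.diags(1.0 / sf)
        out.data = np.log1p(out.data)
        return out.tocsr()
    return np.log1p(np.asarray(counts, dtype=float) / sf)


def _row_variances(mat) -> np.ndarray:
    if sparse.issparse(mat):
        m = np.asarray(mat.mean(axis=1)).ravel()
        sq = np.asarray(mat.multiply(mat).mean(axis=1)).ravel()
        return sq - m**2
    return np.var(np.asarray(mat), axis=1)


def select_hvgs(log_matrix, gene_names, n: int, exclusion=None, groups=None) -> np.ndarray:
    """Top-``n`` genes by variance of log-normalized expression.

    With ``groups`` (one label per cell) the variance is computed across the
    per-group mean profiles instead of across cells, matching selection of
    genes most variable across reference cell types.  ``exclusion`` is a
    :class:`scmultiome.qc.GeneExclusionRules` applied before ranking.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    keep = np.ones(len(gene_names), dtype=bool)
    if exclusion is not None:
        retained = set(exclusion.apply(list(gene_names)))
        keep = np.array([g in retained for g in gene_names])
    if groups is None:
        var = _row_variances(log_matrix)
    else:
        groups = np.asarray(groups)
        uniq = pd.unique(groups)
        means = np.empty((len(gene_names), len(uniq)))
        for j, g in enumerate(uniq):
            cols = np.flatnonzero(groups == g)
            sub = log_matrix[:, cols]
            means[:, j] = np.asarray(sub.mean(axis=1)).ravel()
        var = np.var(means, axis=1)
    var = np.where(keep, var, -np.inf)
    if n > int(keep.sum()):
        raise ValueError(f"requested {n} HVGs but only {int(keep.sum())} genes available")
    order = np.argsort(-var, kind="stable")[:n]
    return gene_names[np.sort(order)]


def _dense_cells_by_genes(log_matrix, gene_names, genes) -> np.ndarray:
    gene_names = np.asarray(gene_names, dtype=object)
    pos = pd.Index(gene_names).get_indexer(np.asarray(genes, dtype=object))
    if (pos < 0).any():
        missing = np.asarray(genes, dtype=object)[pos < 0][:3]
        raise ValueError(f"genes absent from matrix: {list(missing)} ...")
    sub = log_matrix[pos, :]
    if sparse.issparse(sub):
        sub = sub.toarray()
    return np.asarray(sub).T


def fit_pca(log_matrix, gene_names, genes, d: int, random_state: int = 0) -> np.ndarray:
    """PCA coordinates (cells x d) of a log matrix restricted to ``genes``."""
    X = _dense_cells_by_genes(log_matrix, gene_names, genes)
    if d > X.shape[1]:
        raise ValueError(f"d={d} exceeds the number of genes ({X.shape[1]})")
    pca = PCA(n_components=d, svd_solver="randomized", random_state=random_state)
    return pca.fit_transform(X)


@dataclass
class JointEmbedding:
    coordinates: np.ndarray  # (n_ref + n_query) x d
    role: np.ndarray  # 'reference' or 'query' per cell
    genes: np.ndarray
    loadings: np.ndarray  # d x n_genes
    mean: np.ndarray

    @property
    def reference_coords(self) -> np.ndarray:
        return self.coordinates[self.role == "reference"]

    @property
    def query_coords(self) -> np.ndarray:
        return self.coordinates[self.role == "query"]


def joint_embed(ref_log, query_log, gene_names, hvgs, d: int, random_state: int = 0) -> JointEmbedding:
    """Shared PCA of reference and query restricted to ``hvgs``.

    Both matrices must live in the same gene namespace and be log-normalized
    per dataset (which equalizes per-dataset depth).  The components are
    fitted on the concatenation, so identical inputs map to identical
    coordinates.
    """
    hvgs = np.asarray(hvgs, dtype=object)
    if d > len(hvgs):
        raise ValueError(f"d={d} exceeds the number of HVGs ({len(hvgs)})")
    Xr = _dense_cells_by_genes(ref_log, gene_names, hvgs)
    Xq = _dense_cells_by_genes(query_log, gene_names, hvgs)
    X = np.vstack([Xr, Xq])
    pca = PCA(n_components=d, svd_solver="randomized", random_state=random_state)
    coords = pca.fit_transform(X)
    role = np.array(["reference"] * Xr.shape[0] + ["query"] * Xq.shape[0], dtype=object)
    return JointEmbedding(coords, role, hvgs, pca.components_, pca.mean_)


@dataclass
class TransferResult:
    """Per-query-cell assignments with the neighbour evidence behind them."""

    assignments: pd.DataFrame  # label, modal_count, tie
    neighbor_indices: np.ndarray  # query cells x k, into the reference
    k: int

    @property
    def labels(self) -> np.ndarray:
        return self.assignments["label"].to_numpy()

    def accuracy(self, true_labels) -> float:
        return float(np.mean(self.labels == np.asarray(true_labels)))

    def confusion(self, true_labels) -> pd.DataFrame:
        """Row-stochastic confusion matrix (rows = true labels)."""
        df = pd.DataFrame({"true": np.asarray(true_labels), "assigned": self.labels})
        tab = pd.crosstab(df["true"], df["assigned"])
        return tab.div(tab.sum(axis=1), axis=0)

    def summary(self) -> str:
        counts = self.assignments["label"].value_counts()
        lines = [
            "Label transfer (kNN mode vote)",
            f"  query cells: {len(self.assignments)}    k: {self.k}",
            f"  ties broken by nearest reference cell: {int(self.assignments['tie'].sum())}",
            "  assigned label counts:",
        ]
        lines += [f"    {lab:<16s} {int(c)}" for lab, c in counts.items()]
        return "\n".join(lines)


def knn_transfer(embedding: JointEmbedding, reference_labels, k: int) -> TransferResult:
    """Assign each query cell the modal label of its k nearest reference cells.

    Euclidean metric; neighbour-distance ties are broken by lowest reference
    index; label-count ties go to the label of the closest reference cell
    among the tied labels' members.
    """
    ref = embedding.reference_coords
    query = embedding.query_coords
    return _knn_assign(ref, query, reference_labels, k)


def _knn_assign(ref_coords, query_coords, reference_labels, k: int) -> TransferResult:
    reference_labels = np.asarray(reference_labels, dtype=object)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ref_coords.shape[0]:
        raise ValueError("k exceeds the number of reference cells")
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(ref_coords)
    dist, idx = nn.kneighbors(query_coords)
    # deterministic ordering: by distance, then by reference index
    order = np.lexsort((idx, dist), axis=1)
    rows = np.arange(idx.shape[0])[:, None]
    idx = idx[rows, order]
    dist = dist[rows, order]

    labels = np.empty(query_coords.shape[0], dtype=object)
    modal = np.zeros(query_coords.shape[0], dtype=int)
    tie = np.zeros(query_coords.shape[0], dtype=bool)
    for i in range(query_coords.shape[0]):
        neigh = reference_labels[idx[i]]
        uniq, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top])
        if len(tied) > 1:
            tie[i] = True
            for lab in neigh:  # neighbours are distance-ordered
                if lab in tied:
                    labels[i] = lab
                    break
        else:
            labels[i] = uniq[counts.argmax()]
        modal[i] = top
    assignments = pd.DataFrame({"label": labels, "modal_count": modal, "tie": tie})
    return TransferResult(assignments, idx, k)


class LabelTransfer:
    """Model object: reference atlas + query counts -> label assignments.

    Parameters
    ----------
    atlas
        :class:`scmultiome.simulate.ReferenceAtlas` (or any object with
        ``expression`` (genes x cells, log-normalized), ``gene_names`` and
        ``labels``).
    query_counts
        Raw query counts, genes x cells, in ``query_gene_names`` namespace.
    exclusion
        Optional :class:`scmultiome.qc.GeneExclusionRules` removing
        non-informative genes before HVG selection.
    """

    def __init__(self, atlas, query_counts, query_gene_names, exclusion=None):
        self.atlas = atlas
        self.query_log = lognormalize(query_counts)
        self.query_gene_names = np.asarray(query_gene_names, dtype=object)
        self.exclusion = exclusion
        common = pd.Index(atlas.gene_names).intersection(pd.Index(self.query_gene_names))
        if len(common) == 0:
            raise ValueError("reference and query share no genes")
        self._common = np.asarray(common, dtype=object)

    def fit(self, k: int = 25, d: int = 50, n_hvgs: int = 2500, hvg_by_type: bool = True,
            random_state: int = 0) -> TransferResult:
        avail = len(self.atlas.gene_names)
        if self.exclusion is not None:
            avail = len(self.exclusion.apply(list(self.atlas.gene_names)))
        n_hvgs = min(n_hvgs, avail, len(self._common))
        groups = self.atlas.labels if hvg_by_type else None
        hvgs = select_hvgs(
            self.atlas.expression, self.atlas.gene_names, n_hvgs,
            exclusion=self.exclusion, groups=groups,
        )
        hvgs = np.asarray(pd.Index(hvgs).intersection(pd.Index(self._common)), dtype=object)
        d = min(d, len(hvgs))
        emb = self._embed(hvgs, d, random_state)
        result = knn_transfer(emb, self.atlas.labels, k)
        result.embedding = emb
        return result

    def _embed(self, hvgs, d, random_state):
        Xr = _dense_cells_by_genes(self.atlas.expression, self.atlas.gene_names, hvgs)
        Xq = _dense_cells_by_genes(self.query_log, self.query_gene_names, hvgs)
        X = np.vstack([Xr, Xq])
        pca = PCA(n_components=d, svd_solver="randomized", random_state=random_state)
        coords = pca.fit_transform(X)
        role = np.array(["reference"] * Xr.shape[0] + ["query"] * Xq.shape[0], dtype=object)
        return JointEmbedding(coords, role, np.asarray(hvgs, dtype=object), pca.components_, pca.mean_)
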