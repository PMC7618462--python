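"""Per-cell kNN differential abundance between knockdown and wild type.

Each retained cell is tested for local over- or under-representation of
knockdown (KD) cells among its k nearest neighbours (default k = 100) in a
low-dimensional embedding.  The expected KD fraction of a cell is the
timepoint-composition-weighted mean of the global per-timepoint KD ratios
(r_t = KD cells / total cells at timepoint t):

    e_hat = sum_t n_t * r_t / k

where n_t counts the cell's neighbours from timepoint t.  The observed KD
neighbour count x is compared to Binomial(k, e_hat) with an exact two-sided
test (sum of all outcome probabilities not exceeding the observed outcome's
probability), followed by Benjamini-Hochberg FDR across cells.  The DA
level is the observed over expected ratio o / e_hat.

Wild-type cells from the earliest timepoint are excluded by default (both
as tested cells and as neighbour candidates), mirroring the exclusion of
day-3 WT cells: at that timepoint the perturbation has not yet acted, and
keeping only the KD cells anchors the expected ratio there at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DAConfig",
    "DAResult",
    "global_expected_ratios",
    "per_cell_expected_ratio",
    "binomial_two_sided_pvalues",
    "knn_da_test",
    "DifferentialAbundance",
]


def exclude_first_timepoint_wt(meta: pd.DataFrame) -> np.ndarray:
    """Boolean mask of cells to exclude: WT cells of the earliest timepoint."""
    tp = meta["timepoint"]
    if isinstance(tp.dtype, pd.CategoricalDtype):
        first = tp.cat.categories[0]
    else:
        first = sorted(tp.unique())[0]
    return ((tp == first) & (meta["condition"] == "WT")).to_numpy()


@dataclass
class DAConfig:
    k: int = 100
    fdr_max: float = 0.05
    #: predicate(meta) -> boolean exclusion mask; None keeps every cell
    exclude: Callable[[pd.DataFrame], np.ndarray] | None = exclude_first_timepoint_wt
    kd_label: str = "KD"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("DAConfig.k must be >= 1")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("DAConfig.fdr_max must be in (0, 1)")


def global_expected_ratios(cell_meta: pd.DataFrame, kd_label: str = "KD") -> pd.Series:
    """Per-timepoint global KD ratio r_t = KD cells / total cells."""
    if not {"timepoint", "condition"}.issubset(cell_meta.columns):
        raise ValueError("cell metadata needs 'timepoint' and 'condition' columns")
    tp = cell_meta["timepoint"]
    if isinstance(tp.dtype, pd.CategoricalDtype):
        empty = set(tp.cat.categories) - set(tp.unique())
        if empty:
            import warnings

            warnings.warn(f"timepoint(s) without cells omitted: {sorted(empty)}")
    grp = cell_meta.groupby("timepoint", observed=True)["condition"]
    total = grp.size()
    kd = grp.apply(lambda s: int((s == kd_label).sum()))
    return (kd / total).rename("expected_kd_ratio")


def per_cell_expected_ratio(neighbor_timepoint_counts: pd.Series | dict,
                            ratios: pd.Series) -> float:
    """e_hat = sum_t n_t * r_t / k for one cell's neighbour composition."""
    counts = pd.Series(neighbor_timepoint_counts, dtype=float)
    unknown = counts.index.difference(ratios.index)
    if len(unknown):
        raise ValueError(f"neighbour timepoint(s) without a global ratio: {list(unknown)}")
    k = counts.sum()
    if k <= 0:
        raise ValueError("neighbour counts must sum to k >= 1")
    return float((counts * ratios.reindex(counts.index)).sum() / k)


def binomial_two_sided_pvalues(x: np.ndarray, k: int, e: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p-values, vectorised over cells.

    p = sum of P(X = j) over all j whose probability does not exceed the
    observed outcome's probability (up to a 1e-9 relative tolerance guarding
    floating-point ties); this reduces to tail doubling for symmetric e.
    Degenerate expectations are handled by the exact mass: an outcome with
    probability zero under e in {0, 1} receives the smallest positive float.
    """
    x = np.asarray(x, dtype=int)
    e = np.asarray(e, dtype=float)
    j = np.arange(k + 1)
    pmf = stats.binom.pmf(j[None, :], k, e[:, None])
    px = pmf[np.arange(len(x)), x]
    include = pmf <= px[:, None] * (1.0 + 1e-9)
    p = (pmf * include).sum(axis=1)
    p = np.minimum(p, 1.0)
    return np.where(px > 0, p, np.finfo(float).tiny)


@dataclass
class DAResult:
    """Per-cell DA test results plus the global expected ratios used."""

    table: pd.DataFrame  # cell, o, e_hat, x, p, q, level + nn_<tp> columns
    global_ratios: pd.Series
    config: DAConfig

    @property
    def significant(self) -> np.ndarray:
        return (self.table["q"] < self.config.fdr_max).to_numpy()

    def summary(self) -> str:
        t = self.table
        sig = self.significant
        depleted = sig & (t["level"] < 1)
        enriched = sig & (t["level"] > 1)
        lines = [
            f"kNN differential abundance (k = {self.config.k}, exact two-sided binomial)",
            f"  cells tested: {len(t)}",
            "  global expected KD ratio by timepoint: "
            + ", ".join(f"{i}={v:.3f}" for i, v in self.global_ratios.items()),
            f"  significant at FDR < {self.config.fdr_max}: {int(sig.sum())} "
            f"({int(depleted.sum())} depleted, {int(enriched.sum())} enriched)",
        ]
        return "\n".join(lines)

    def plot_levels(self, ax=None):
        """Histogram of per-cell DA levels, significant cells highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lv = self.table["level"].replace([np.inf], np.nan).dropna()
        ax.hist(lv, bins=50, color="lightgrey", label="all cells")
        sig = self.table.loc[self.significant, "level"].replace([np.inf], np.nan).dropna()
        if len(sig):
            ax.hist(sig, bins=50, color="firebrick", label=f"q < {self.config.fdr_max}")
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_xlabel("DA level (observed / expected KD ratio)")
        ax.set_ylabel("cells")
        ax.legend()
        return ax


def knn_da_test(embedding: np.ndarray, cell_meta: pd.DataFrame,
                config: DAConfig | None = None) -> DAResult:
    """Run the per-cell kNN binomial DA test.

    ``embedding`` has one row per row of ``cell_meta``.  Cells matching the
    exclusion predicate are dropped both as tested cells and as neighbour
    candidates; each cell is excluded from its own neighbour set.
    """
    config = config or DAConfig()
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != len(cell_meta):
        raise ValueError("embedding row count does not match cell metadata")
    meta = cell_meta.reset_index(drop=True)
    keep = np.ones(len(meta), dtype=bool)
    if config.exclude is not None:
        keep = ~np.asarray(config.exclude(meta), dtype=bool)
    meta = meta.loc[keep].reset_index(drop=True)
    X = embedding[keep]
    n = len(meta)
    k = config.k
    if n <= k:
        raise ValueError(f"need more than k={k} retained cells, have {n}")

    ratios = global_expected_ratios(meta, kd_label=config.kd_label)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self; if the self column is not first (duplicate coordinates),
    # remove the matching index and keep the first k others
    neigh = np.empty((n, k), dtype=int)
    rows = np.arange(n)
    self_pos = np.argmax(idx == rows[:, None], axis=1)
    has_self = (idx == rows[:, None]).any(axis=1)
    for i in range(n):
        row = np.delete(idx[i], self_pos[i]) if has_self[i] else idx[i][:-1]
        neigh[i] = row[:k]

    is_kd = (meta["condition"] == config.kd_label).to_numpy()
    tp_codes, tp_labels = pd.factorize(meta["timepoint"], sort=False)
    # restrict to timepoints present among retained cells, in ratio order
    ratio_vec = ratios.reindex(tp_labels).to_numpy()

    x = is_kd[neigh].sum(axis=1)
    o = x / k
    nn_tp = np.zeros((n, len(tp_labels)), dtype=int)
    codes_n = tp_codes[neigh]
    for t in range(len(tp_labels)):
        nn_tp[:, t] = (codes_n == t).sum(axis=1)
    e_hat = nn_tp @ ratio_vec / k

    p = binomial_two_sided_pvalues(x, k, e_hat)
    q = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(
            e_hat > 0, o / np.where(e_hat > 0, e_hat, 1.0), np.where(x == 0, 1.0, np.inf)
        )

    table = pd.DataFrame(
        {
            "cell": meta["cell"] if "cell" in meta.columns else meta.index.astype(str),
            "x": x,
            "o": o,
            "e_hat": e_hat,
            "p": p,
            "q": q,
            "level": level,
        }
    )
    for t, lab in enumerate(tp_labels):
        table[f"nn_{lab}"] = nn_tp[:, t]
    for col in ("timepoint", "condition", "celltype"):
        if col in meta.columns:
            table[col] = meta[col].to_numpy()
    return DAResult(table, ratios, config)


class DifferentialAbundance:
    """Model object: embedding + cell metadata -> per-cell DA results."""

    def __init__(self, embedding: np.ndarray, cell_meta: pd.DataFrame,
                 config: DAConfig | None = None):
        self.embedding = np.asarray(embedding, dtype=float)
        self.cell_meta = cell_meta
        self.config = config or DAConfig()

    def fit(self) -> DAResult:
        return knn_da_test(self.embedding, self.cell_meta, self.config)
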