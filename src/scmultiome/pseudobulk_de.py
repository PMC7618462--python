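"""Pseudobulk differential expression/accessibility between conditions.

For each cell type and condition, five pseudobulk replicates are built by
randomly sampling 40% of the group's cells (without replacement within a
replicate; replicates may overlap each other) and summing their counts.
Features are filtered on expression level (CPM) and cellular detection
rate, then tested per feature with a Welch two-sample test on replicate
log2-CPM values; a feature is called significant when |log2FC| > 0.5 and
BH-FDR < 0.05.  The same machinery applies unchanged to peak counts for
differential accessibility.

A caveat by construction: subsampled pseudobulk replicates of one cell pool
do not capture pool-level sampling noise, so the replicate-based p-values
understate biological variability; the |log2FC| gate is part of the
decision rule for exactly this reason.

``celltype_specific_logfc`` implements the chimera-style comparison of a
feature's per-cell-type log fold change against its average log fold change
across cell types (missing features enter the average as logFC 0), with a
z-test of the deviation against the across-type spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReplicateSet",
    "make_replicates",
    "filter_features",
    "de_test",
    "celltype_specific_logfc",
    "PseudobulkDE",
    "DEResults",
]


@dataclass
class ReplicateSet:
    """Pseudobulk replicate count matrix for one (cell type x condition) group."""

    counts: np.ndarray  # features x n_reps
    sampled_cells: list[np.ndarray]  # per replicate, indices into the group
    group: str
    seed: int

    @property
    def n_reps(self) -> int:
        return self.counts.shape[1]


def make_replicates(counts, cell_indices, n_reps: int = 5, frac: float = 0.4,
                    seed: int = 0, group: str = "") -> ReplicateSet:
    """Build ``n_reps`` pseudobulk replicates from one group of cells.

    Each replicate sums the counts of ``round(frac * group size)`` cells
    sampled without replacement; different replicates are sampled
    independently and may share cells.
    """
    cell_indices = np.asarray(cell_indices, dtype=int)
    m = len(cell_indices)
    if m < int(np.ceil(1.0 / frac)):
        raise ValueError(
            f"group {group or cell_indices[:3]!r} too small for frac={frac} "
            f"({m} cells, need >= {int(np.ceil(1.0 / frac))})"
        )
    size = int(round(frac * m))
    rng = np.random.default_rng(seed)
    X = counts.tocsc() if sparse.issparse(counts) else np.asarray(counts)
    out = np.empty((counts.shape[0], n_reps), dtype=np.int64)
    sampled = []
    for r in range(n_reps):
        take = cell_indices[rng.choice(m, size=size, replace=False)]
        sampled.append(np.sort(take))
        out[:, r] = np.asarray(X[:, take].sum(axis=1)).ravel()
    return ReplicateSet(out, sampled, group=group, seed=seed)


def _cpm(mat: np.ndarray) -> np.ndarray:
    lib = mat.sum(axis=0, keepdims=True).astype(float)
    if np.any(lib == 0):
        raise ValueError("replicate with zero library size")
    return mat / lib * 1e6


def filter_features(replicate_sets, counts, group_cells, feature_names,
                    min_cpm: float = 1.0, min_detected_fraction: float = 0.05,
                    exclusion=None) -> np.ndarray:
    """Boolean mask of features passing expression/detection thresholds.

    A feature is retained iff its CPM is >= ``min_cpm`` in at least half of
    all replicates (pooled over the supplied replicate sets), it is detected
    (count > 0) in >= ``min_detected_fraction`` of the group's cells, and it
    survives the optional name-based exclusion rules.
    """
    reps = np.hstack([rs.counts for rs in replicate_sets])
    cpm = _cpm(reps)
    expr_ok = (cpm >= min_cpm).sum(axis=1) >= int(np.ceil(reps.shape[1] / 2))

    cells = np.asarray(group_cells, dtype=int)
    X = counts.tocsc() if sparse.issparse(counts) else np.asarray(counts)
    sub = X[:, cells]
    det = np.asarray((sub > 0).sum(axis=1)).ravel()
    det_ok = det >= min_detected_fraction * len(cells)

    keep = expr_ok & det_ok
    if exclusion is not None:
        names = np.asarray(feature_names, dtype=object)
        keep &= np.array([not exclusion.excludes(n) for n in names])
    return keep


def de_test(kd_replicates: ReplicateSet, wt_replicates: ReplicateSet,
            feature_names, logfc_min: float = 0.5, fdr_max: float = 0.05) -> pd.DataFrame:
    """Per-feature differential test between two replicate sets (KD vs WT).

    log2FC is the difference of mean log2(CPM + 1) (KD minus WT); p-values
    come from a Welch two-sample test on the replicate log2-CPM values.
    """
    if kd_replicates.n_reps < 2 or wt_replicates.n_reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    a = np.log2(_cpm(kd_replicates.counts) + 1.0)
    b = np.log2(_cpm(wt_replicates.counts) + 1.0)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p undefined; identical means are null
    nanmask = ~np.isfinite(p)
    p[nanmask] = np.where(np.isclose(logfc[nanmask], 0.0), 1.0, 0.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature": np.asarray(feature_names),
            "logfc": logfc,
            "p": p,
            "fdr": fdr,
        }
    )
    out["significant"] = (np.abs(out["logfc"]) > logfc_min) & (out["fdr"] < fdr_max)
    return out


def celltype_specific_logfc(logfc_by_celltype: pd.DataFrame,
                            logfc_min: float = 0.5, fdr_max: float = 0.05) -> pd.DataFrame:
    """Deviation of each cell type's logFC from the across-type average.

    ``logfc_by_celltype`` is features x cell types; missing entries (a
    feature filtered out in one cell type) are set to logFC 0 before
    averaging.  The deviation is z-tested against the across-type standard
    deviation of that feature's logFCs; significance uses the |deviation| >
    ``logfc_min`` and FDR < ``fdr_max`` rule.
    """
    if logfc_by_celltype.shape[1] < 3:
        raise ValueError("need logFC for >= 3 cell types")
    L = logfc_by_celltype.fillna(0.0)
    mean = L.mean(axis=1)
    dev = L.sub(mean, axis=0)
    spread = L.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev.div(spread.replace(0.0, np.nan), axis=0)
    p = pd.DataFrame(
        2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=z.index, columns=z.columns
    ).fillna(1.0)
    long = (
        dev.stack().rename("deviation").to_frame()
        .join(p.stack().rename("p"))
        .reset_index()
        .rename(columns={"level_0": "feature", "level_1": "celltype"})
    )
    long["fdr"] = multipletests(long["p"].to_numpy(), method="fdr_bh")[1]
    long["significant"] = (long["deviation"].abs() > logfc_min) & (long["fdr"] < fdr_max)
    return long


@dataclass
class DEResults:
    """Per-cell-type DE tables plus the replicate bookkeeping behind them."""

    tables: dict[str, pd.DataFrame]  # cell type -> DE table
    replicate_sets: dict[tuple[str, str], ReplicateSet]  # (celltype, condition)
    group_sizes: dict[tuple[str, str], int]

    def combined(self) -> pd.DataFrame:
        parts = []
        for ct, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "celltype", ct)
            parts.append(t)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    def logfc_matrix(self) -> pd.DataFrame:
        """Features x cell types logFC matrix (NaN where untested)."""
        cols = {ct: tab.set_index("feature")["logfc"] for ct, tab in self.tables.items()}
        return pd.DataFrame(cols)

    def celltype_specific(self, logfc_min: float = 0.5, fdr_max: float = 0.05) -> pd.DataFrame:
        return celltype_specific_logfc(self.logfc_matrix(), logfc_min, fdr_max)

    def summary(self) -> str:
        lines = ["Pseudobulk differential expression (KD vs WT)"]
        for ct, tab in self.tables.items():
            n_sig = int(tab["significant"].sum())
            up = int((tab["significant"] & (tab["logfc"] > 0)).sum())
            lines.append(
                f"  {ct:<10s} features tested: {len(tab):5d}   "
                f"significant: {n_sig:4d} ({up} up, {n_sig - up} down)"
            )
        return "\n".join(lines)


class PseudobulkDE:
    """Model object: counts + metadata -> per-cell-type differential tables.

    Parameters
    ----------
    counts
        Features x cells matrix (RNA genes or ATAC peaks).
    cell_meta
        Per-cell table with ``groupby`` (cell type) and ``condition_col``.
    contrast
        Pair (test condition, reference condition); logFC is test minus
        reference.
    """

    def __init__(self, counts, cell_meta: pd.DataFrame, feature_names,
                 groupby: str = "celltype", condition_col: str = "condition",
                 contrast: tuple[str, str] = ("KD", "WT")):
        self.counts = counts
        self.cell_meta = cell_meta.reset_index(drop=True)
        self.feature_names = np.asarray(feature_names, dtype=object)
        self.groupby = groupby
        self.condition_col = condition_col
        self.contrast = contrast

    def fit(self, n_reps: int = 5, frac: float = 0.4, seed: int = 0,
            min_cpm: float = 1.0, min_detected_fraction: float = 0.05,
            exclusion=None, min_cells: int = 10) -> DEResults:
        test, ref = self.contrast
        tables = {}
        rep_sets = {}
        sizes = {}
        celltypes = sorted(self.cell_meta[self.groupby].unique())
        for i, ct in enumerate(celltypes):
            in_ct = self.cell_meta[self.groupby] == ct
            idx_test = np.flatnonzero(in_ct & (self.cell_meta[self.condition_col] == test))
            idx_ref = np.flatnonzero(in_ct & (self.cell_meta[self.condition_col] == ref))
            sizes[(ct, test)] = len(idx_test)
            sizes[(ct, ref)] = len(idx_ref)
            if len(idx_test) < min_cells or len(idx_ref) < min_cells:
                continue
            rs_test = make_replicates(
                self.counts, idx_test, n_reps, frac, seed=seed * 1000 + 2 * i,
                group=f"{ct}/{test}",
            )
            rs_ref = make_replicates(
                self.counts, idx_ref, n_reps, frac, seed=seed * 1000 + 2 * i + 1,
                group=f"{ct}/{ref}",
            )
            rep_sets[(ct, test)] = rs_test
            rep_sets[(ct, ref)] = rs_ref
            keep = filter_features(
                [rs_test, rs_ref], self.counts,
                np.concatenate([idx_test, idx_ref]), self.feature_names,
                min_cpm=min_cpm, min_detected_fraction=min_detected_fraction,
                exclusion=exclusion,
            )
            tab = de_test(
                ReplicateSet(rs_test.counts[keep], rs_test.sampled_cells, rs_test.group, rs_test.seed),
                ReplicateSet(rs_ref.counts[keep], rs_ref.sampled_cells, rs_ref.group, rs_ref.seed),
                self.feature_names[keep],
            )
            tables[ct] = tab
        return DEResults(tables, rep_sets, sizes)
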