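"""In-silico ChIP: TF occupancy prediction from paired pseudobulk profiles.

For every transcription factor, the Pearson correlation across pseudobulk
clusters between the TF's log-normalized expression and the log-normalized
accessibility of each peak carrying its motif is scaled by the min-max
normalized product of the peak's motif score and its maximum normalized
accessibility over clusters:

    score(tf, peak) = corr(tf, peak) * minmax_tf(motif_score * a(peak))

with a(peak) the peak's maximum pseudobulk accessibility over clusters
divided by the global maximum over all peaks and clusters (an alternative
per-peak reading is switchable).  The min-max runs over the motif-containing
peaks of each TF by default, so scores are comparable within a TF.  Peaks
with score > tau (default 0.2) are called bound; TFs with fewer than 40
bound peaks are flagged for exclusion from downstream TF-activity analyses.

The module also provides one-vs-rest marker detection (rank-sum test with
the FDR <= 0.1 & log2FC >= 0.5 cutoff), hypergeometric motif enrichment of
marker peaks against a background, and genomic interval overlap with a
minimum-overlap requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PseudobulkProfiles",
    "BindingScoreMatrix",
    "pseudobulk",
    "tf_peak_correlation",
    "binding_scores",
    "marker_features",
    "motif_enrichment",
    "overlap_peaks",
    "InSilicoChip",
]


@dataclass
class PseudobulkProfiles:
    """Cluster-aggregated, CPM-log-normalized feature profiles."""

    values: pd.DataFrame  # features x clusters
    cluster_sizes: pd.Series

    @property
    def clusters(self) -> list:
        return list(self.values.columns)


def pseudobulk(counts, cluster_assignment, feature_names=None) -> PseudobulkProfiles:
    """Sum counts per cluster, then ``ln(sum / cluster_total * 1e6 + 1)``.

    ``counts`` is features x cells; every cell must belong to exactly one
    cluster and no cluster may be empty.
    """
    clusters = np.asarray(cluster_assignment)
    if counts.shape[1] != len(clusters):
        raise ValueError("cluster assignment length does not match cell count")
    uniq = pd.unique(clusters)
    X = counts.tocsc() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    sums = np.empty((counts.shape[0], len(uniq)))
    sizes = {}
    for j, cl in enumerate(uniq):
        cols = np.flatnonzero(clusters == cl)
        if len(cols) == 0:
            raise ValueError(f"cluster {cl!r} has no cells")
        sizes[cl] = int(len(cols))
        sums[:, j] = np.asarray(X[:, cols].sum(axis=1)).ravel()
    totals = sums.sum(axis=0)
    if np.any(totals == 0):
        bad = uniq[totals == 0][0]
        raise ValueError(f"cluster {bad!r} has zero total counts")
    vals = np.log(sums / totals * 1e6 + 1.0)
    if feature_names is None:
        feature_names = np.arange(counts.shape[0])
    df = pd.DataFrame(vals, index=np.asarray(feature_names), columns=uniq)
    return PseudobulkProfiles(df, pd.Series(sizes))


def _pearson_rows(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlation of each row of A with y; zero-variance rows give 0."""
    Ac = A - A.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Ac**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def tf_peak_correlation(profiles_expr: pd.DataFrame, profiles_acc: pd.DataFrame,
                        tf: str, motif_matches: pd.DataFrame) -> pd.Series:
    """Across-cluster Pearson correlation of a TF with its motif peaks.

    Degenerate (zero-variance) vectors yield correlation 0 by convention so
    a genome-wide run never aborts on a flat peak.
    """
    if profiles_expr.shape[1] < 3:
        raise ValueError("need >= 3 pseudobulk clusters for correlation")
    if tf not in profiles_expr.index:
        raise ValueError(f"TF {tf!r} absent from expression profiles")
    peaks = motif_matches.loc[motif_matches["tf"] == tf, "peak"].to_numpy()
    peaks = np.asarray(pd.Index(peaks).intersection(profiles_acc.index), dtype=object)
    y = profiles_expr.loc[tf].to_numpy(dtype=float)
    A = profiles_acc.loc[peaks].to_numpy(dtype=float)
    return pd.Series(_pearson_rows(A, y), index=peaks, name=tf)


@dataclass
class BindingScoreMatrix:
    """Long-format scores per (TF, motif-containing peak) plus TF summaries."""

    table: pd.DataFrame  # tf, peak, correlation, scaled_product, score, bound
    tau: float
    min_bound: int
    tf_summary: pd.DataFrame = field(default=None)  # bound_peaks, retained

    def __post_init__(self):
        if self.tf_summary is None:
            counts = self.table.groupby("tf", sort=True)["bound"].sum().astype(int)
            self.tf_summary = pd.DataFrame(
                {"bound_peaks": counts, "retained": counts >= self.min_bound}
            )

    @property
    def bound_pairs(self) -> set[tuple[str, str]]:
        b = self.table[self.table["bound"]]
        return set(zip(b["tf"], b["peak"]))

    def retained_tfs(self) -> list[str]:
        return list(self.tf_summary.index[self.tf_summary["retained"]])

    def score_pivot(self) -> pd.DataFrame:
        """TF x peak score matrix; entries without a motif match are NaN."""
        return self.table.pivot(index="tf", columns="peak", values="score")

    def summary(self) -> str:
        n_tf = self.tf_summary.shape[0]
        lines = [
            "In-silico ChIP binding scores",
            f"  TF-peak motif pairs scored: {len(self.table)}",
            f"  bound (score > {self.tau}): {int(self.table['bound'].sum())}",
            f"  TFs: {n_tf}; retained (>= {self.min_bound} bound peaks): "
            f"{int(self.tf_summary['retained'].sum())}",
        ]
        return "\n".join(lines)


def binding_scores(correlations: dict[str, pd.Series] | pd.DataFrame,
                   motif_matches: pd.DataFrame,
                   profiles_acc: pd.DataFrame,
                   tau: float = 0.2,
                   min_bound: int = 40,
                   minmax_axis: str = "per_tf",
                   accessibility_mode: str = "global") -> BindingScoreMatrix:
    """Combine correlations, motif scores and accessibility into binding scores.

    Parameters
    ----------
    correlations
        Mapping TF -> Series of per-peak correlations (as produced by
        :func:`tf_peak_correlation`).
    accessibility_mode
        ``"global"``: a(peak) = max-over-clusters accessibility divided by
        the global maximum over all peaks and clusters (default).
        ``"per_peak"``: the peak's profile is scaled by its own maximum, so
        the accessibility term is identically 1 and only the motif score
        enters the product.
    minmax_axis
        ``"per_tf"`` (default) rescales the motif x accessibility product to
        [0, 1] over each TF's motif-containing peaks; ``"global"`` rescales
        over all pairs at once.
    """
    if accessibility_mode not in ("global", "per_peak"):
        raise ValueError("accessibility_mode must be 'global' or 'per_peak'")
    if minmax_axis not in ("per_tf", "global"):
        raise ValueError("minmax_axis must be 'per_tf' or 'global'")
    if isinstance(correlations, pd.DataFrame):
        correlations = {
            tf: correlations.loc[tf].dropna() for tf in correlations.index
        }

    acc_max = profiles_acc.max(axis=1)
    global_max = float(acc_max.max()) if len(acc_max) else 1.0
    score_lookup = motif_matches.set_index(["tf", "peak"])["score"]

    rows = []
    for tf in sorted(correlations):
        corr = correlations[tf]
        for peak in corr.index:
            a = float(acc_max.get(peak, 0.0))
            if accessibility_mode == "global":
                a = a / global_max if global_max > 0 else 0.0
            else:
                a = 1.0 if a > 0 else 0.0
            ms = float(score_lookup.loc[(tf, peak)])
            rows.append((tf, peak, float(corr.loc[peak]), ms * a))
    table = pd.DataFrame(rows, columns=["tf", "peak", "correlation", "product"])

    def _minmax(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            # single peak (or all products equal): min-max undefined -> 1
            return np.ones_like(x)
        return (x - lo) / (hi - lo)

    if len(table):
        if minmax_axis == "per_tf":
            table["scaled_product"] = table.groupby("tf")["product"].transform(
                lambda s: _minmax(s.to_numpy())
            )
        else:
            table["scaled_product"] = _minmax(table["product"].to_numpy())
    else:
        table["scaled_product"] = []
    table["score"] = table["correlation"] * table["scaled_product"]
    table["bound"] = table["score"] > tau
    table = table.drop(columns=["product"])
    return BindingScoreMatrix(table, tau=tau, min_bound=min_bound)


class InSilicoChip:
    """Model object: pseudobulk profiles + motif matches -> binding scores.

    Parameters
    ----------
    expression, accessibility
        Pseudobulk profiles (features x clusters) as returned by
        :func:`pseudobulk`, or raw count matrices plus ``clusters`` to
        aggregate here.
    motif_matches
        DataFrame with columns ``peak``, ``tf``, ``score`` (>= 0).
    """

    def __init__(self, expression, accessibility, motif_matches: pd.DataFrame,
                 clusters=None, gene_names=None, peak_names=None):
        if clusters is not None:
            expression = pseudobulk(expression, clusters, gene_names).values
            accessibility = pseudobulk(accessibility, clusters, peak_names).values
        elif isinstance(expression, PseudobulkProfiles):
            expression = expression.values
            accessibility = accessibility.values
        self.expression = expression
        self.accessibility = accessibility
        self.motif_matches = motif_matches

    def fit(self, tau: float = 0.2, min_bound: int = 40,
            minmax_axis: str = "per_tf",
            accessibility_mode: str = "global") -> BindingScoreMatrix:
        tfs = [t for t in pd.unique(self.motif_matches["tf"]) if t in self.expression.index]
        corrs = {
            tf: tf_peak_correlation(self.expression, self.accessibility, tf, self.motif_matches)
            for tf in tfs
        }
        return binding_scores(
            corrs, self.motif_matches, self.accessibility,
            tau=tau, min_bound=min_bound, minmax_axis=minmax_axis,
            accessibility_mode=accessibility_mode,
        )


def marker_features(values, group_labels, feature_names=None,
                    fdr_max: float = 0.1, log2fc_min: float = 0.5) -> pd.DataFrame:
    """One-vs-rest rank-sum markers per group.

    ``values`` is features x cells (normalized expression or accessibility).
    Returns a long table with per-(group, feature) log2 fold change of the
    group mean vs the rest mean (pseudocount 1), rank-sum p, BH-FDR within
    group, and the marker call at FDR <= ``fdr_max`` and log2FC >=
    ``log2fc_min``.
    """
    groups = np.asarray(group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for marker detection")
    X = values.toarray() if sparse.issparse(values) else np.asarray(values, dtype=float)
    if feature_names is None:
        feature_names = np.arange(X.shape[0])
    out = []
    for g in uniq:
        mask = groups == g
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        a, b = X[:, mask], X[:, ~mask]
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0
        lfc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
        fdr = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "group": g,
                "feature": np.asarray(feature_names),
                "log2fc": lfc,
                "p": p,
                "fdr": fdr,
            }
        )
        df["marker"] = (df["fdr"] <= fdr_max) & (df["log2fc"] >= log2fc_min)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def motif_enrichment(marker_peaks, background_peaks, motif_matches: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of TF motifs in marker peaks.

    Draws ``|marker|`` peaks from ``|background|``; for each TF the number
    of motif-containing peaks in the marker set is tested against the
    background count.  A TF with zero background hits gets a null fold and
    p = 1.
    """
    marker = pd.Index(pd.unique(np.asarray(marker_peaks, dtype=object)))
    background = pd.Index(pd.unique(np.asarray(background_peaks, dtype=object)))
    if not marker.isin(background).all():
        raise ValueError("marker peaks must be a subset of the background")
    N, n = len(background), len(marker)
    rows = []
    for tf, sub in motif_matches.groupby("tf", sort=True):
        with_motif = pd.Index(pd.unique(sub["peak"])).intersection(background)
        K = len(with_motif)
        k = len(with_motif.intersection(marker))
        if K == 0:
            rows.append((tf, k, n, K, N, np.nan, 1.0))
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else np.nan
        rows.append((tf, k, n, K, N, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["tf", "marker_hits", "marker_size", "background_hits",
                 "background_size", "fold", "p"],
    )
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out


def _check_intervals(df: pd.DataFrame, which: str) -> pd.DataFrame:
    need = {"chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"interval set {which} needs columns {sorted(need)}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"malformed interval in {which}: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return df


def overlap_peaks(set_a: pd.DataFrame, set_b: pd.DataFrame, min_overlap: int = 100) -> pd.DataFrame:
    """Pairs (index_a, index_b) overlapping by >= ``min_overlap`` bases.

    Intervals are 0-based half-open on named chromosomes.
    """
    a = _check_intervals(set_a.reset_index(drop=True), "a")
    b = _check_intervals(set_b.reset_index(drop=True), "b")
    pairs = []
    for chrom, ai in a.groupby("chrom", sort=True):
        bi = b[b["chrom"] == chrom]
        if bi.empty:
            continue
        bs = bi["start"].to_numpy()
        be = bi["end"].to_numpy()
        bidx = bi.index.to_numpy()
        order = np.argsort(bs, kind="stable")
        bs, be, bidx = bs[order], be[order], bidx[order]
        for ia, s, e in zip(ai.index, ai["start"].to_numpy(), ai["end"].to_numpy()):
            # candidates must start before the latest admissible position
            hi = np.searchsorted(bs, e - min_overlap, side="right")
            ov = np.minimum(e, be[:hi]) - np.maximum(s, bs[:hi])
            for j in np.flatnonzero(ov >= min_overlap):
                pairs.append((ia, int(bidx[j]), int(ov[j])))
    out = pd.DataFrame(pairs, columns=["index_a", "index_b", "overlap"])
    return out.sort_values(["index_a", "index_b"], ignore_index=True)
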