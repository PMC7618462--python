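"""Cell- and gene-level quality filters.

All thresholds follow the published filtering rules for droplet multiome
data: open intervals on log10 read counts and detected genes, upper bounds
on mitochondrial and ribosomal read percentages and on the doublet score for
the RNA modality; a TSS-enrichment window, a minimum fragment count and a
maximum blacklist-region fraction for the ATAC modality.  Every printed
">" / "<" is treated as a strict inequality, so boundary values are
excluded.  A ``chimera`` profile carries the stricter thresholds used for
chimera scRNA-seq.

Gene exclusion removes non-informative and batch-prone genes by name
pattern (starting or ending with Rik, Mt, Rps, Rpl, Gm — plus lowercase
"mt-" mitochondrial symbols, see :class:`GeneExclusionRules`) and by
explicit lists (haemoglobin genes, imprinted Grb10/Nnat; the chimera
profile additionally drops Xist, Tsix, Y-linked genes and the tdTomato
transgene).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "GeneExclusionRules",
    "compute_qc_metrics",
    "filter_cells_rna",
    "filter_cells_atac",
    "flag_doublets",
    "exclude_genes",
]

HAEMOGLOBIN_GENES = (
    "Hba-a1", "Hba-a2", "Hba-x", "Hbb-bh1", "Hbb-bs", "Hbb-bt", "Hbb-y",
)
IMPRINTED_GENES = ("Grb10", "Nnat")
Y_CHROMOSOME_GENES = ("Ddx3y", "Eif2s3y", "Uty", "Kdm5d")
SEX_GENES = ("Xist", "Tsix")


@dataclass(frozen=True)
class QCThresholds:
    """Filtering thresholds; intervals are open (strict inequalities)."""

    rna_log10_reads: tuple[float, float] = (3.0, 5.0)
    rna_genes: tuple[float, float] = (2500.0, 12000.0)
    rna_mito_pct_max: float = 25.0
    rna_ribo_pct_max: float = 30.0
    doublet_score_max: float = 1.25
    atac_tss: tuple[float, float] = (9.0, 35.0)
    atac_min_frags: float = 3500.0
    atac_blacklist_frac_max: float = 0.05

    def __post_init__(self):
        for name in ("rna_log10_reads", "rna_genes", "atac_tss"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"QCThresholds.{name}: lower bound must be < upper bound")
        for name in ("rna_mito_pct_max", "rna_ribo_pct_max"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"QCThresholds.{name} must be a percentage in [0, 100]")

    @classmethod
    def chimera(cls) -> "QCThresholds":
        return cls(
            rna_log10_reads=(3.5, 5.0),
            rna_genes=(1500.0, 10000.0),
            rna_mito_pct_max=5.0,
            rna_ribo_pct_max=35.0,
            doublet_score_max=0.5,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        d = dict(d)
        for name in ("rna_log10_reads", "rna_genes", "atac_tss"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass(frozen=True)
class GeneExclusionRules:
    """Name-based gene exclusion; patterns are case-sensitive as printed.

    ``Mt`` matches capitalized symbols as printed; lowercase ``mt-``
    mitochondrial symbols are additionally matched because mouse
    nomenclature uses the lowercase prefix and removing mitochondrial genes
    is the evident intent (both are on by default, configurable).
    """

    name_prefixes: tuple[str, ...] = ("Rik", "Mt", "Rps", "Rpl", "Gm", "mt-")
    name_suffixes: tuple[str, ...] = ("Rik", "Mt", "Rps", "Rpl", "Gm")
    explicit_genes: frozenset[str] = frozenset(HAEMOGLOBIN_GENES + IMPRINTED_GENES)

    def __post_init__(self):
        if any(not p for p in self.name_prefixes) or any(not s for s in self.name_suffixes):
            raise ValueError("exclusion patterns must be non-empty strings")

    @classmethod
    def chimera(cls) -> "GeneExclusionRules":
        extra = SEX_GENES + Y_CHROMOSOME_GENES + ("tdTomato",)
        return cls(
            explicit_genes=frozenset(HAEMOGLOBIN_GENES + IMPRINTED_GENES + extra)
        )

    def excludes(self, name: str) -> bool:
        if name in self.explicit_genes:
            return True
        if any(name.startswith(p) for p in self.name_prefixes):
            return True
        return any(name.endswith(s) for s in self.name_suffixes)

    def apply(self, names: Sequence[str]) -> list[str]:
        return [n for n in names if not self.excludes(n)]


def exclude_genes(gene_names: Sequence[str], rules: GeneExclusionRules | None = None) -> list[str]:
    """Retained gene names after pattern/explicit exclusion, order preserved."""
    if len(gene_names) == 0:
        raise ValueError("gene name list is empty")
    return (rules or GeneExclusionRules()).apply(gene_names)


def compute_qc_metrics(dataset, mito_genes: Iterable[str] | None = None,
                       ribo_genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-cell QC metrics computed from realized RNA counts.

    Returns log10 total reads (``-inf`` and a ``zero_reads`` flag for empty
    cells), detected genes, mitochondrial and ribosomal read percentages,
    with the ATAC metrics (and doublet score) passed through from the cell
    metadata when present.  Default mito/ribo gene sets are the ``mt-`` and
    ``Rps``/``Rpl`` name-prefix matches.
    """
    names = np.asarray(dataset.gene_names, dtype=object)
    if mito_genes is None:
        mito_mask = np.array([n.startswith("mt-") for n in names])
    else:
        mito_genes = set(mito_genes)
        unknown = mito_genes - set(names)
        if unknown:
            raise ValueError(f"mito_genes not in gene_meta: {sorted(unknown)[:3]}")
        mito_mask = np.array([n in mito_genes for n in names])
    if ribo_genes is None:
        ribo_mask = np.array([n.startswith(("Rps", "Rpl")) for n in names])
    else:
        ribo_genes = set(ribo_genes)
        unknown = ribo_genes - set(names)
        if unknown:
            raise ValueError(f"ribo_genes not in gene_meta: {sorted(unknown)[:3]}")
        ribo_mask = np.array([n in ribo_genes for n in names])

    X = dataset.rna_counts.tocsc()
    total = np.asarray(X.sum(axis=0)).ravel().astype(float)
    detected = np.asarray((X > 0).sum(axis=0)).ravel().astype(int)
    mito = np.asarray(X[mito_mask, :].sum(axis=0)).ravel().astype(float)
    ribo = np.asarray(X[ribo_mask, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log10_reads = np.where(total > 0, np.log10(np.maximum(total, 1e-300)), -np.inf)
        pct_mito = np.where(total > 0, 100.0 * mito / total, 0.0)
        pct_ribo = np.where(total > 0, 100.0 * ribo / total, 0.0)

    out = pd.DataFrame(
        {
            "cell": dataset.cell_meta["cell"].to_numpy(),
            "log10_reads": log10_reads,
            "n_genes": detected,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "zero_reads": total == 0,
        }
    )
    for col in ("doublet_score", "tss_enrichment", "n_fragments", "blacklist_fraction"):
        if col in dataset.cell_meta.columns:
            out[col] = dataset.cell_meta[col].to_numpy()
    return out


_RNA_COLUMNS = ("log10_reads", "n_genes", "pct_mito", "pct_ribo")
_ATAC_COLUMNS = ("tss_enrichment", "n_fragments", "blacklist_fraction")


def _require(metrics: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table is missing required column(s): {missing}")


def filter_cells_rna(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Index:
    """Cells passing all RNA criteria (every inequality strict)."""
    t = thresholds or QCThresholds()
    _require(metrics, _RNA_COLUMNS)
    lo_r, hi_r = t.rna_log10_reads
    lo_g, hi_g = t.rna_genes
    keep = (
        (metrics["log10_reads"] > lo_r)
        & (metrics["log10_reads"] < hi_r)
        & (metrics["n_genes"] > lo_g)
        & (metrics["n_genes"] < hi_g)
        & (metrics["pct_mito"] < t.rna_mito_pct_max)
        & (metrics["pct_ribo"] < t.rna_ribo_pct_max)
    )
    return metrics.index[keep]


def filter_cells_atac(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Index:
    """Cells passing the ATAC criteria.

    TSS enrichment must lie strictly inside the window; fragment count is
    a >= minimum and blacklist fraction a <= maximum.
    """
    t = thresholds or QCThresholds()
    _require(metrics, _ATAC_COLUMNS)
    lo_t, hi_t = t.atac_tss
    keep = (
        (metrics["tss_enrichment"] > lo_t)
        & (metrics["tss_enrichment"] < hi_t)
        & (metrics["n_fragments"] >= t.atac_min_frags)
        & (metrics["blacklist_fraction"] <= t.atac_blacklist_frac_max)
    )
    return metrics.index[keep]


def flag_doublets(doublet_score, threshold: float = 1.25) -> np.ndarray:
    """True where score is strictly greater than the threshold."""
    scores = np.asarray(doublet_score, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("doublet scores must be finite")
    return scores > threshold
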