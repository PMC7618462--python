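"""Synthetic paired RNA+ATAC multiome generator with planted structure.

Emulates the statistical design of an embryoid-body differentiation multiome
experiment: cells sampled at 12-hour intervals (day 3 to day 5), two genetic
conditions (wild type and knockdown), discrete cell types with type-specific
marker genes and peaks, TF->peak regulatory links that couple a transcription
factor's expression to the accessibility of its target peaks, planted
condition-specific lineage depletion, and a planted low-quality/doublet
subpopulation for QC filters to remove.  A matching labelled reference atlas
is drawn from the same generative model so that label transfer can be scored
against ground truth.

Counts follow a negative-binomial model: for cell ``c`` of type ``t`` and
feature ``g``, ``count ~ NB(mean = depth_c * pi[g, t], size = theta)`` where
``pi[:, t]`` is the type's normalized mean profile and ``depth_c`` is a
lognormal per-cell sequencing depth.  Setting ``nb_dispersion = 0`` disables
sampling noise (counts are rounded means), which is useful for degenerate
archetype references.

Every random choice is derived from ``SimConfig.seed`` through independent
named streams, so e.g. enlarging the gene panel does not perturb cell-type
assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimConfig",
    "MultiomeDataset",
    "GroundTruth",
    "ReferenceAtlas",
    "simulate_multiome",
    "simulate_reference_atlas",
]

# fixed offsets mixed with the master seed to give independent streams
_STREAMS = {
    "model": 11,
    "cells": 23,
    "rna": 37,
    "atac": 53,
    "qcmeta": 71,
    "atlas": 89,
}

_DEFAULT_TIMEPOINTS = ("D3", "D3.5", "D4", "D4.5", "D5")
_STAGES = ("E6.5", "E7.0", "E7.25", "E7.5", "E7.75", "E8.0", "E8.25", "E8.5")

_MITO_GENES = ("mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Cytb", "mt-Atp6")
_RIBO_GENES = tuple(f"Rps{i}" for i in range(1, 6)) + tuple(f"Rpl{i}" for i in range(1, 6))
_DECOY_EXCLUDED = ("Gm10073", "1700012A03Rik", "Hba-a1", "Hbb-bs", "Grb10", "Nnat")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Sizes (``n_cells`` .. ``n_celltypes``) are desk-scale by default; the
    structural parameters (timepoints, knockdown fraction, depletion,
    regulatory effect sizes, noise levels) are the study conditions and are
    not meant to be tuned per run.
    """

    n_cells: int = 3000
    n_genes: int = 1000
    n_peaks: int = 2500
    n_tfs: int = 40
    n_celltypes: int = 12
    timepoints: Sequence[str] = _DEFAULT_TIMEPOINTS
    kd_fraction_per_timepoint: float | Mapping[str, float] = 0.5
    #: cell-type index -> depletion factor f in (0, 1]; in the knockdown the
    #: type's composition probability is multiplied by f (mass redistributed
    #: over the remaining types), so the KD:WT composition ratio converges to f.
    depleted_celltypes: dict[int, float] = field(default_factory=dict)
    #: explicit (tf_index, peak_index, effect>=0) links; None plants
    #: ``n_links_per_tf`` links per TF with effect ``link_effect`` plus an
    #: equal number of decoy motif matches.
    regulatory_links: list[tuple[int, int, float]] | None = None
    n_links_per_tf: int = 12
    link_effect: float = 1.5
    rna_depth_lognormal_params: tuple[float, float] = (np.log(1e4), 0.35)
    atac_depth_lognormal_params: tuple[float, float] = (np.log(1.5e4), 0.45)
    nb_dispersion: float = 2.0
    #: planted differential expression: (gene_index, celltype_index, log2fc)
    #: applied to KD cells of that type.
    de_genes: list[tuple[int, int, float]] = field(default_factory=list)
    marker_genes_per_type: int = 25
    marker_log2fc: float = 3.0
    tf_log2fc: float = 3.0
    peak_type_sigma: float = 0.3
    low_quality_fraction: float = 0.05
    doublet_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_peaks", "n_tfs", "n_celltypes"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"SimConfig.{name} must be a positive integer")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("SimConfig.timepoints must be unique labels")
        fracs = self._kd_fractions()
        for tp, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"SimConfig.kd_fraction_per_timepoint[{tp!r}] must be in [0, 1]"
                )
        for ct, f in self.depleted_celltypes.items():
            if not 0 <= int(ct) < self.n_celltypes:
                raise ValueError(f"SimConfig.depleted_celltypes: unknown cell type {ct}")
            if not 0.0 < float(f) <= 1.0:
                raise ValueError(
                    f"SimConfig.depleted_celltypes[{ct}] must be in (0, 1]"
                )
        if self.regulatory_links is not None:
            for tf, peak, eff in self.regulatory_links:
                if not 0 <= int(tf) < self.n_tfs:
                    raise ValueError(f"SimConfig.regulatory_links: unknown TF {tf}")
                if not 0 <= int(peak) < self.n_peaks:
                    raise ValueError(f"SimConfig.regulatory_links: unknown peak {peak}")
                if float(eff) < 0:
                    raise ValueError("SimConfig.regulatory_links: effect must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("SimConfig.nb_dispersion must be >= 0")
        n_special = self.n_tfs + len(_MITO_GENES) + len(_RIBO_GENES) + len(_DECOY_EXCLUDED)
        if self.n_genes < n_special + self.n_celltypes * self.marker_genes_per_type:
            raise ValueError(
                "SimConfig.n_genes too small for the requested TFs and markers "
                f"(need >= {n_special + self.n_celltypes * self.marker_genes_per_type})"
            )
        for g, ct, _ in self.de_genes:
            if not 0 <= int(g) < self.n_genes:
                raise ValueError(f"SimConfig.de_genes: unknown gene {g}")
            if not 0 <= int(ct) < self.n_celltypes:
                raise ValueError(f"SimConfig.de_genes: unknown cell type {ct}")

    def _kd_fractions(self) -> dict[str, float]:
        if isinstance(self.kd_fraction_per_timepoint, Mapping):
            return {tp: float(self.kd_fraction_per_timepoint.get(tp, 0.0)) for tp in self.timepoints}
        return {tp: float(self.kd_fraction_per_timepoint) for tp in self.timepoints}

    def to_json(self) -> str:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["depleted_celltypes"] = {str(k): v for k, v in self.depleted_celltypes.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["depleted_celltypes"] = {int(k): float(v) for k, v in d.get("depleted_celltypes", {}).items()}
        if d.get("regulatory_links") is not None:
            d["regulatory_links"] = [tuple(x) for x in d["regulatory_links"]]
        d["de_genes"] = [tuple(x) for x in d.get("de_genes", [])]
        d["timepoints"] = tuple(d["timepoints"])
        for k in ("rna_depth_lognormal_params", "atac_depth_lognormal_params"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class MultiomeDataset:
    """Paired counts plus annotations; matrices are features x cells CSR."""

    rna_counts: sparse.csr_matrix
    atac_counts: sparse.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    peak_meta: pd.DataFrame
    motif_matches: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[1]

    @property
    def gene_names(self) -> np.ndarray:
        return self.gene_meta["name"].to_numpy()

    @property
    def peak_names(self) -> np.ndarray:
        return self.peak_meta["name"].to_numpy()

    def validate(self) -> None:
        n = self.cell_meta.shape[0]
        if self.rna_counts.shape != (self.gene_meta.shape[0], n):
            raise ValueError("rna_counts shape inconsistent with gene/cell metadata")
        if self.atac_counts.shape != (self.peak_meta.shape[0], n):
            raise ValueError("atac_counts shape inconsistent with peak/cell metadata")
        if (self.peak_meta["start"] >= self.peak_meta["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
        if len(self.motif_matches) and (self.motif_matches["score"] < 0).any():
            raise ValueError("motif scores must be nonnegative")


@dataclass
class GroundTruth:
    celltype_per_cell: np.ndarray
    bound_pairs: set[tuple[str, str]]
    depleted_celltypes: dict[str, float]
    de_genes: list[tuple[str, str, float]]
    wt_composition: pd.DataFrame  # timepoints x cell types

    def to_json(self) -> str:
        return json.dumps(
            {
                "celltype_per_cell": list(map(str, self.celltype_per_cell)),
                "bound_pairs": sorted(map(list, self.bound_pairs)),
                "depleted_celltypes": self.depleted_celltypes,
                "de_genes": [list(x) for x in self.de_genes],
                "wt_composition": self.wt_composition.to_dict(orient="split"),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        comp = pd.DataFrame(
            d["wt_composition"]["data"],
            index=d["wt_composition"]["index"],
            columns=d["wt_composition"]["columns"],
        )
        return cls(
            celltype_per_cell=np.asarray(d["celltype_per_cell"], dtype=object),
            bound_pairs={tuple(x) for x in d["bound_pairs"]},
            depleted_celltypes={k: float(v) for k, v in d["depleted_celltypes"].items()},
            de_genes=[(g, ct, float(l)) for g, ct, l in d["de_genes"]],
            wt_composition=comp,
        )


@dataclass
class ReferenceAtlas:
    """Labelled log-normalized reference with a linear embedding."""

    expression: sparse.csr_matrix  # genes x reference cells, log-normalized
    gene_names: np.ndarray
    labels: np.ndarray
    stage: np.ndarray
    embedding: np.ndarray  # reference cells x d

    def validate(self) -> None:
        n = self.expression.shape[1]
        if not (len(self.labels) == len(self.stage) == self.embedding.shape[0] == n):
            raise ValueError("reference atlas annotation lengths inconsistent")


# ---------------------------------------------------------------------------
# model construction (shared between dataset and atlas so both draw cells
# from the same cell-type archetypes)
# ---------------------------------------------------------------------------


def _celltype_names(n: int) -> list[str]:
    return [f"CT{i:02d}" for i in range(n)]


def _build_model(config: SimConfig) -> dict:
    rng = _rng(config.seed, "model")
    n_g, n_p, n_ct, n_tf = config.n_genes, config.n_peaks, config.n_celltypes, config.n_tfs

    tf_names = [f"Tf{i:03d}" for i in range(n_tf)]
    special = list(_MITO_GENES) + list(_RIBO_GENES) + list(_DECOY_EXCLUDED)
    n_plain = n_g - n_tf - len(special)
    gene_names = np.array(
        tf_names + special + [f"Gene{i:05d}" for i in range(n_plain)], dtype=object
    )
    is_tf = np.zeros(n_g, dtype=bool)
    is_tf[:n_tf] = True

    base_gene = rng.lognormal(mean=0.0, sigma=1.0, size=n_g)
    mult = np.ones((n_g, n_ct))

    # type-specific marker blocks drawn from the plain genes
    plain_idx = np.arange(n_tf + len(special), n_g)
    marker_pool = rng.permutation(plain_idx)
    markers: dict[int, np.ndarray] = {}
    off = 0
    for ct in range(n_ct):
        block = marker_pool[off : off + config.marker_genes_per_type]
        off += config.marker_genes_per_type
        markers[ct] = block
        mult[block, ct] *= 2.0 ** config.marker_log2fc

    # each TF is highly expressed in a subset of types; this is the signal
    # in-silico ChIP correlates against
    n_active = max(1, n_ct // 4)
    tf_active = np.zeros((n_tf, n_ct), dtype=bool)
    for t in range(n_tf):
        act = rng.choice(n_ct, size=n_active, replace=False)
        tf_active[t, act] = True
        mult[t, act] *= 2.0 ** config.tf_log2fc

    mean_gene = base_gene[:, None] * mult  # genes x types

    # per-timepoint WT composition
    comp = rng.dirichlet(np.full(n_ct, 8.0), size=len(config.timepoints))

    # peaks
    chroms = np.array([f"chr{(i % 19) + 1}" for i in range(n_p)], dtype=object)
    starts = 10_000 + 1_000 * (np.arange(n_p) // 19)
    ends = starts + 600
    peak_names = np.array(
        [f"{c}:{s}-{e}" for c, s, e in zip(chroms, starts, ends)], dtype=object
    )

    base_peak = rng.lognormal(mean=0.0, sigma=1.0, size=n_p)
    jitter = rng.lognormal(mean=0.0, sigma=config.peak_type_sigma, size=(n_p, n_ct))
    mean_peak = base_peak[:, None] * jitter

    # regulatory links and motif matches
    if config.regulatory_links is None:
        per_tf = config.n_links_per_tf
        need = 2 * per_tf * n_tf
        if need > n_p:
            raise ValueError(
                "SimConfig.n_peaks too small for the planted links and decoys "
                f"(need >= {need})"
            )
        pool = rng.permutation(n_p)
        links = []
        decoy_rows = []
        off = 0
        for t in range(n_tf):
            linked = pool[off : off + per_tf]
            off += per_tf
            decoys = pool[off : off + per_tf]
            off += per_tf
            links.extend((t, int(pk), config.link_effect) for pk in linked)
            decoy_rows.extend((t, int(pk)) for pk in decoys)
    else:
        links = [(int(t), int(p), float(e)) for t, p, e in config.regulatory_links]
        linked_set = {(t, p) for t, p, _ in links}
        free = np.array([p for p in range(n_p) if all((t, p) not in linked_set for t in range(n_tf))])
        decoy_rows = []
        if len(links) and len(free):
            take = rng.choice(free, size=min(len(links), len(free)), replace=False)
            decoy_rows = [(links[i % len(links)][0], int(pk)) for i, pk in enumerate(take)]

    # TF activity profile (normalized to max 1) drives linked-peak accessibility
    tf_expr = mean_gene[:n_tf, :]
    tf_act = tf_expr / tf_expr.max(axis=1, keepdims=True)
    for t, pk, eff in links:
        mean_peak[pk, :] = mean_peak[pk, :] * np.exp(eff * tf_act[t])

    rows = []
    for t, pk, eff in links:
        score = rng.uniform(5.0, 10.0)  # upper half of the score range
        rows.append((peak_names[pk], tf_names[t], score, True))
    for t, pk in decoy_rows:
        rows.append((peak_names[pk], tf_names[t], rng.uniform(0.0, 10.0), False))
    motif_matches = pd.DataFrame(rows, columns=["peak", "tf", "score", "planted"])

    pi_gene = mean_gene / mean_gene.sum(axis=0, keepdims=True)
    pi_peak = mean_peak / mean_peak.sum(axis=0, keepdims=True)

    return {
        "gene_names": gene_names,
        "is_tf": is_tf,
        "tf_names": tf_names,
        "markers": markers,
        "pi_gene": pi_gene,
        "pi_peak": pi_peak,
        "comp": comp,
        "chroms": chroms,
        "starts": starts,
        "ends": ends,
        "peak_names": peak_names,
        "links": links,
        "motif_matches": motif_matches,
        "celltypes": np.array(_celltype_names(config.n_celltypes), dtype=object),
    }


def _kd_composition(comp_t: np.ndarray, depleted: Mapping[int, float]) -> np.ndarray:
    """Deplete types multiplicatively; redistribute the removed mass."""
    p = comp_t.copy()
    if not depleted:
        return p
    dep = np.array(sorted(depleted))
    keep_f = np.array([depleted[i] for i in dep])
    removed = float(np.sum(p[dep] * (1.0 - keep_f)))
    p[dep] = p[dep] * keep_f
    others = np.setdiff1d(np.arange(len(p)), dep)
    if len(others) and p[others].sum() > 0:
        p[others] = p[others] * (1.0 + removed / p[others].sum())
    return p / p.sum()


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, theta: float
) -> np.ndarray:
    if theta == 0:
        return np.rint(mu).astype(np.int32)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.int32)


def _sample_counts(
    rng: np.random.Generator,
    pi: np.ndarray,  # features x types
    depth: np.ndarray,  # per cell
    celltype_idx: np.ndarray,
    theta: float,
    pi_kd: np.ndarray | None = None,
    is_kd: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """NB counts assembled group-by-group (deterministic iteration order)."""
    n_feat = pi.shape[0]
    blocks: list[sparse.csc_matrix] = []
    cols: list[np.ndarray] = []
    conditions = [False, True] if is_kd is not None else [None]
    for ct in range(pi.shape[1]):
        for kd in conditions:
            if kd is None:
                idx = np.flatnonzero(celltype_idx == ct)
                prof = pi[:, ct]
            else:
                idx = np.flatnonzero((celltype_idx == ct) & (is_kd == kd))
                prof = (pi_kd if kd else pi)[:, ct]
            if len(idx) == 0:
                continue
            mu = prof[:, None] * depth[idx][None, :]
            blocks.append(sparse.csc_matrix(_nb_counts(rng, mu, theta)))
            cols.append(idx)
    if not blocks:
        return sparse.csr_matrix((n_feat, len(celltype_idx)), dtype=np.int32)
    mat = sparse.hstack(blocks, format="csc")
    order = np.argsort(np.concatenate(cols), kind="stable")
    return mat[:, order].tocsr()


# ---------------------------------------------------------------------------
# QC metadata
# ---------------------------------------------------------------------------


def _qc_metadata(
    rng: np.random.Generator,
    n: int,
    low_quality: np.ndarray,
    doublet: np.ndarray,
    rna_depth: np.ndarray,
    atac_depth: np.ndarray,
) -> pd.DataFrame:
    """Full-transcriptome-scale QC metrics.

    Detected-gene counts (and the ATAC metrics) are simulated at the scale of
    a real experiment rather than derived from the desk-scale count matrices,
    so that the published filtering thresholds apply unchanged; ranks are
    consistent with the realized per-cell depths.
    """
    lo = low_quality
    n_genes = np.where(
        lo,
        rng.lognormal(np.log(1000.0), 0.4, n),
        rng.lognormal(np.log(6000.0), 0.18, n),
    ).round().astype(int)
    pct_mito = 100 * np.where(lo, rng.beta(12, 12, n), rng.beta(2, 38, n))
    pct_ribo = 100 * rng.beta(15, 60, n)
    doublet_score = np.abs(rng.normal(0.0, 0.3, n))
    doublet_score[doublet] = rng.normal(2.0, 0.3, int(doublet.sum()))
    tss = np.where(lo, rng.normal(4.0, 1.5, n), rng.normal(16.0, 2.5, n))
    blacklist = np.where(lo, rng.beta(10, 90, n), rng.beta(2, 148, n))
    return pd.DataFrame(
        {
            "total_rna_reads": rna_depth.round().astype(int),
            "log10_reads": np.log10(rna_depth),
            "n_genes": n_genes,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "doublet_score": doublet_score,
            "tss_enrichment": tss,
            "n_fragments": atac_depth.round().astype(int),
            "blacklist_fraction": blacklist,
        }
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def simulate_multiome(config: SimConfig) -> tuple[MultiomeDataset, GroundTruth]:
    """Draw a paired multiome dataset and its ground truth from ``config``."""
    config.validate()
    model = _build_model(config)
    n = config.n_cells
    n_ct = config.n_celltypes
    tps = list(config.timepoints)
    kd_frac = config._kd_fractions()

    cells = _rng(config.seed, "cells")
    # near-even split of cells across timepoints
    per_tp = np.full(len(tps), n // len(tps))
    per_tp[: n % len(tps)] += 1
    tp_idx = np.repeat(np.arange(len(tps)), per_tp)

    is_kd = np.zeros(n, dtype=bool)
    celltype_idx = np.zeros(n, dtype=int)
    for t in range(len(tps)):
        sel = np.flatnonzero(tp_idx == t)
        is_kd[sel] = cells.random(len(sel)) < kd_frac[tps[t]]
        wt_p = model["comp"][t]
        kd_p = _kd_composition(wt_p, config.depleted_celltypes)
        kd_sel = sel[is_kd[sel]]
        wt_sel = sel[~is_kd[sel]]
        celltype_idx[wt_sel] = cells.choice(n_ct, size=len(wt_sel), p=wt_p)
        celltype_idx[kd_sel] = cells.choice(n_ct, size=len(kd_sel), p=kd_p)

    low_quality = cells.random(n) < config.low_quality_fraction
    doublet = (~low_quality) & (cells.random(n) < config.doublet_fraction)

    qc_rng = _rng(config.seed, "qcmeta")
    mu_r, sd_r = config.rna_depth_lognormal_params
    mu_a, sd_a = config.atac_depth_lognormal_params
    rna_depth = np.where(
        low_quality, qc_rng.lognormal(np.log(300.0), 0.5, n), qc_rng.lognormal(mu_r, sd_r, n)
    )
    atac_depth = np.where(
        low_quality, qc_rng.lognormal(np.log(800.0), 0.5, n), qc_rng.lognormal(mu_a, sd_a, n)
    )

    # planted DE shifts the KD profile of the affected type
    pi_gene = model["pi_gene"]
    pi_kd = pi_gene.copy()
    for g, ct, l2fc in config.de_genes:
        pi_kd[int(g), int(ct)] *= 2.0 ** float(l2fc)
    pi_kd = pi_kd / pi_kd.sum(axis=0, keepdims=True)

    rna = _sample_counts(
        _rng(config.seed, "rna"), pi_gene, rna_depth, celltype_idx,
        config.nb_dispersion, pi_kd=pi_kd, is_kd=is_kd,
    )
    atac = _sample_counts(
        _rng(config.seed, "atac"), model["pi_peak"], atac_depth, celltype_idx,
        config.nb_dispersion,
    )

    ct_names = model["celltypes"]
    meta = _qc_metadata(qc_rng, n, low_quality, doublet, rna_depth, atac_depth)
    meta.insert(0, "cell", [f"cell_{i:06d}" for i in range(n)])
    meta.insert(1, "sample", [f"{tps[t]}_{'KD' if k else 'WT'}" for t, k in zip(tp_idx, is_kd)])
    meta.insert(2, "timepoint", pd.Categorical([tps[t] for t in tp_idx], categories=tps, ordered=True))
    meta.insert(3, "condition", np.where(is_kd, "KD", "WT"))
    meta.insert(4, "celltype", ct_names[celltype_idx])
    meta["planted_low_quality"] = low_quality
    meta["planted_doublet"] = doublet

    gene_meta = pd.DataFrame({"name": model["gene_names"], "is_tf": model["is_tf"]})
    peak_meta = pd.DataFrame(
        {
            "name": model["peak_names"],
            "chrom": model["chroms"],
            "start": model["starts"],
            "end": model["ends"],
        }
    )
    motifs = model["motif_matches"][["peak", "tf", "score"]].copy()

    dataset = MultiomeDataset(rna, atac, meta, gene_meta, peak_meta, motifs)
    dataset.validate()

    truth = GroundTruth(
        celltype_per_cell=ct_names[celltype_idx],
        bound_pairs={
            (model["tf_names"][t], model["peak_names"][pk])
            for t, pk, eff in model["links"]
            if eff > 0
        },
        depleted_celltypes={ct_names[ct]: float(f) for ct, f in config.depleted_celltypes.items()},
        de_genes=[
            (model["gene_names"][g], ct_names[ct], float(l)) for g, ct, l in config.de_genes
        ],
        wt_composition=pd.DataFrame(model["comp"], index=tps, columns=ct_names),
    )
    return dataset, truth


def simulate_reference_atlas(
    config: SimConfig, n_ref_cells: int, d: int = 50, n_hvgs: int = 500
) -> ReferenceAtlas:
    """Reference cells drawn from the same archetypes as the paired dataset.

    Composition is the WT composition averaged over timepoints; expression is
    log-normalized and embedded with the label-transfer module's PCA.
    """
    from . import transfer  # deferred: avoids an import cycle

    config.validate()
    if n_ref_cells < config.n_celltypes:
        raise ValueError("n_ref_cells must be >= n_celltypes")
    model = _build_model(config)
    rng = _rng(config.seed, "atlas")

    comp = model["comp"].mean(axis=0)
    comp = comp / comp.sum()
    celltype_idx = rng.choice(config.n_celltypes, size=n_ref_cells, p=comp)
    mu_r, sd_r = config.rna_depth_lognormal_params
    depth = rng.lognormal(mu_r, sd_r, n_ref_cells)
    counts = _sample_counts(rng, model["pi_gene"], depth, celltype_idx, config.nb_dispersion)

    logexpr = transfer.lognormalize(counts)
    n_hvgs = min(n_hvgs, config.n_genes)
    hvgs = transfer.select_hvgs(logexpr, model["gene_names"], n_hvgs)
    d_eff = min(d, len(hvgs), max(1, n_ref_cells - 1))
    emb = transfer.fit_pca(logexpr, model["gene_names"], hvgs, d_eff)

    stages = np.array(
        [_STAGES[i % len(_STAGES)] for i in rng.integers(0, len(config.timepoints), n_ref_cells)],
        dtype=object,
    )
    atlas = ReferenceAtlas(
        expression=logexpr,
        gene_names=model["gene_names"],
        labels=model["celltypes"][celltype_idx],
        stage=stages,
        embedding=emb,
    )
    atlas.validate()
    return atlas
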