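"""End-to-end analysis: simulate -> QC -> label transfer -> in-silico ChIP
-> differential abundance -> pseudobulk differential expression.

One :class:`~scmultiome.simulate.SimConfig` plus a seed determines every
byte of output; running twice writes identical files.  QC filtering uses
the full-transcriptome-scale metrics carried in the cell metadata (see the
simulator's documentation) with the published thresholds unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, insilico_chip, io, pseudobulk_de, qc, simulate, transfer

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: simulate.MultiomeDataset
    truth: simulate.GroundTruth
    kept_cells: np.ndarray  # boolean mask over all simulated cells
    transfer_result: transfer.TransferResult
    binding: insilico_chip.BindingScoreMatrix
    da_result: abundance.DAResult
    de_results: pseudobulk_de.DEResults
    manifest: dict | None = None

    def transfer_accuracy(self) -> float:
        truth_labels = self.truth.celltype_per_cell[self.kept_cells]
        return self.transfer_result.accuracy(truth_labels)

    def summary(self) -> str:
        parts = [
            f"Cells simulated: {len(self.kept_cells)}; passing QC: {int(self.kept_cells.sum())}",
            f"Label-transfer accuracy vs ground truth: {self.transfer_accuracy():.3f}",
            self.binding.summary(),
            self.da_result.summary(),
            self.de_results.summary(),
        ]
        return "\n\n".join(parts)


def run_pipeline(config: simulate.SimConfig, seed: int | None = None,
                 outdir=None, k_transfer: int = 25, d: int = 50,
                 n_hvgs: int = 2500, k_da: int = 100,
                 n_ref_cells: int | None = None) -> PipelineResult:
    """Run the whole pipeline from one config and seed."""
    if seed is not None:
        config = replace(config, seed=int(seed))
    dataset, truth = simulate.simulate_multiome(config)

    manifest = None
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        manifest = io.write_dataset(dataset, outdir / "dataset")
        (outdir / "ground_truth.json").write_text(truth.to_json())
        (outdir / "config.json").write_text(config.to_json())

    # --- QC on metadata metrics with the published thresholds -------------
    thresholds = qc.QCThresholds()
    meta = dataset.cell_meta
    rna_keep = qc.filter_cells_rna(meta, thresholds)
    atac_keep = qc.filter_cells_atac(meta, thresholds)
    doublet = qc.flag_doublets(meta["doublet_score"], thresholds.doublet_score_max)
    keep = np.zeros(dataset.n_cells, dtype=bool)
    keep[rna_keep.intersection(atac_keep)] = True
    keep &= ~doublet

    kept_idx = np.flatnonzero(keep)
    rna = dataset.rna_counts[:, kept_idx]
    atac = dataset.atac_counts[:, kept_idx]
    kept_meta = meta.iloc[kept_idx].reset_index(drop=True)

    # --- label transfer ---------------------------------------------------
    n_ref = n_ref_cells if n_ref_cells is not None else max(config.n_celltypes * 50, 500)
    atlas = simulate.simulate_reference_atlas(config, n_ref)
    model = transfer.LabelTransfer(
        atlas, rna, dataset.gene_names, exclusion=qc.GeneExclusionRules()
    )
    tr = model.fit(k=k_transfer, d=d, n_hvgs=n_hvgs)

    # --- in-silico ChIP on true-cell-type pseudobulks ---------------------
    clusters = truth.celltype_per_cell[kept_idx]
    chip = insilico_chip.InSilicoChip(
        rna, atac, dataset.motif_matches, clusters=clusters,
        gene_names=dataset.gene_names, peak_names=dataset.peak_names,
    )
    binding = chip.fit()

    # --- differential abundance on the query part of the joint embedding --
    query_emb = tr.embedding.query_coords
    da = abundance.DifferentialAbundance(
        query_emb, kept_meta, abundance.DAConfig(k=k_da)
    ).fit()

    # --- pseudobulk DE per cell type --------------------------------------
    de = pseudobulk_de.PseudobulkDE(
        rna, kept_meta.assign(celltype=clusters), dataset.gene_names
    ).fit(seed=config.seed)

    result = PipelineResult(dataset, truth, keep, tr, binding, da, de, manifest)

    if outdir is not None:
        qc_df = pd.DataFrame({"cell": meta["cell"], "kept": keep})
        qc_df.to_csv(outdir / "qc_kept_cells.tsv", sep="\t", index=False)
        labels_df = tr.assignments.copy()
        labels_df.insert(0, "cell", kept_meta["cell"].to_numpy())
        labels_df.to_csv(outdir / "transfer_labels.tsv", sep="\t", index=False)
        binding.table.to_csv(outdir / "binding_scores.tsv", sep="\t", index=False)
        da.table.to_csv(outdir / "da_results.tsv", sep="\t", index=False)
        de.combined().to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(
                {
                    "n_cells": int(dataset.n_cells),
                    "n_kept": int(keep.sum()),
                    "transfer_accuracy": result.transfer_accuracy(),
                    "n_bound_pairs": int(binding.table["bound"].sum()),
                    "n_da_significant": int(da.significant.sum()),
                    "n_de_significant": int(de.combined()["significant"].sum())
                    if len(de.tables) else 0,
                },
                indent=1,
            )
        )
    return result
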