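"""Reading and writing datasets in 10x-style plain-text formats.

A dataset directory contains, per modality, a Matrix Market sparse count
matrix with accompanying ``features.tsv`` and ``barcodes.tsv`` (10x
convention: features as rows, barcodes as columns), peak intervals as BED3
(0-based half-open), cell metadata and motif matches as headered TSV, and a
JSON manifest.  Writing then reading round-trips the dataset losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth, MultiomeDataset, SimConfig

__all__ = ["write_dataset", "read_dataset", "write_ground_truth", "read_ground_truth"]

_MANIFEST = "manifest.json"


def _write_mtx(directory: Path, counts, feature_df: pd.DataFrame, barcodes) -> list[str]:
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(counts))
    feature_df.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    return [
        str(directory / "matrix.mtx"),
        str(directory / "features.tsv"),
        str(directory / "barcodes.tsv"),
    ]


def write_dataset(dataset: MultiomeDataset, directory) -> dict:
    """Write all dataset components; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    barcodes = dataset.cell_meta["cell"].to_numpy()
    files = {}
    files["rna"] = _write_mtx(
        directory / "rna", dataset.rna_counts.astype(np.int64),
        dataset.gene_meta[["name", "is_tf"]], barcodes,
    )
    files["atac"] = _write_mtx(
        directory / "atac", dataset.atac_counts.astype(np.int64),
        dataset.peak_meta[["name"]], barcodes,
    )
    peaks_bed = directory / "peaks.bed"
    dataset.peak_meta[["chrom", "start", "end"]].to_csv(
        peaks_bed, sep="\t", header=False, index=False
    )
    files["peaks"] = [str(peaks_bed)]
    meta_path = directory / "cell_metadata.tsv"
    dataset.cell_meta.to_csv(meta_path, sep="\t", index=False)
    files["cell_metadata"] = [str(meta_path)]
    motif_path = directory / "motif_matches.tsv"
    dataset.motif_matches.to_csv(motif_path, sep="\t", index=False)
    files["motif_matches"] = [str(motif_path)]

    manifest = {k: [str(Path(p).relative_to(directory)) for p in v] for k, v in files.items()}
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=1))
    return manifest


def _read_mtx(directory: Path) -> sparse.csr_matrix:
    return sparse.csr_matrix(spio.mmread(str(directory / "matrix.mtx")).astype(np.int32))


def read_dataset(directory) -> MultiomeDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    if not (directory / _MANIFEST).exists():
        raise FileNotFoundError(f"no {_MANIFEST} in {directory}")
    rna = _read_mtx(directory / "rna")
    atac = _read_mtx(directory / "atac")
    features = pd.read_csv(
        directory / "rna" / "features.tsv", sep="\t", header=None,
        names=["name", "is_tf"],
    )
    features["is_tf"] = features["is_tf"].astype(bool)
    peak_names = pd.read_csv(
        directory / "atac" / "features.tsv", sep="\t", header=None, names=["name"]
    )
    bed = pd.read_csv(
        directory / "peaks.bed", sep="\t", header=None, names=["chrom", "start", "end"]
    )
    peak_meta = pd.concat([peak_names, bed], axis=1)
    cell_meta = pd.read_csv(directory / "cell_metadata.tsv", sep="\t")
    if "timepoint" in cell_meta.columns:
        order = list(dict.fromkeys(cell_meta["timepoint"]))
        cell_meta["timepoint"] = pd.Categorical(
            cell_meta["timepoint"], categories=order, ordered=True
        )
    motifs = pd.read_csv(directory / "motif_matches.tsv", sep="\t")
    ds = MultiomeDataset(rna, atac, cell_meta, features, peak_meta, motifs)
    if ds.n_cells:
        ds.validate()
    return ds


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
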