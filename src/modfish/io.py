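"""Readers and writers for the standard on-disk formats.

Count matrices travel as Matrix Market MTX with ``genes.tsv`` /
``barcodes.tsv`` sidecars (or dense CSV/TSV); panels as CSV or JSON;
image rounds and label maps as multi-page TIFF; simulation truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .design import GenePanel
from .quantify import CellByModuleMatrix
from .reference import GeneExpressionReference
from .simulate import ImageStack, SegmentationLabelMap, SyntheticTruth

__all__ = [
    "read_counts_mtx",
    "write_counts_mtx",
    "read_counts_dense",
    "read_labels_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_panel_json",
    "read_image_stack",
    "write_image_stack",
    "read_label_map",
    "write_label_map",
    "write_truth_json",
    "read_truth_json",
    "write_cell_matrix",
    "read_cell_matrix",
]


def read_counts_mtx(
    mtx_path, genes_path=None, barcodes_path=None, labels_path=None
) -> GeneExpressionReference:
    """Load genes x cells counts from MTX plus gene/cell index text files."""
    mtx_path = Path(mtx_path)
    genes_path = genes_path or mtx_path.parent / "genes.tsv"
    barcodes_path = barcodes_path or mtx_path.parent / "barcodes.tsv"
    counts = np.asarray(spio.mmread(mtx_path).todense())
    gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    cell_ids = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    labels = None
    if labels_path is not None:
        labels = read_labels_csv(labels_path, cell_ids)
    return GeneExpressionReference(
        counts=counts.astype(np.int64), gene_ids=gene_ids, cell_ids=cell_ids,
        cell_labels=labels,
    )


def write_counts_mtx(ref: GeneExpressionReference, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(ref.counts))
    pd.Series(ref.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(ref.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    if ref.cell_labels is not None:
        pd.DataFrame({"cell_id": ref.cell_ids, "label": ref.cell_labels}).to_csv(
            out / "labels.csv", index=False
        )


def read_counts_dense(
    path, sep: str = ",", genes_as_rows: bool = True, labels_path=None
) -> GeneExpressionReference:
    """Dense CSV/TSV with gene ids in the first column, cell ids in the header."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not genes_as_rows:
        df = df.T
    labels = None
    if labels_path is not None:
        labels = read_labels_csv(labels_path, df.columns.to_numpy(dtype=object))
    return GeneExpressionReference(
        counts=df.to_numpy(dtype=np.int64),
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
        cell_labels=labels,
    )


def read_labels_csv(path, cell_ids: np.ndarray) -> np.ndarray:
    """Cluster labels from a two-column (cell_id, label) CSV, in cell order."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("labels CSV needs (cell_id, label) columns")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
    missing = [c for c in cell_ids if str(c) not in mapping]
    if missing:
        raise KeyError(f"labels missing for cells: {missing[:5]}")
    return np.array([mapping[str(c)] for c in cell_ids], dtype=object)


def read_panel_csv(path) -> GenePanel:
    return GenePanel.from_frame(pd.read_csv(path))


def write_panel_csv(panel: GenePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def write_panel_json(panel: GenePanel, path) -> None:
    payload = [
        {
            "module_id": m.module_id,
            "genes": list(m.genes),
            "probes_per_gene": {g: m.probes(g) for g in m.genes},
            "reference_genes": list(m.reference_genes),
            "target_label": m.target_label,
            "strategy": m.strategy,
        }
        for m in panel.modules
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def write_image_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF, one page per round, round names in page metadata."""
    with tifffile.TiffWriter(path) as tw:
        for name, img in stack.rounds.items():
            tw.write(
                img.astype(np.float32), description=name, contiguous=False
            )


def read_image_stack(
    path, pixel_size: float = 1.0, nuclear_round: str = "nuclear",
    background_round: str | None = None, fov_id: str = "fov0",
) -> ImageStack:
    rounds: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = page.description or f"round{i}"
            rounds[name] = page.asarray().astype(float)
    return ImageStack(
        rounds=rounds, pixel_size=pixel_size, fov_id=fov_id,
        nuclear_round=nuclear_round, background_round=background_round,
    )


def write_label_map(label_map: SegmentationLabelMap, path) -> None:
    tifffile.imwrite(path, label_map.labels.astype(np.int32))


def read_label_map(path) -> SegmentationLabelMap:
    return SegmentationLabelMap(tifffile.imread(path).astype(np.int32))


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "cell_type_labels": [str(x) for x in truth.cell_type_labels],
        "module_membership": truth.module_membership,
        "module_ids": truth.module_ids,
        "module_target_types": truth.module_target_types,
        "cell_centroids": truth.cell_centroids.tolist(),
        "per_cell_module_signal": truth.per_cell_module_signal.tolist(),
        "gene_baseline_means": (
            None if truth.gene_baseline_means is None
            else truth.gene_baseline_means.tolist()
        ),
        "applied_shifts": truth.applied_shifts,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        cell_type_labels=np.array(d["cell_type_labels"], dtype=object),
        module_membership=d["module_membership"],
        module_ids=d["module_ids"],
        module_target_types={k: int(v) for k, v in d["module_target_types"].items()},
        cell_centroids=np.asarray(d["cell_centroids"], dtype=float),
        per_cell_module_signal=np.asarray(d["per_cell_module_signal"], dtype=float),
        gene_baseline_means=(
            None if d.get("gene_baseline_means") is None
            else np.asarray(d["gene_baseline_means"], dtype=float)
        ),
        applied_shifts=(
            None
            if d["applied_shifts"] is None
            else {k: tuple(v) for k, v in d["applied_shifts"].items()}
        ),
    )


def write_cell_matrix(matrix: CellByModuleMatrix, values_path, cells_path) -> None:
    matrix.values.to_csv(values_path)
    matrix.cells.to_csv(cells_path)


def read_cell_matrix(
    values_path, cells_path, pixel_size: float = 1.0, fov_id: str = "fov0"
) -> CellByModuleMatrix:
    values = pd.read_csv(values_path, index_col=0)
    cells = pd.read_csv(cells_path, index_col=0)
    cells["qc_flag"] = cells["qc_flag"].astype(bool)
    cells["qc_reason"] = cells["qc_reason"].fillna("")
    return CellByModuleMatrix(
        values=values, cells=cells, pixel_size=pixel_size, fov_id=fov_id
    )
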