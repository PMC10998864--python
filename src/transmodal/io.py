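"""Reading and writing count matrices.

Supported formats: a Matrix Market triplet directory (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``), an ``.h5ad`` container, and a plain CSV
with cells as rows.  Parsing of the standard formats is delegated to
``scipy.io`` and ``anndata``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, PredictedMatrix

__all__ = ["load_count_matrix", "save_count_matrix", "save_predicted_matrix"]


class ParseError(ValueError):
    pass


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _load_mtx_dir(path: Path) -> tuple[sp.spmatrix, list[str], list[str]]:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    try:
        mat = scipy.io.mmread(str(mtx))
    except ValueError as exc:
        raise ParseError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    features_file = path / "features.tsv"
    if not features_file.exists():
        features_file = path / "genes.tsv"
    features = _read_id_column(features_file)
    barcodes = _read_id_column(path / "barcodes.tsv")
    # cellranger convention stores features x cells; ours is cells x features
    mat = sp.csr_matrix(mat)
    if mat.shape == (len(barcodes), len(features)):
        pass
    elif mat.shape == (len(features), len(barcodes)):
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither ({len(barcodes)} cells,"
            f" {len(features)} features) nor its transpose"
        )
    return mat, barcodes, features


def _load_csv(path: Path) -> tuple[sp.spmatrix, list[str], list[str]]:
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed CSV {path}: {exc}") from exc
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[coerced.isna() & df[col].notna()].tolist()
            if rows:
                raise ParseError(
                    f"non-numeric value in column {col!r} of {path} at row(s) {rows[:5]}"
                )
        raise ParseError(f"non-numeric column(s) {list(bad)} in {path}")
    mat = sp.csr_matrix(df.to_numpy(dtype=np.float64))
    return mat, [str(i) for i in df.index], [str(c) for c in df.columns]


def load_count_matrix(path, fmt: str, modality: str) -> CountMatrix:
    """Load a raw count matrix.

    Parameters
    ----------
    path
        File (csv, h5ad) or directory (mtx_dir) to read.
    fmt
        One of ``"mtx_dir"``, ``"h5ad"``, ``"csv"``.
    modality
        ``"rna"``, ``"atac"`` or ``"adt"``.  For chromatin data, feature names
        matching ``chrom:start-end`` (or ``chrom-start-end``) are parsed into
        genomic intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cell_labels = batch_labels = None
    if fmt == "mtx_dir":
        values, cells, features = _load_mtx_dir(path)
    elif fmt == "csv":
        values, cells, features = _load_csv(path)
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(str(path))
        values = sp.csr_matrix(adata.X)
        cells = adata.obs_names.tolist()
        features = adata.var_names.tolist()
        if "cell_type" in adata.obs:
            cell_labels = adata.obs["cell_type"].astype(str).tolist()
        if "batch" in adata.obs:
            batch_labels = adata.obs["batch"].astype(str).tolist()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CountMatrix(
        values=values,
        cell_ids=cells,
        feature_ids=features,
        modality=modality,
        cell_labels=cell_labels,
        batch_labels=batch_labels,
    )


def save_count_matrix(cm: CountMatrix, out_dir) -> None:
    """Write a CountMatrix as a Matrix Market triplet directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(cm.values))
    pd.Series(cm.feature_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = {"modality": cm.modality}
    if cm.cell_labels is not None:
        meta["cell_labels"] = list(cm.cell_labels)
    if cm.batch_labels is not None:
        meta["batch_labels"] = list(cm.batch_labels)
    (out / "meta.json").write_text(json.dumps(meta))


def save_predicted_matrix(pred: PredictedMatrix, path) -> None:
    """Write a prediction as an .h5ad container with direction metadata."""
    import anndata

    adata = anndata.AnnData(X=np.asarray(pred.values))
    adata.uns["direction"] = "->".join(pred.direction)
    adata.uns["thresholded"] = pred.thresholded
    adata.uns["model_fingerprint"] = pred.model_fingerprint
    adata.write_h5ad(str(path))
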