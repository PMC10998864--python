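"""Modality-specific preprocessing.

Transcriptome: median library-size normalization, log1p, highly-variable-gene
selection.  Chromatin: binarization, rare-peak filtering, TF-IDF scaled to
[0, 1] with the state needed to invert it.  Surface proteins: centered
log-ratio across each cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .containers import (
    ChromosomeIndex,
    CountMatrix,
    ProcessedMatrix,
    TfidfModel,
    parse_interval,
)

__all__ = [
    "preprocess_rna",
    "preprocess_atac",
    "preprocess_adt",
    "group_peaks_by_chromosome",
]


def _dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense(), dtype=np.float64)
    return np.asarray(values, dtype=np.float64)


def _hvg_rank(logged: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Normalized-dispersion ranking on log data, binned by mean expression.

    Genes are binned by mean, and within each bin the dispersion
    (variance/mean) is z-scored; genes are ranked by that normalized
    dispersion.  Returns gene indices sorted most-variable first.
    """
    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    n_bins = min(n_bins, max(1, len(mean) // 2))
    # quantile bins on the mean so every bin is populated
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.searchsorted(quantiles[1:-1], mean, side="right")
    norm_disp = np.zeros_like(dispersion)
    for b in np.unique(bins):
        sel = bins == b
        d = dispersion[sel]
        sd = d.std()
        norm_disp[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    # stable tie-break on gene index
    order = np.lexsort((np.arange(len(mean)), -norm_disp))
    return order


def preprocess_rna(raw: CountMatrix, n_hvg: int | None = 3000) -> ProcessedMatrix:
    """Normalize, log-transform and select highly variable genes.

    Every cell's total count is scaled to the median of the pre-normalization
    totals, values are log(1+x) transformed, and the ``n_hvg`` most variable
    genes (normalized dispersion, binned by mean) are retained.  ``n_hvg=None``
    keeps all genes.
    """
    if raw.modality != "rna":
        raise ValueError(f"expected rna modality, got {raw.modality!r}")
    x = _dense(raw.values)
    totals = x.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if len(zero):
        ids = [raw.cell_ids[i] for i in zero[:10]]
        raise ValueError(
            f"{len(zero)} cell(s) have zero total counts (e.g. {ids}); filter them first"
        )
    if n_hvg is not None and n_hvg > raw.n_features:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {raw.n_features}")
    median_total = float(np.median(totals))
    normed = x * (median_total / totals)[:, None]
    logged = np.log1p(normed)
    log = [
        {"transform": "normalize_total", "target_sum": median_total},
        {"transform": "log1p"},
    ]
    if n_hvg is None or n_hvg == raw.n_features:
        selected = np.arange(raw.n_features)
    else:
        order = _hvg_rank(logged)
        selected = np.sort(order[:n_hvg])
    log.append({"transform": "hvg", "method": "normalized_dispersion_binned",
                "n_hvg": int(len(selected))})
    return ProcessedMatrix(
        values=logged[:, selected],
        modality="rna",
        transform_log=log,
        selected_features=selected,
        feature_ids=[raw.feature_ids[i] for i in selected],
        cell_ids=list(raw.cell_ids),
    )


def preprocess_atac(
    raw: CountMatrix, min_cell_frac: float = 0.005
) -> tuple[ProcessedMatrix, TfidfModel]:
    """Binarize, filter rare peaks, and apply scaled TF-IDF.

    Peaks open in strictly fewer than ``min_cell_frac`` of all cells are
    removed.  With the binarized matrix ``B``: ``TF[i,j] = B[i,j]/rowsum_i``,
    ``IDF[j] = log(1 + n/colsum_j)`` (natural log), and the TF-IDF product is
    divided by its global maximum ``S`` so the output lies in [0, 1].  The
    returned :class:`TfidfModel` carries ``idf``, ``S``, per-cell totals and
    the kept-feature indices needed for count recovery.
    """
    if raw.modality != "atac":
        raise ValueError(f"expected atac modality, got {raw.modality!r}")
    x = _dense(raw.values)
    n = x.shape[0]
    binary = (x > 0).astype(np.float64)
    colsum = binary.sum(axis=0)
    kept = np.where(colsum >= min_cell_frac * n)[0]
    if len(kept) == 0:
        raise ValueError("no peaks survive the rare-peak filter")
    binary = binary[:, kept]
    rowsum = binary.sum(axis=1)
    empty = np.where(rowsum == 0)[0]
    if len(empty):
        ids = [raw.cell_ids[i] for i in empty[:10]]
        raise ValueError(
            f"{len(empty)} cell(s) have no open peaks after filtering (e.g. {ids})"
        )
    tf = binary / rowsum[:, None]
    idf = np.log(1.0 + n / binary.sum(axis=0))
    tfidf = tf * idf[None, :]
    scale = float(tfidf.max())
    processed = ProcessedMatrix(
        values=tfidf / scale,
        modality="atac",
        transform_log=[
            {"transform": "binarize"},
            {"transform": "filter_peaks", "min_cell_frac": min_cell_frac,
             "n_removed": int(raw.n_features - len(kept))},
            {"transform": "tfidf_scaled", "scale": scale},
        ],
        selected_features=kept,
        feature_ids=[raw.feature_ids[i] for i in kept],
        cell_ids=list(raw.cell_ids),
    )
    model = TfidfModel(
        idf=idf,
        scale=scale,
        cell_totals=rowsum.astype(np.int64),
        kept_features=kept,
    )
    return processed, model


def preprocess_adt(raw: CountMatrix, pseudocount: float = 1.0) -> ProcessedMatrix:
    """Centered log-ratio transform across each cell.

    With ``x' = x + pseudocount``, every protein value becomes
    ``log(x'_j / geometric_mean(x'))``; each output row sums to zero.
    """
    if raw.modality != "adt":
        raise ValueError(f"expected adt modality, got {raw.modality!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = _dense(raw.values) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ProcessedMatrix(
        values=clr,
        modality="adt",
        transform_log=[{"transform": "clr", "pseudocount": pseudocount}],
        selected_features=np.arange(raw.n_features),
        feature_ids=list(raw.feature_ids),
        cell_ids=list(raw.cell_ids),
    )


def group_peaks_by_chromosome(
    feature_ids: list[str],
    feature_intervals: list[tuple[str, int, int] | None] | None = None,
) -> ChromosomeIndex:
    """Partition chromatin features by chromosome in first-appearance order.

    Names that do not parse as genomic intervals fall into a catch-all block
    (one extra network group when non-empty).  Raises if *no* feature parses,
    suggesting a single-group fallback.
    """
    if feature_intervals is None:
        feature_intervals = [parse_interval(f) for f in feature_ids]
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    catch_all: list[int] = []
    for i, iv in enumerate(feature_intervals):
        if iv is None:
            catch_all.append(i)
            continue
        chrom = iv[0]
        if chrom not in groups:
            groups[chrom] = []
            order.append(chrom)
        groups[chrom].append(i)
    if not order:
        raise ValueError(
            "no feature names parse as genomic intervals; pass a single-group "
            "index (one group holding all features) to skip chromosome pruning"
        )
    if catch_all:
        warnings.warn(
            f"{len(catch_all)} feature name(s) are not genomic intervals; "
            "grouped into a catch-all block"
        )
    return ChromosomeIndex(
        groups=[(c, np.array(groups[c], dtype=np.intp)) for c in order],
        catch_all=np.array(catch_all, dtype=np.intp),
    )
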