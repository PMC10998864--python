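"""Evaluation protocols for translated profiles.

Clustering-based heterogeneity scores (PCA-50 + Leiden against true labels),
annotation agreement metrics, the perturbation DEG-overlap / bootstrap-R2
protocol, and per-cell correlations for protein panels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn import metrics as skm

from .containers import EvalReport

__all__ = [
    "clustering_heterogeneity_eval",
    "annotation_metrics",
    "perturbation_metrics",
    "adt_correlations",
    "leiden_cluster",
]


def leiden_cluster(matrix: np.ndarray, n_pcs: int = 50, resolution: float = 1.0,
                   n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """PCA -> neighbor graph -> Leiden community labels."""
    import anndata
    import scanpy as sc

    x = np.asarray(matrix, dtype=np.float64)
    k = min(n_pcs, x.shape[0] - 1, x.shape[1] - 1)
    if k < n_pcs:
        warnings.warn(f"reducing PCA dimensionality to {k} (few cells/features)")
    adata = anndata.AnnData(X=x.astype(np.float32))
    sc.pp.pca(adata, n_comps=k, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, x.shape[0] - 1),
                    n_pcs=k, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="leidenalg")
    return adata.obs["leiden"].to_numpy().astype(str)


def clustering_heterogeneity_eval(matrix: np.ndarray, true_labels,
                                  n_pcs: int = 50, resolution: float = 1.0,
                                  n_neighbors: int = 15, seed: int = 0,
                                  ) -> EvalReport:
    """Cluster a profile matrix and score the partition against known labels.

    ARI and AMI are chance-corrected; NMI and AMI use the arithmetic mean of
    the two label entropies as normalizer; HOM is cluster purity with respect
    to the true labels.
    """
    true_labels = np.asarray(true_labels).astype(str)
    clusters = leiden_cluster(matrix, n_pcs=n_pcs, resolution=resolution,
                              n_neighbors=n_neighbors, seed=seed)
    m = {
        "ARI": float(skm.adjusted_rand_score(true_labels, clusters)),
        "AMI": float(skm.adjusted_mutual_info_score(
            true_labels, clusters, average_method="arithmetic")),
        "NMI": float(skm.normalized_mutual_info_score(
            true_labels, clusters, average_method="arithmetic")),
        "HOM": float(skm.homogeneity_score(true_labels, clusters)),
        "n_clusters": float(len(np.unique(clusters))),
    }
    return EvalReport(metrics=m, params={"n_pcs": n_pcs, "resolution": resolution,
                                         "n_neighbors": n_neighbors}, seed=seed)


def annotation_metrics(pred_labels, true_labels) -> EvalReport:
    """Accuracy, Cohen's kappa, and macro/support-weighted F1.

    A degenerate single-class truth makes kappa undefined; it is reported as
    0 with a flag.
    """
    pred = np.asarray(pred_labels).astype(str)
    true = np.asarray(true_labels).astype(str)
    if len(pred) != len(true):
        raise ValueError("label vectors must have equal length")
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = skm.cohen_kappa_score(true, pred)
    if np.isnan(kappa):
        kappa = 0.0
        flags.append("kappa_undefined_degenerate_labels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = {
            "Acc": float(skm.accuracy_score(true, pred)),
            "Kappa": float(kappa),
            "F1_macro": float(skm.f1_score(true, pred, average="macro")),
            "F1_weighted": float(skm.f1_score(true, pred, average="weighted")),
        }
    return EvalReport(metrics=m, flags=flags)


def rank_sum_deg_scores(ctrl: np.ndarray, stim: np.ndarray) -> np.ndarray:
    """Per-gene one-sided (stimulated > control) Wilcoxon rank-sum z scores,
    with mid-ranks for ties."""
    ctrl = np.asarray(ctrl, dtype=np.float64)
    stim = np.asarray(stim, dtype=np.float64)
    n_c, n_s = ctrl.shape[0], stim.shape[0]
    n = n_c + n_s
    combined = np.vstack([stim, ctrl])
    ranks = stats.rankdata(combined, axis=0)
    r_stim = ranks[:n_s].sum(axis=0)
    expected = n_s * (n + 1) / 2.0
    # tie-corrected variance (counts are heavily tied)
    tie_term = np.empty(combined.shape[1])
    for j in range(combined.shape[1]):
        _, counts = np.unique(combined[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = n_c * n_s / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 1e-300))
    return (r_stim - expected) / sd


def top_degs(ctrl: np.ndarray, stim: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the ``n_top`` genes most up-regulated under perturbation."""
    scores = rank_sum_deg_scores(ctrl, stim)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:n_top]


def perturbation_metrics(ctrl: np.ndarray, real_stim: np.ndarray,
                         pred_stim: np.ndarray, n_top: int = 100,
                         n_boot: int = 100, frac: float = 0.8,
                         rng: np.random.Generator | None = None) -> EvalReport:
    """DEG overlap and bootstrap R2 for predicted perturbation responses.

    Genes are ranked by a one-sided rank-sum score of control vs real
    perturbed cells (real DEGs) and control vs predicted cells (predicted
    DEGs); the overlap of the two top-``n_top`` lists is reported.  Then
    ``n_boot`` resamples of ``frac`` of the test cells (with replacement)
    each yield the squared Pearson correlation of the top-``n_top`` real
    DEGs' mean expression between predicted and real perturbed cells.  When
    the two matrices have the same number of cells the same resample indices
    are applied to both (paired bootstrap); otherwise each set is resampled
    independently.
    """
    rng = np.random.default_rng() if rng is None else rng
    real_top = top_degs(ctrl, real_stim, n_top)
    pred_top = top_degs(ctrl, pred_stim, n_top)
    common = len(set(real_top.tolist()) & set(pred_top.tolist()))
    r2s = np.empty(n_boot)
    n_real, n_pred = real_stim.shape[0], pred_stim.shape[0]
    m_real = max(2, int(round(frac * n_real)))
    m_pred = max(2, int(round(frac * n_pred)))
    for b in range(n_boot):
        ri = rng.integers(0, n_real, size=m_real)
        pi = ri if n_pred == n_real else rng.integers(0, n_pred, size=m_pred)
        mu_real = real_stim[ri][:, real_top].mean(axis=0)
        mu_pred = pred_stim[pi][:, real_top].mean(axis=0)
        r = np.corrcoef(mu_real, mu_pred)[0, 1]
        r2s[b] = r * r
    m = {
        "common_degs": float(common),
        "r2_mean": float(r2s.mean()),
        "r2_sd": float(r2s.std(ddof=1)) if n_boot > 1 else 0.0,
    }
    return EvalReport(metrics=m, params={"n_top": n_top, "n_boot": n_boot,
                                         "frac": frac})


def adt_correlations(real: np.ndarray, pred: np.ndarray) -> EvalReport:
    """Per-cell Pearson and Spearman correlation of protein vectors."""
    real = np.asarray(real, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if real.shape != pred.shape:
        raise ValueError("real and predicted matrices must have equal shape")
    pearson = np.empty(real.shape[0])
    spearman = np.empty(real.shape[0])
    for i in range(real.shape[0]):
        pearson[i] = stats.pearsonr(real[i], pred[i]).statistic
        spearman[i] = stats.spearmanr(real[i], pred[i]).statistic
    m = {
        "pearson_mean": float(np.nanmean(pearson)),
        "pearson_median": float(np.nanmedian(pearson)),
        "spearman_mean": float(np.nanmean(spearman)),
        "spearman_median": float(np.nanmedian(spearman)),
    }
    return EvalReport(metrics=m)
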