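"""Evaluation metrics against straight-line contingency-table formulas."""

import numpy as np
import pytest
from scipy.special import comb

from transmodal.metrics import (
    adt_correlations,
    annotation_metrics,
    clustering_heterogeneity_eval,
    perturbation_metrics,
    rank_sum_deg_scores,
    top_degs,
)


# --- independent straight-line implementations ------------------------------

def _contingency(a, b):
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    table = np.zeros((len(av), len(bv)), dtype=np.int64)
    for i, j in zip(ai, bi):
        table[i, j] += 1
    return table


def _ari(a, b):
    t = _contingency(a, b)
    n = t.sum()
    sum_ij = sum(comb(x, 2) for x in t.ravel())
    sum_a = sum(comb(x, 2) for x in t.sum(axis=1))
    sum_b = sum(comb(x, 2) for x in t.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts):
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_info(t):
    n = t.sum()
    mi = 0.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            if t[i, j] > 0:
                mi += t[i, j] / n * np.log(n * t[i, j] / (rows[i] * cols[j]))
    return mi


def _expected_mi(t):
    # Vinh et al. exact expectation of MI under the permutation model
    n = int(t.sum())
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    emi = 0.0
    for ai in rows:
        for bj in cols:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = nij / n * np.log(n * nij / (ai * bj))
                prob = (comb(bj, nij) * comb(n - bj, ai - nij)) / comb(n, ai)
                emi += term * prob
    return emi


def _nmi(a, b):
    t = _contingency(a, b)
    mi = _mutual_info(t)
    ha, hb = _entropy(t.sum(axis=1)), _entropy(t.sum(axis=0))
    if ha == 0 and hb == 0:
        return 1.0
    return float(mi / ((ha + hb) / 2))


def _ami(a, b):
    t = _contingency(a, b)
    mi = _mutual_info(t)
    emi = _expected_mi(t)
    ha, hb = _entropy(t.sum(axis=1)), _entropy(t.sum(axis=0))
    denom = (ha + hb) / 2 - emi
    if denom == 0:
        return 1.0
    return float((mi - emi) / denom)


def _homogeneity(truth, clusters):
    t = _contingency(truth, clusters)
    h_truth = _entropy(t.sum(axis=1))
    if h_truth == 0:
        return 1.0
    # conditional entropy H(truth | cluster)
    n = t.sum()
    h_cond = 0.0
    for j in range(t.shape[1]):
        col = t[:, j]
        cn = col.sum()
        p = col[col > 0] / cn
        h_cond += cn / n * float(-(p * np.log(p)).sum())
    return 1.0 - h_cond / h_truth


def _kappa(truth, pred):
    t = _contingency(truth, pred)
    # square the table over the union of labels
    labs = sorted(set(truth) | set(pred))
    table = np.zeros((len(labs), len(labs)))
    for x, y in zip(truth, pred):
        table[labs.index(x), labs.index(y)] += 1
    n = table.sum()
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    return (po - pe) / (1 - pe)


def _f1_scores(truth, pred):
    labs = sorted(set(truth) | set(pred))
    f1s, supports = [], []
    for lab in labs:
        tp = sum(1 for x, y in zip(truth, pred) if x == lab and y == lab)
        fp = sum(1 for x, y in zip(truth, pred) if x != lab and y == lab)
        fn = sum(1 for x, y in zip(truth, pred) if x == lab and y != lab)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
        supports.append(sum(1 for x in truth if x == lab))
    f1s = np.array(f1s)
    supports = np.array(supports, dtype=float)
    return f1s.mean(), float((f1s * supports).sum() / supports.sum())


# --- tests -------------------------------------------------------------------

def _cluster_metrics_only(truth, clusters):
    """Score a given partition without the PCA/Leiden pipeline."""
    from sklearn import metrics as skm

    return {
        "ARI": skm.adjusted_rand_score(truth, clusters),
        "AMI": skm.adjusted_mutual_info_score(truth, clusters,
                                              average_method="arithmetic"),
        "NMI": skm.normalized_mutual_info_score(truth, clusters,
                                                average_method="arithmetic"),
        "HOM": skm.homogeneity_score(truth, clusters),
    }


class TestClusteringMetricOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_partitions_match_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        truth = rng.integers(0, rng.integers(2, 5), n).astype(str)
        clusters = rng.integers(0, rng.integers(2, 5), n).astype(str)
        got = _cluster_metrics_only(truth, clusters)
        assert got["ARI"] == pytest.approx(_ari(truth, clusters), abs=1e-9)
        assert got["NMI"] == pytest.approx(_nmi(truth, clusters), abs=1e-9)
        assert got["AMI"] == pytest.approx(_ami(truth, clusters), abs=1e-7)
        assert got["HOM"] == pytest.approx(_homogeneity(truth, clusters), abs=1e-9)

    def test_six_cell_hand_case(self):
        clusters = ["a", "a", "b", "b", "b", "a"]
        truth = ["x", "x", "x", "y", "y", "y"]
        got = _cluster_metrics_only(truth, clusters)
        assert got["ARI"] == pytest.approx(_ari(truth, clusters), abs=1e-12)
        assert got["HOM"] == pytest.approx(_homogeneity(truth, clusters), abs=1e-12)

    def test_pipeline_perfect_separation_scores_one(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(scale=30.0, size=(3, 20))
        truth = rng.integers(0, 3, 120)
        x = centers[truth] + rng.normal(size=(120, 20))
        rep = clustering_heterogeneity_eval(x, truth.astype(str), seed=0)
        assert rep["ARI"] == 1.0
        assert rep["AMI"] > 0.99
        assert rep["HOM"] == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 20))
        truth = rng.integers(0, 2, 300).astype(str)
        rep = clustering_heterogeneity_eval(x, truth, seed=0)
        assert abs(rep["ARI"]) < 0.05

    def test_small_matrix_reduces_pca_dims(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 8))
        with pytest.warns(UserWarning, match="reducing PCA"):
            clustering_heterogeneity_eval(x, ["a"] * 10 + ["b"] * 10, seed=0)


class TestAnnotationMetrics:
    def test_perfect_prediction(self):
        rep = annotation_metrics(list("aabbc"), list("aabbc"))
        assert rep["Acc"] == rep["Kappa"] == rep["F1_macro"] == rep["F1_weighted"] == 1.0

    def test_confusion_hand_case(self):
        # confusion [[1,1],[0,2]]: one 'a' called 'b'
        truth = ["a", "a", "b", "b"]
        pred = ["a", "b", "b", "b"]
        rep = annotation_metrics(pred, truth)
        assert rep["Acc"] == pytest.approx(0.75)
        assert rep["Kappa"] == pytest.approx(0.5)
        assert rep["F1_macro"] == pytest.approx((2 / 3 + 4 / 5) / 2, abs=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_labels_match_formula_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 50))
        truth = rng.integers(0, 4, n).astype(str).tolist()
        pred = rng.integers(0, 4, n).astype(str).tolist()
        rep = annotation_metrics(pred, truth)
        assert rep["Acc"] == pytest.approx(np.mean([x == y for x, y in zip(truth, pred)]))
        assert rep["Kappa"] == pytest.approx(_kappa(truth, pred), abs=1e-9)
        macro, weighted = _f1_scores(truth, pred)
        assert rep["F1_macro"] == pytest.approx(macro, abs=1e-9)
        assert rep["F1_weighted"] == pytest.approx(weighted, abs=1e-9)

    def test_single_class_truth_kappa_flagged_zero(self):
        rep = annotation_metrics(["a", "a", "a"], ["a", "a", "a"])
        assert rep["Kappa"] == 0.0
        assert "kappa_undefined_degenerate_labels" in rep.flags


class TestPerturbationMetrics:
    def test_perfect_prediction_full_overlap_and_r2_one(self):
        rng = np.random.default_rng(0)
        ctrl = rng.poisson(2.0, size=(40, 60)).astype(float)
        stim = ctrl.copy()
        stim[:, :10] += 5.0
        rep = perturbation_metrics(ctrl, stim, stim, n_top=10, n_boot=20,
                                   rng=np.random.default_rng(1))
        assert rep["common_degs"] == 10
        assert rep["r2_mean"] == pytest.approx(1.0)
        assert rep["r2_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_no_signal_overlap_matches_hypergeometric_expectation(self):
        # real DEGs are strongly planted in a known gene set; the prediction
        # carries no signal, so its top-k list is an effectively random
        # k-subset and the expected overlap is k^2 / G
        rng = np.random.default_rng(3)
        n_top, n_genes = 20, 200
        overlaps = []
        for rep_i in range(12):
            planted = rng.choice(n_genes, size=n_top, replace=False)
            ctrl = rng.poisson(3.0, size=(60, n_genes)).astype(float)
            stim = rng.poisson(3.0, size=(60, n_genes)).astype(float)
            stim[:, planted] += 8.0
            pred = rng.poisson(3.0, size=(60, n_genes)).astype(float)
            rep = perturbation_metrics(ctrl, stim, pred, n_top=n_top, n_boot=2,
                                       rng=np.random.default_rng(rep_i))
            overlaps.append(rep["common_degs"])
        expected = n_top**2 / n_genes  # = 2
        # mean of 12 replicates; hypergeometric sd ~ 1.3 per replicate
        assert np.mean(overlaps) == pytest.approx(expected, abs=1.5)

    def test_rank_sum_scores_detect_planted_shift(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(size=(50, 30))
        stim = rng.normal(size=(50, 30))
        stim[:, [3, 7]] += 3.0
        top = top_degs(ctrl, stim, 2)
        assert set(top.tolist()) == {3, 7}
        # one-sided: down-shifted genes score negative
        stim[:, 11] -= 5.0
        scores = rank_sum_deg_scores(ctrl, stim)
        assert scores[11] < 0

    def test_r2_on_equal_means(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(size=(30, 10))
        stim = rng.normal(loc=1.0, size=(30, 10))
        rep = perturbation_metrics(ctrl, stim, stim.copy(), n_top=2, n_boot=5,
                                   rng=np.random.default_rng(0))
        assert rep["r2_mean"] == pytest.approx(1.0)


class TestAdtCorrelations:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 6))
        rep = adt_correlations(x, x)
        assert rep["pearson_mean"] == pytest.approx(1.0)
        assert rep["spearman_mean"] == pytest.approx(1.0)
        rep2 = adt_correlations(x, -x)
        assert rep2["pearson_mean"] == pytest.approx(-1.0)

    def test_four_protein_hand_case(self):
        real = np.array([[1.0, 2.0, 3.0, 4.0]])
        pred = np.array([[2.0, 1.0, 5.0, 6.0]])
        r = np.corrcoef(real[0], pred[0])[0, 1]
        rep = adt_correlations(real, pred)
        assert rep["pearson_mean"] == pytest.approx(r)
        # spearman from the rank vectors: ranks (1,2,3,4) vs (2,1,3,4)
        from scipy import stats

        rho = np.corrcoef(stats.rankdata(real[0]), stats.rankdata(pred[0]))[0, 1]
        assert rep["spearman_mean"] == pytest.approx(rho)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shape"):
            adt_correlations(np.ones((2, 3)), np.ones((3, 2)))
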