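"""Model/Results front end.

``TranslationModel`` is built from two raw count matrices, owns the
modality-specific preprocessing, and ``fit(seed)`` runs pretraining plus
integrative adversarial training, returning a ``TranslationResults`` that
translates datasets, recovers chromatin counts, evaluates against labels and
prints a summary table.  ``PerturbationModel`` does the same for unpaired
control/perturbed transcriptomes with optimal-transport pairing and
out-of-sample prediction of a held-out cell type.
"""

from __future__ import annotations

import numpy as np

from . import inference, metrics, pairing, preprocess, training
from .containers import CountMatrix, EvalReport, PairedDataset, PredictedMatrix
from .model import ModelConfig, ModelState

__all__ = ["TranslationModel", "TranslationResults",
           "PerturbationModel", "PerturbationResults"]


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class TranslationModel:
    """Cross-modality translator between a transcriptome side and a second
    modality (chromatin, protein panel, or another transcriptome).

    Parameters
    ----------
    rna, second
        Raw count matrices; row i of both must be the same cell.
    config
        Hyperparameters; defaults follow :class:`ModelConfig`.
    augmentation
        ``"none"`` trains on the original pairs; ``"label"`` adds two rounds
        of within-cell-type shuffling (training set triples); ``"cluster"``
        does the same with Leiden cluster labels from a joint embedding when
        no annotation exists.
    labels
        Cell-type labels for ``augmentation="label"`` (defaults to
        ``rna.cell_labels``).
    n_hvg
        Highly-variable-gene count for the transcriptome side (``None`` keeps
        all genes); capped at the gene count.
    """

    def __init__(self, rna: CountMatrix, second: CountMatrix,
                 config: ModelConfig | None = None, augmentation: str = "none",
                 labels=None, n_hvg: int | None = 3000,
                 min_cell_frac: float = 0.005,
                 cluster_provider=None, cluster_resolution: float = 3.0):
        if rna.n_cells != second.n_cells:
            raise ValueError("the two modalities must cover the same cells")
        if augmentation not in ("none", "label", "cluster"):
            raise ValueError(f"unknown augmentation {augmentation!r}")
        self.config = config if config is not None else ModelConfig()
        self.augmentation = augmentation
        self.cluster_provider = cluster_provider
        self.cluster_resolution = cluster_resolution
        self.raw_rna = rna
        self.raw_second = second
        if n_hvg is not None:
            n_hvg = min(n_hvg, rna.n_features)
        self.processed_r = preprocess.preprocess_rna(rna, n_hvg=n_hvg)
        self.tfidf = None
        self.chrom_index = None
        if second.modality == "atac":
            self.processed_a, self.tfidf = preprocess.preprocess_atac(
                second, min_cell_frac=min_cell_frac)
            self.chrom_index = preprocess.group_peaks_by_chromosome(
                self.processed_a.feature_ids)
        elif second.modality == "adt":
            self.processed_a = preprocess.preprocess_adt(second)
        else:
            self.processed_a = preprocess.preprocess_rna(second, n_hvg=n_hvg)
        self.labels = np.asarray(labels if labels is not None else
                                 (rna.cell_labels or []))
        if augmentation == "label" and len(self.labels) != rna.n_cells:
            raise ValueError("label augmentation needs per-cell labels")

    @classmethod
    def from_anndata(cls, adata_rna, adata_second, modality_second: str, **kw):
        import scipy.sparse as sp

        def to_cm(adata, modality):
            return CountMatrix(
                values=sp.csr_matrix(adata.X), cell_ids=adata.obs_names.tolist(),
                feature_ids=adata.var_names.tolist(), modality=modality,
                cell_labels=(adata.obs["cell_type"].astype(str).tolist()
                             if "cell_type" in adata.obs else None))
        return cls(to_cm(adata_rna, "rna"), to_cm(adata_second, modality_second), **kw)

    def build_pairs(self, seed: int) -> PairedDataset:
        n = self.processed_r.n_cells
        rng = np.random.default_rng(_derived_seeds(seed, 5)[1])
        if self.augmentation == "none":
            idx = np.arange(n)
            return PairedDataset(idx1=idx, idx2=idx, origins=["original"] * n,
                                 group_labels=[""] * n)
        if self.augmentation == "label":
            labels = self.labels
        else:
            labels = pairing.derive_cluster_labels(
                self.processed_r, self.processed_a,
                resolution=self.cluster_resolution,
                provider=self.cluster_provider, seed=seed)
        return pairing.augment_by_label(n, labels, rounds=2, rng=rng)

    def fit(self, seed: int = 0) -> "TranslationResults":
        seeds = _derived_seeds(seed, 6)
        kinds = {"r": "rna", "a": self.raw_second.modality}
        features = {"r": self.processed_r.n_features,
                    "a": self.processed_a.n_features}
        state = ModelState(self.config, kinds, features, seeds[0],
                           chrom_index=self.chrom_index)
        pairs = self.build_pairs(seed)
        # validation split by cell: held-out cells contribute only their own
        # (original) pairs to the early-stopping monitor
        n = self.processed_r.n_cells
        split_rng = np.random.default_rng(seeds[5])
        perm = split_rng.permutation(n)
        n_val = max(1, int(round(self.config.val_fraction * n)))
        val_cells = np.zeros(n, dtype=bool)
        val_cells[perm[:n_val]] = True
        keep = ~val_cells[pairs.idx1] & ~val_cells[pairs.idx2]
        x_r = self.processed_r.values[pairs.idx1[keep]]
        x_a = self.processed_a.values[pairs.idx2[keep]]
        val_r = self.processed_r.values[val_cells]
        val_a = self.processed_a.values[val_cells]
        logs = {
            "pretrain_r": training.pretrain_side(
                state, "r", x_r, np.random.default_rng(seeds[2]), x_val=val_r),
            "pretrain_a": training.pretrain_side(
                state, "a", x_a, np.random.default_rng(seeds[3]), x_val=val_a),
            "integrative": training.train_integrative(
                state, x_r, x_a, np.random.default_rng(seeds[4]),
                val_r=val_r, val_a=val_a),
        }
        return TranslationResults(self, state, logs, pairs, seed)


class TranslationResults:
    """Fitted translator: trained parameters, training history, and the
    translate/evaluate interface."""

    def __init__(self, model: TranslationModel, state: ModelState, logs: dict,
                 pairs: PairedDataset, seed: int):
        self.model = model
        self.state = state
        self.logs = logs
        self.pairs = pairs
        self.seed = seed

    def translate(self, direction: str = "r2a", data=None,
                  batch_size: int = 512) -> PredictedMatrix:
        """Translate a processed matrix (default: the training data itself,
        i.e. data-enhancement mode)."""
        src, _ = inference._resolve_direction(self.state, direction)
        if data is None:
            data = (self.model.processed_r if src == "r"
                    else self.model.processed_a).values
        elif hasattr(data, "values") and not isinstance(data, np.ndarray):
            data = data.values
        return inference.translate_dataset(self.state, data, direction,
                                           batch_size=batch_size)

    def recover_counts(self, pred: PredictedMatrix, cell_totals=None):
        if self.model.tfidf is None:
            raise ValueError("no TF-IDF state: the second modality is not chromatin")
        if cell_totals is None and pred.values.shape[0] == self.model.raw_second.n_cells:
            cell_totals = self.model.tfidf.cell_totals
        return inference.recover_atac_counts(pred, self.model.tfidf,
                                             cell_totals=cell_totals)

    def evaluate_translation(self, direction: str = "r2a", labels=None,
                             data=None, seed: int = 0) -> EvalReport:
        """Translate and score cluster agreement against cell-type labels."""
        if labels is None:
            labels = self.model.raw_rna.cell_labels
        if labels is None:
            raise ValueError("no labels available for evaluation")
        pred = self.translate(direction, data=data)
        return metrics.clustering_heterogeneity_eval(pred.values, labels, seed=seed)

    def evaluate_adt(self) -> EvalReport:
        if self.state.side_kinds["a"] != "adt":
            raise ValueError("protein correlations need an ADT second modality")
        pred = self.translate("r2a")
        return metrics.adt_correlations(self.model.processed_a.values, pred.values)

    def save(self, path) -> None:
        self.state.save(path)

    def summary(self) -> str:
        cfg = self.state.cfg
        lines = [
            "Cross-modality translation model",
            "=" * 48,
            f"sides:          rna ({self.state.side_features['r']} features) <-> "
            f"{self.state.side_kinds['a']} ({self.state.side_features['a']} features)",
            f"augmentation:   {self.model.augmentation} "
            f"({len(self.pairs)} training pairs)",
            f"latent dim:     {cfg.latent_dim}   batch size: {cfg.batch_size}",
            f"seed:           {self.seed}",
            "-" * 48,
        ]
        for name, log in self.logs.items():
            last = log.epochs[-1]
            lines.append(
                f"{name:<12} epochs {len(log.epochs):>4}  best {log.best_epoch:>4}"
                f"  val loss {min(log.val_losses):.4f}")
            if name == "integrative":
                lines.append(
                    f"{'':<12} recon_r {last['recon_r']:.4f}  recon_a "
                    f"{last['recon_a']:.4f}  kl {last['kl_r'] + last['kl_a']:.4f}"
                    f"  disc {last['disc']:.4f}")
        return "\n".join(lines)


class PerturbationModel:
    """Perturbation-response predictor on unpaired control/perturbed cells.

    Both conditions are transcriptomes; training pairs come from per-type
    exact optimal transport in PCA space, the held-out cell type is excluded
    from training and predicted out of sample.
    """

    def __init__(self, ctrl: CountMatrix, stim: CountMatrix,
                 holdout_type: str | None = None,
                 config: ModelConfig | None = None, n_pcs: int = 50):
        if ctrl.cell_labels is None or stim.cell_labels is None:
            raise ValueError("both conditions need cell-type labels")
        if ctrl.feature_ids != stim.feature_ids:
            raise ValueError("conditions must share the same gene list")
        self.config = config if config is not None else ModelConfig()
        self.n_pcs = n_pcs
        self.raw_ctrl, self.raw_stim = ctrl, stim
        self.holdout_type = holdout_type
        self.proc_ctrl = preprocess.preprocess_rna(ctrl, n_hvg=None)
        self.proc_stim = preprocess.preprocess_rna(stim, n_hvg=None)
        self.ctrl_labels = np.asarray(ctrl.cell_labels)
        self.stim_labels = np.asarray(stim.cell_labels)

    def fit(self, seed: int = 0) -> "PerturbationResults":
        seeds = _derived_seeds(seed, 6)
        hold = self.holdout_type
        tr_c = np.where(self.ctrl_labels != hold)[0]
        tr_s = np.where(self.stim_labels != hold)[0]
        if len(tr_c) == 0 or len(tr_s) == 0:
            raise ValueError("holdout leaves no training cells")
        plan, pairs = pairing.ot_pair_perturbation(
            self.proc_ctrl.values[tr_c], self.ctrl_labels[tr_c],
            self.proc_stim.values[tr_s], self.stim_labels[tr_s],
            n_pcs=self.n_pcs, seed=seeds[1])
        x_r_all = self.proc_ctrl.values[tr_c][pairs.idx1]
        x_a_all = self.proc_stim.values[tr_s][pairs.idx2]
        # validation split by control cell
        split_rng = np.random.default_rng(seeds[5])
        n_pairs = len(pairs)
        perm = split_rng.permutation(n_pairs)
        n_val = max(1, int(round(self.config.val_fraction * n_pairs)))
        val_sel = np.zeros(n_pairs, dtype=bool)
        val_sel[perm[:n_val]] = True
        x_r, x_a = x_r_all[~val_sel], x_a_all[~val_sel]
        val_r, val_a = x_r_all[val_sel], x_a_all[val_sel]
        kinds = {"r": "rna", "a": "rna"}
        features = {"r": x_r.shape[1], "a": x_a.shape[1]}
        state = ModelState(self.config, kinds, features, seeds[0])
        # pretraining sees the same training-sample multiset as the
        # integrative phase (matched pairs are the training samples)
        logs = {
            "pretrain_r": training.pretrain_side(
                state, "r", x_r, np.random.default_rng(seeds[2]), x_val=val_r),
            "pretrain_a": training.pretrain_side(
                state, "a", x_a, np.random.default_rng(seeds[3]), x_val=val_a),
            "integrative": training.train_integrative(
                state, x_r, x_a, np.random.default_rng(seeds[4]),
                val_r=val_r, val_a=val_a),
        }
        return PerturbationResults(self, state, logs, plan, pairs, seed)


class PerturbationResults:
    def __init__(self, model: PerturbationModel, state: ModelState, logs: dict,
                 plan, pairs: PairedDataset, seed: int):
        self.model = model
        self.state = state
        self.logs = logs
        self.transport_plan = plan
        self.pairs = pairs
        self.seed = seed

    def holdout_indices(self) -> tuple[np.ndarray, np.ndarray]:
        hold = self.model.holdout_type
        return (np.where(self.model.ctrl_labels == hold)[0],
                np.where(self.model.stim_labels == hold)[0])

    def predict_response(self, data=None) -> PredictedMatrix:
        """Predict perturbed profiles (default: for the held-out control
        cells)."""
        if data is None:
            hc, _ = self.holdout_indices()
            data = self.model.proc_ctrl.values[hc]
        return inference.translate_dataset(self.state, data, "r2a")

    def evaluate(self, n_top: int = 100, n_boot: int = 100, frac: float = 0.8,
                 seed: int = 0) -> EvalReport:
        """DEG overlap and bootstrap R2 on the held-out cell type."""
        hc, hs = self.holdout_indices()
        pred = self.predict_response()
        return metrics.perturbation_metrics(
            self.model.proc_ctrl.values[hc], self.model.proc_stim.values[hs],
            pred.values, n_top=n_top, n_boot=n_boot, frac=frac,
            rng=np.random.default_rng(seed))

    def summary(self) -> str:
        lines = [
            "Perturbation-response model",
            "=" * 48,
            f"genes:          {self.state.side_features['r']}",
            f"holdout type:   {self.model.holdout_type}",
            f"training pairs: {len(self.pairs)} (optimal-transport matched)",
            f"seed:           {self.seed}",
            "-" * 48,
        ]
        for name, log in self.logs.items():
            lines.append(
                f"{name:<12} epochs {len(log.epochs):>4}  best {log.best_epoch:>4}"
                f"  val loss {min(log.val_losses):.4f}")
        return "\n".join(lines)
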