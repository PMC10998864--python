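"""Running trained models: dataset translation, sparsity thresholding, and
inversion of the chromatin TF-IDF back to binarized counts."""

from __future__ import annotations

import numpy as np

from .containers import PredictedMatrix, TfidfModel
from .model import ModelState

__all__ = ["translate_dataset", "recover_atac_counts", "chain_translate",
           "SPARSITY_THRESHOLD"]

SPARSITY_THRESHOLD = 1e-4

_DIRECTIONS = {"r2a": ("r", "a"), "a2r": ("a", "r"),
               "r2r": ("r", "r"), "a2a": ("a", "a")}


def _resolve_direction(state: ModelState, direction) -> tuple[str, str]:
    if isinstance(direction, str):
        if direction in _DIRECTIONS:
            return _DIRECTIONS[direction]
        # modality-named form, e.g. "atac2rna"
        parts = direction.split("2")
        if len(parts) == 2:
            rev = {v: k for k, v in state.side_kinds.items()}
            if parts[0] in rev and parts[1] in rev:
                return rev[parts[0]], rev[parts[1]]
        raise ValueError(f"unsupported direction {direction!r} for this model")
    src, tgt = direction
    if src not in ("r", "a") or tgt not in ("r", "a"):
        raise ValueError(f"unsupported direction {direction!r}")
    return src, tgt


def translate_dataset(state: ModelState, data: np.ndarray, direction,
                      batch_size: int = 512) -> PredictedMatrix:
    """Deterministic translation of a processed matrix.

    Runs the mean (no-sampling) path with masking and dropout disabled, in
    batches (row-wise independent, so batching cannot change the result), and
    zeroes every predicted value below 1e-4.  Protein targets keep their
    signed CLR values un-thresholded.
    """
    src, tgt = _resolve_direction(state, direction)
    data = np.asarray(data, dtype=np.float64)
    if data.shape[1] != state.side_features[src]:
        raise ValueError(
            f"data width {data.shape[1]} does not match source side "
            f"({state.side_features[src]} features)")
    enc = state.encoders[src]
    dec = state.decoders[tgt]
    trans = state.translator
    chunks = []
    for start in range(0, data.shape[0], batch_size):
        xb = data[start:start + batch_size]
        h = enc(xb, training=False)
        lb = trans.translate(h, src, tgt, sample=False)
        chunks.append(dec(lb.embedding, training=False))
    pred = np.vstack(chunks)
    tgt_kind = state.side_kinds[tgt]
    thresholded = tgt_kind in ("rna", "atac")
    if thresholded:
        pred = np.where(pred < SPARSITY_THRESHOLD, 0.0, pred)
    return PredictedMatrix(values=pred,
                           direction=(state.side_kinds[src], tgt_kind),
                           thresholded=thresholded,
                           model_fingerprint=state.fingerprint())


def recover_atac_counts(pred: PredictedMatrix, tfidf: TfidfModel,
                        cell_totals: np.ndarray | None = None) -> np.ndarray:
    """Invert the scaled TF-IDF and binarize.

    ``counts[i,j] = pred[i,j] * S / IDF[j] * totals[i]``, then an entry is set
    to 1 iff it is strictly greater than both its row mean and its column mean
    of the recovered count matrix.  ``cell_totals`` should be the per-cell
    open-peak totals of the translated cells' own raw chromatin data; when
    unavailable the scalar median of the training totals is used (recorded in
    ``pred.cell_totals_source``).
    """
    if pred.direction[1] != "atac":
        raise ValueError("count recovery applies to chromatin-target predictions")
    x = np.asarray(pred.values, dtype=np.float64)
    if x.shape[1] != len(tfidf.idf):
        raise ValueError(
            f"prediction has {x.shape[1]} features but the TF-IDF model kept "
            f"{len(tfidf.idf)}")
    if cell_totals is None:
        totals = np.full(x.shape[0], float(np.median(tfidf.cell_totals)))
        pred.cell_totals_source = "train_median"
    else:
        totals = np.asarray(cell_totals, dtype=np.float64)
        if len(totals) != x.shape[0]:
            raise ValueError("cell_totals length must match the cell count")
        pred.cell_totals_source = "test"
    counts = x * tfidf.scale / tfidf.idf[None, :] * totals[:, None]
    row_mean = counts.mean(axis=1, keepdims=True)
    col_mean = counts.mean(axis=0, keepdims=True)
    return ((counts > row_mean) & (counts > col_mean)).astype(np.int8)


def chain_translate(state_1: ModelState, state_2: ModelState,
                    data: np.ndarray, directions: tuple, batch_size: int = 512,
                    features_1=None, features_2=None,
                    ) -> tuple[PredictedMatrix, PredictedMatrix]:
    """Consecutive translation through two trained models.

    The first model's prediction feeds the second model; when feature-id lists
    are given for the handoff they must match exactly.  Returns (final,
    intermediate) predictions.
    """
    d1, d2 = directions
    if features_1 is not None and features_2 is not None:
        if list(features_1) != list(features_2):
            missing = [f for f in features_2 if f not in set(features_1)]
            raise ValueError(
                f"feature lists differ between stages; {len(missing)} features "
                f"expected by stage 2 are absent (e.g. {missing[:5]})")
    inter = translate_dataset(state_1, data, d1, batch_size=batch_size)
    src2, _ = _resolve_direction(state_2, d2)
    if inter.values.shape[1] != state_2.side_features[src2]:
        raise ValueError(
            f"stage-1 output width {inter.values.shape[1]} does not match "
            f"stage-2 source width {state_2.side_features[src2]}")
    final = translate_dataset(state_2, inter.values, d2, batch_size=batch_size)
    return final, inter
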