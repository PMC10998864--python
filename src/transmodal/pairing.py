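"""Training-pair generation.

Three schemes: within-group label shuffling (data augmentation, with either
given cell-type labels or Leiden cluster labels from a joint embedding),
proportion-matched sampling for unpaired datasets, and exact optimal-transport
matching of control to perturbed cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.decomposition import PCA

from .containers import PairedDataset, ProcessedMatrix, TransportPlan

__all__ = [
    "augment_by_label",
    "derive_cluster_labels",
    "pair_unpaired_by_type",
    "ot_pair_perturbation",
    "emd_exact",
]


def augment_by_label(n_cells: int, labels, rounds: int = 2,
                     rng: np.random.Generator | None = None) -> PairedDataset:
    """Label-shuffle augmentation: originals plus ``rounds`` within-group
    permutation pairings.

    Each round pairs the modality-1 profile of every cell with the modality-2
    profile of a uniformly shuffled cell of the same group, so the output has
    exactly ``(rounds + 1) * n_cells`` pairs (two rounds triple the training
    set).  Modality-2 indices are the shuffled side.
    """
    if rounds < 0:
        raise ValueError("rounds must be non-negative")
    labels = np.asarray(labels)
    if len(labels) != n_cells:
        raise ValueError(f"labels length {len(labels)} != n_cells {n_cells}")
    rng = np.random.default_rng() if rng is None else rng
    idx1 = [np.arange(n_cells)]
    idx2 = [np.arange(n_cells)]
    origins = ["original"] * n_cells
    groups = {lab: np.where(labels == lab)[0] for lab in dict.fromkeys(labels.tolist())}
    for r in range(1, rounds + 1):
        shuffled = np.empty(n_cells, dtype=np.intp)
        for members in groups.values():
            shuffled[members] = rng.permutation(members)
        idx1.append(np.arange(n_cells))
        idx2.append(shuffled)
        origins += [f"shuffled_round_{r}"] * n_cells
    idx1 = np.concatenate(idx1)
    idx2 = np.concatenate(idx2)
    return PairedDataset(idx1=idx1, idx2=idx2, origins=origins,
                         group_labels=[str(labels[i]) for i in idx1])


def _default_joint_embedding(m1: ProcessedMatrix, m2: ProcessedMatrix,
                             n_pcs: int, seed: int) -> np.ndarray:
    """Per-modality PCA, normalized and concatenated: a lightweight joint
    embedding standing in for a trained multi-omics integration model.

    Each modality's embedding block is scaled to unit total variance so both
    modalities contribute comparably; the within-block principal-component
    scale structure is preserved (per-component z-scoring would inflate pure
    noise directions).
    """
    parts = []
    for m in (m1, m2):
        x = np.asarray(m.values, dtype=np.float64)
        k = min(n_pcs, x.shape[0] - 1, x.shape[1])
        emb = PCA(n_components=k, random_state=seed).fit_transform(x)
        emb = emb - emb.mean(axis=0)
        total_sd = np.sqrt(emb.var(axis=0).sum())
        if total_sd > 0:
            emb = emb / total_sd
        parts.append(emb)
    return np.concatenate(parts, axis=1)


def derive_cluster_labels(m1: ProcessedMatrix, m2: ProcessedMatrix,
                          resolution: float = 3.0, provider=None,
                          seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """Cluster paired cells on a joint embedding for label-free augmentation.

    ``provider(m1, m2) -> embedding`` may supply any joint embedding (or
    pre-computed labels can bypass this function entirely); the default is
    per-modality PCA-50, z-scored and concatenated.  Communities come from
    Leiden at the given resolution (high resolution favours cluster purity).
    """
    if m1.n_cells != m2.n_cells:
        raise ValueError("matrices must be row-aligned (same cells)")
    if provider is None:
        emb = _default_joint_embedding(m1, m2, 50, seed)
    else:
        try:
            emb = np.asarray(provider(m1, m2))
        except Exception as exc:
            raise RuntimeError(f"joint-embedding provider failed: {exc}") from exc
    import anndata
    import scanpy as sc

    adata = anndata.AnnData(X=emb.astype(np.float32))
    sc.pp.neighbors(adata, use_rep="X", n_neighbors=min(n_neighbors, emb.shape[0] - 1),
                    random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="leidenalg")
    return adata.obs["leiden"].to_numpy().astype(str)


def pair_unpaired_by_type(labels1, labels2, rng: np.random.Generator,
                          ) -> tuple[PairedDataset, np.ndarray, list[str]]:
    """Pair two unpaired datasets by shared cell type.

    For shared type ``i`` with proportions ``s_i^1`` and ``s_i^2`` in the two
    datasets, the sampling proportion is the normalized average
    ``s_i = (s_i^1 + s_i^2) / sum_k (s_k^1 + s_k^2)`` and
    ``round(s_i * (n1 + n2) / 2)`` pairs are drawn (round-half-to-even), each
    by independently sampling one cell of that type from each dataset (with
    replacement whenever a pool is smaller than its quota).  Returns the
    pairs, the ``s`` vector over shared types, and the shared type list.
    Non-shared types are excluded from training pairs (kept for testing by
    the caller).
    """
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    shared = [t for t in dict.fromkeys(labels1.tolist()) if t in set(labels2.tolist())]
    if not shared:
        raise ValueError("no cell types shared between the two datasets")
    n1, n2 = len(labels1), len(labels2)
    p1 = np.array([(labels1 == t).mean() for t in shared])
    p2 = np.array([(labels2 == t).mean() for t in shared])
    s = (p1 + p2) / (p1 + p2).sum()
    idx1, idx2, origins, glabels = [], [], [], []
    for t, si in zip(shared, s):
        quota = int(np.round(si * (n1 + n2) / 2.0))  # numpy rounds half to even
        pool1 = np.where(labels1 == t)[0]
        pool2 = np.where(labels2 == t)[0]
        c1 = rng.choice(pool1, size=quota, replace=quota > len(pool1))
        c2 = rng.choice(pool2, size=quota, replace=quota > len(pool2))
        idx1.append(c1)
        idx2.append(c2)
        origins += ["unpaired_sampled"] * quota
        glabels += [str(t)] * quota
    return (
        PairedDataset(idx1=np.concatenate(idx1), idx2=np.concatenate(idx2),
                      origins=origins, group_labels=glabels),
        s,
        [str(t) for t in shared],
    )


def emd_exact(cost: np.ndarray, w_row: np.ndarray, w_col: np.ndarray) -> np.ndarray:
    """Exact Earth Mover's Distance coupling via linear programming.

    Minimizes ``<gamma, cost>_F`` subject to ``gamma @ 1 = w_row``,
    ``gamma.T @ 1 = w_col``, ``gamma >= 0`` (HiGHS solver).
    """
    nr, nc = cost.shape
    # row-marginal constraints
    data, ri, ci = [], [], []
    for i in range(nr):
        for j in range(nc):
            data.append(1.0)
            ri.append(i)
            ci.append(i * nc + j)
    for j in range(nc):
        for i in range(nr):
            data.append(1.0)
            ri.append(nr + j)
            ci.append(i * nc + j)
    a_eq = sp.coo_matrix((data, (ri, ci)), shape=(nr + nc, nr * nc)).tocsr()
    b_eq = np.concatenate([w_row, w_col])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"EMD linear program failed: {res.message}")
    return res.x.reshape(nr, nc)


def ot_pair_perturbation(ctrl: np.ndarray, ctrl_labels, stim: np.ndarray,
                         stim_labels, n_pcs: int = 50, seed: int = 0,
                         ) -> tuple[TransportPlan, PairedDataset]:
    """Optimal-transport pairing of control and perturbed cells by type.

    Per shared cell type: PCA (fit on the pooled control + perturbed cells of
    that type) to ``n_pcs`` dimensions, Euclidean cost, exact EMD with uniform
    marginals, then each control cell is matched to the perturbed cell with
    the largest coupling weight in its row (ties break to the lowest index;
    a perturbed cell may serve several control cells).  Types with fewer than
    two cells in either condition are skipped with a warning.
    """
    ctrl_labels = np.asarray(ctrl_labels)
    stim_labels = np.asarray(stim_labels)
    shared = [t for t in dict.fromkeys(ctrl_labels.tolist())
              if t in set(stim_labels.tolist())]
    if not shared:
        raise ValueError("no cell types shared between conditions")
    couplings, costs, objectives = {}, {}, {}
    idx1, idx2, origins, glabels = [], [], [], []
    for t in shared:
        ci = np.where(ctrl_labels == t)[0]
        si = np.where(stim_labels == t)[0]
        if len(ci) < 2 or len(si) < 2:
            warnings.warn(f"cell type {t!r} has fewer than 2 cells in one "
                          "condition; skipped in OT pairing")
            continue
        pooled = np.vstack([ctrl[ci], stim[si]])
        k = min(n_pcs, pooled.shape[0] - 1, pooled.shape[1])
        emb = PCA(n_components=k, random_state=seed).fit_transform(pooled)
        e_ctrl, e_stim = emb[: len(ci)], emb[len(ci):]
        diff = e_ctrl[:, None, :] - e_stim[None, :, :]
        cost = np.sqrt((diff**2).sum(axis=2))
        w_ctrl = np.full(len(ci), 1.0 / len(ci))
        w_stim = np.full(len(si), 1.0 / len(si))
        gamma = emd_exact(cost, w_ctrl, w_stim)
        key = str(t)
        couplings[key] = gamma
        costs[key] = cost
        objectives[key] = float((gamma * cost).sum())
        match = gamma.argmax(axis=1)  # argmax takes the lowest index on ties
        idx1.append(ci)
        idx2.append(si[match])
        origins += ["ot_matched"] * len(ci)
        glabels += [key] * len(ci)
    if not idx1:
        raise ValueError("no shared cell type has enough cells for OT pairing")
    plan = TransportPlan(couplings=couplings, costs=costs, objective=objectives)
    pairs = PairedDataset(idx1=np.concatenate(idx1), idx2=np.concatenate(idx2),
                          origins=origins, group_labels=glabels)
    return plan, pairs
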