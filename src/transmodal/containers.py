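"""Core data containers shared across the package."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ProcessedMatrix",
    "TfidfModel",
    "ChromosomeIndex",
    "PredictedMatrix",
    "PairedDataset",
    "TransportPlan",
    "EvalReport",
    "parse_interval",
]

MODALITIES = ("rna", "atac", "adt")

# accepts "chr1:100-200" and "chr1-100-200"
_INTERVAL_RE = re.compile(r"^([A-Za-z0-9_.]+)[:\-](\d+)-(\d+)$")


def parse_interval(feature_id: str):
    """Parse a genomic-interval feature name into (chrom, start, end).

    Returns ``None`` when the name does not look like an interval.  The
    coordinates are kept as opaque integers; no 0/1-based arithmetic is done.
    """
    m = _INTERVAL_RE.match(feature_id)
    if m is None:
        return None
    return m.group(1), int(m.group(2)), int(m.group(3))


@dataclass
class CountMatrix:
    """Raw sparse cell x feature counts for one modality.

    ``feature_intervals`` is populated for chromatin peaks whose names parse as
    genomic intervals; entries are ``None`` for unparseable names.
    """

    values: sp.spmatrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    cell_labels: list[str] | None = None
    batch_labels: list[str] | None = None
    feature_intervals: list[tuple[str, int, int] | None] | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = sp.csr_matrix(self.values)
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if len(self.feature_ids) != m:
            raise ValueError(
                f"matrix has {m} columns but {len(self.feature_ids)} feature ids"
            )
        for name, lab in (("cell_labels", self.cell_labels), ("batch_labels", self.batch_labels)):
            if lab is not None and len(lab) != n:
                raise ValueError(f"{name} must have length {n}, got {len(lab)}")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if self.modality == "atac" and self.feature_intervals is None:
            self.feature_intervals = [parse_interval(f) for f in self.feature_ids]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ProcessedMatrix:
    """Training-ready matrix plus a log of the transforms that produced it."""

    values: np.ndarray
    modality: str
    transform_log: list[dict] = field(default_factory=list)
    selected_features: np.ndarray | None = None
    feature_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.selected_features is not None:
            self.selected_features = np.asarray(self.selected_features, dtype=np.intp)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TfidfModel:
    """Invertible state of the chromatin TF-IDF transform.

    ``idf`` and ``scale`` let the scaled TF-IDF matrix be mapped back to the
    binarized counts; ``cell_totals`` are the row sums of the binarized matrix
    at fit time (the per-cell number of open peaks among kept features).
    """

    idf: np.ndarray
    scale: float
    cell_totals: np.ndarray
    kept_features: np.ndarray

    def __post_init__(self):
        self.idf = np.asarray(self.idf, dtype=np.float64)
        self.cell_totals = np.asarray(self.cell_totals)
        self.kept_features = np.asarray(self.kept_features, dtype=np.intp)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if np.any(self.idf <= 0):
            raise ValueError("idf entries must be positive")

    def to_dict(self) -> dict:
        return {
            "idf": self.idf.tolist(),
            "scale": float(self.scale),
            "cell_totals": self.cell_totals.tolist(),
            "kept_features": self.kept_features.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TfidfModel":
        return cls(
            idf=np.array(d["idf"]),
            scale=d["scale"],
            cell_totals=np.array(d["cell_totals"]),
            kept_features=np.array(d["kept_features"]),
        )


@dataclass
class ChromosomeIndex:
    """Partition of chromatin features by chromosome.

    ``groups`` lists (chromosome name, feature indices) in first-appearance
    order; unparseable names land in ``catch_all`` which, when non-empty, is
    treated as one extra group by the encoder/decoder.
    """

    groups: list[tuple[str, np.ndarray]]
    catch_all: np.ndarray

    def __post_init__(self):
        self.groups = [(name, np.asarray(idx, dtype=np.intp)) for name, idx in self.groups]
        self.catch_all = np.asarray(self.catch_all, dtype=np.intp)

    def block_indices(self) -> list[np.ndarray]:
        """Index lists for the per-chromosome network blocks (catch-all last)."""
        blocks = [idx for _, idx in self.groups]
        if len(self.catch_all):
            blocks.append(self.catch_all)
        return blocks

    @property
    def n_features(self) -> int:
        return sum(len(b) for b in self.block_indices())

    def to_dict(self) -> dict:
        return {
            "groups": [[name, idx.tolist()] for name, idx in self.groups],
            "catch_all": self.catch_all.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromosomeIndex":
        return cls(
            groups=[(name, np.array(idx, dtype=np.intp)) for name, idx in d["groups"]],
            catch_all=np.array(d["catch_all"], dtype=np.intp),
        )


@dataclass
class PredictedMatrix:
    values: np.ndarray
    direction: tuple[str, str]  # (source modality, target modality)
    thresholded: bool
    model_fingerprint: str
    cell_totals_source: str = "test"  # "test" or "train_median" (count recovery)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class PairedDataset:
    """Index-level pairing of cells across two matrices.

    Each pair is (index into modality-1, index into modality-2); ``origins``
    tags the provenance of each pair and ``group_labels`` the cell type or
    cluster it was drawn within.
    """

    idx1: np.ndarray
    idx2: np.ndarray
    origins: list[str]
    group_labels: list[str]

    def __post_init__(self):
        self.idx1 = np.asarray(self.idx1, dtype=np.intp)
        self.idx2 = np.asarray(self.idx2, dtype=np.intp)
        if not (len(self.idx1) == len(self.idx2) == len(self.origins) == len(self.group_labels)):
            raise ValueError("pair columns must have equal length")

    def __len__(self) -> int:
        return len(self.idx1)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"idx1": self.idx1, "idx2": self.idx2,
                      "origin": self.origins}).to_csv(
            path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "PairedDataset":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=None,
                         names=["idx1", "idx2", "origin"])
        return cls(idx1=df["idx1"].to_numpy(), idx2=df["idx2"].to_numpy(),
                   origins=df["origin"].astype(str).tolist(),
                   group_labels=[""] * len(df))


@dataclass
class TransportPlan:
    """Per-cell-type exact optimal-transport couplings."""

    couplings: dict[str, np.ndarray]  # type -> gamma (n_ctr x n_sti)
    costs: dict[str, np.ndarray]  # type -> Euclidean cost matrix
    objective: dict[str, float]  # type -> <gamma, M>_F at the optimum


@dataclass
class EvalReport:
    metrics: dict[str, float]
    params: dict = field(default_factory=dict)
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def to_dict(self) -> dict:
        return {"metrics": self.metrics, "params": self.params, "seed": self.seed, "flags": self.flags}

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
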