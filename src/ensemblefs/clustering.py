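"""Random-forest proximity clustering and classical MDS embedding.

Proximity between two subjects is the fraction of trees in which they land
in the same terminal node. The embedding treats 1 - proximity as a squared
dissimilarity and applies classical (Torgerson) MDS: double-center, take the
top eigenvectors scaled by the square roots of their (nonnegative)
eigenvalues. Label separation in the embedding is quantified by the mean
silhouette, turning the qualitative "obese subjects cluster together"
observation into a number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score


@dataclass
class ProximityMatrix:
    values: np.ndarray  # (n, n) in [0, 1], symmetric, unit diagonal
    n_trees_used: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("proximity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("proximity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("proximities must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t")


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # (n, dims), centered, ordered by eigenvalue
    eigenvalues: np.ndarray  # full spectrum of the double-centered matrix

    def to_tsv(self, path, subject_ids=None, labels=None) -> None:
        import pandas as pd

        n, d = self.coordinates.shape
        data = {"subject_id": subject_ids if subject_ids is not None else np.arange(1, n + 1)}
        for k in range(d):
            data[f"dim{k + 1}"] = self.coordinates[:, k]
        if labels is not None:
            data["label"] = np.asarray(labels)
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def proximity_matrix(forest, X) -> ProximityMatrix:
    """Fraction of trees in which each subject pair shares a terminal node.

    ``forest`` is any object exposing ``apply(X) -> (n, n_trees)`` leaf
    indices (the :class:`~ensemblefs.learners.forest.Forest` handle).
    """
    leaves = np.asarray(forest.apply(np.asarray(X, dtype=float)))
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=float)
    for t in range(n_trees):
        col = leaves[:, t]
        prox += (col[:, None] == col[None, :])
    prox /= n_trees
    return ProximityMatrix(values=prox, n_trees_used=n_trees)


def mds_embed(prox: ProximityMatrix, dims: int = 2) -> MdsEmbedding:
    """Classical MDS of the proximity matrix (d^2 = 1 - proximity)."""
    D2 = 1.0 - prox.values
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(Bmat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.maximum(eigval, 0.0)
    rank = int(np.sum(pos > 1e-12 * max(pos.max(), 1.0)))
    if dims > rank:
        warnings.warn(
            f"requested {dims} dimensions but the centered matrix has rank {rank}; "
            "padding with zeros"
        )
    coords = eigvec[:, :dims] * np.sqrt(pos[:dims])[None, :]
    coords[:, rank:] = 0.0
    coords = coords - coords.mean(axis=0, keepdims=True)  # numerically exact centering
    return MdsEmbedding(coordinates=coords, eigenvalues=eigval)


def label_separation(embedding: MdsEmbedding, labels) -> float:
    """Mean silhouette of the embedding under binary labels.

    Degenerate case: if every subject sits at the same point, separation is
    defined as 0 (no geometry to separate).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both labels must be present")
    coords = embedding.coordinates
    if np.allclose(coords, coords[0]):
        return 0.0
    return float(silhouette_score(coords, labels))
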