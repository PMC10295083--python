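"""k-means over learned feature vectors and representative selection.

Positive-family sequences are embedded by a trained model (200-dim
autoencoder latents or 64-dim transformer Extract vectors), partitioned
with k-means, and each cluster is summarized by the member whose vector
lies closest to the cluster centroid.  A distance report compares every
sequence to a chosen reference in feature space, optionally joined with
externally computed alignment bitscores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans


@dataclass
class FeatureMatrix:
    ids: list[str]
    vectors: np.ndarray          # (n, d)
    family: str

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("feature matrix ids must be unique")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors disagree on n")

    def row(self, rid: str) -> np.ndarray:
        return self.vectors[self.ids.index(rid)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.vectors, index=self.ids).to_csv(path, sep="\t",
                                                          header=False)

    @classmethod
    def from_tsv(cls, path: str | Path, family: str = "unknown") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls(ids=[str(i) for i in df.index],
                   vectors=df.to_numpy(dtype=float), family=family)


@dataclass
class RepresentativeSet:
    k: int
    centroids: np.ndarray                     # (k, d)
    assignment: dict[str, int]                # id -> cluster
    seed: int
    inertia: float
    representatives: dict[int, str] = field(default_factory=dict)


def kmeans_cluster(matrix: FeatureMatrix, k: int = 7, seed: int = 0,
                   n_init: int = 10) -> RepresentativeSet:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` by inertia."""
    n = matrix.vectors.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.vectors)
    assignment = {rid: int(lab) for rid, lab in zip(matrix.ids, labels)}
    return RepresentativeSet(k=k, centroids=km.cluster_centers_,
                             assignment=assignment, seed=seed,
                             inertia=float(km.inertia_))


def select_representatives(reps: RepresentativeSet,
                           matrix: FeatureMatrix) -> RepresentativeSet:
    """Per cluster, the member nearest (Euclidean) to the centroid.

    Ties resolve to the earliest id in the matrix's input order; clusters
    that ended up empty are skipped with a warning.
    """
    reps.representatives = {}
    for c in range(reps.k):
        member_idx = [i for i, rid in enumerate(matrix.ids)
                      if reps.assignment.get(rid) == c]
        if not member_idx:
            warnings.warn(f"cluster {c} is empty; skipped", stacklevel=2)
            continue
        d = np.linalg.norm(matrix.vectors[member_idx] - reps.centroids[c], axis=1)
        best = member_idx[int(np.argmin(d))]
        reps.representatives[c] = matrix.ids[best]
    return reps


def distance_report(matrix: FeatureMatrix, reference_id: str,
                    bitscore_table: str | Path | None = None) -> pd.DataFrame:
    """Euclidean feature-space distance of every sequence to the reference.

    If a tab-separated (id, bitscore) table from an external similarity
    search is given, it is joined by id and the Spearman rank correlation
    between distance and bitscore is stored in ``df.attrs["spearman_r"]``.
    """
    if reference_id not in matrix.ids:
        raise KeyError(f"reference {reference_id!r} not in feature matrix")
    ref = matrix.row(reference_id)
    dist = np.linalg.norm(matrix.vectors - ref, axis=1)
    df = pd.DataFrame({"id": matrix.ids, "distance": dist})
    if bitscore_table is not None:
        bits = pd.read_csv(bitscore_table, sep="\t", header=None,
                           names=["id", "bitscore"], comment="#")
        df = df.merge(bits, on="id", how="left")
        both = df.dropna(subset=["bitscore"])
        others = both[both["id"] != reference_id]
        if len(others) >= 3:
            r, _ = spearmanr(others["distance"], others["bitscore"])
            df.attrs["spearman_r"] = float(r)
    return df
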