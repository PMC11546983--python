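"""Partitioning sequences with five algorithms and forming a consensus.

Each algorithm consumes the pairwise p-distance structure in the
representation natural to it:

* K-means — rows of the distance matrix as feature vectors (each sequence
  described by its distance profile);
* complete-linkage hierarchical and DBSCAN — the distance matrix as a
  precomputed metric (DBSCAN on the min–max *scaled* matrix, so that a
  0.5 neighbourhood radius is meaningful for p-distances that rarely
  exceed ~0.1);
* Brunet-style NMF (KL divergence, multiplicative updates, best of many
  random restarts) — the non-negative distance matrix, rows assigned to the
  dominant basis component;
* affinity propagation — the similarity matrix 1 − d, with the exemplar
  preference set to the median off-diagonal similarity (the customary
  default), so the number of clusters emerges from the data.

A consensus partition is formed by aligning cluster labels across
algorithms with Hungarian matching and voting per sequence; agreement is
quantified by pairwise adjusted Rand indices.  DBSCAN noise points (-1)
abstain from the vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN, KMeans
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import NMF
from sklearn.metrics import adjusted_rand_score

from .distances import DistanceMatrix, pairwise_similarity, scale_matrix

__all__ = [
    "ClusterResult",
    "ConsensusResult",
    "kmeans",
    "hierarchical_complete",
    "nmf_cluster",
    "dbscan",
    "affinity_propagation",
    "consensus",
    "cluster_all",
]


@dataclass
class ClusterResult:
    """Per-sequence integer labels from one algorithm (−1 = DBSCAN noise)."""

    algorithm: str
    labels: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def k_found(self) -> int:
        """Number of non-noise clusters."""
        return int(np.unique(self.labels[self.labels >= 0]).size)

    @property
    def n(self) -> int:
        return self.labels.size


@dataclass
class ConsensusResult:
    """Majority partition over several algorithms plus agreement statistics."""

    per_algorithm: list[ClusterResult]
    agreement: np.ndarray  # pairwise ARI, noise points excluded
    consensus_labels: np.ndarray
    unanimous: bool
    ambiguous: np.ndarray  # indices where the vote was tied

    @property
    def algorithms(self) -> list[str]:
        return [r.algorithm for r in self.per_algorithm]


def _dense_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber non-noise labels densely 0..k−1 in order of first appearance."""
    out = np.asarray(labels, dtype=int).copy()
    mapping: dict[int, int] = {}
    for i, lab in enumerate(out):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans(
    features: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """Lloyd's K-means, best of ``n_init`` random starts by SSE."""
    x = np.asarray(features, dtype=float)
    if k < 1 or k > x.shape[0]:
        raise ValueError(f"k={k} outside [1, {x.shape[0]}]")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(x)
    return ClusterResult(
        algorithm="kmeans",
        labels=_dense_relabel(km.labels_),
        params={"k": k, "n_init": n_init, "inertia": float(km.inertia_)},
        seed=seed,
    )


def hierarchical_complete(dm: DistanceMatrix, k: int) -> ClusterResult:
    """Complete-linkage agglomeration on the precomputed p-distances, cut at k."""
    if k < 1 or k > dm.n:
        raise ValueError(f"k={k} outside [1, {dm.n}]")
    z = linkage(dm.condensed(), method="complete")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    return ClusterResult(
        algorithm="hierarchical",
        labels=_dense_relabel(labels),
        params={"k": k, "linkage": "complete"},
    )


def nmf_cluster(
    matrix: np.ndarray, rank: int, nrun: int = 1000, seed: int = 0,
    max_iter: int = 500,
) -> ClusterResult:
    """KL-divergence NMF with multiplicative updates, best of ``nrun`` restarts.

    Each row is assigned to the basis component with the largest
    coefficient.  The restart with the smallest final divergence wins.
    """
    x = np.asarray(matrix, dtype=float)
    if x.min() < 0:
        raise ValueError("NMF input must be non-negative")
    if rank >= min(x.shape):
        raise ValueError("rank must be smaller than both matrix dimensions")
    # KL updates stall on all-zero rows/columns; a tiny floor keeps the
    # divergence finite without disturbing the block structure.
    x = np.maximum(x, 1e-9)
    rng = np.random.default_rng(seed)
    best_err = np.inf
    best_w: np.ndarray | None = None
    for _ in range(nrun):
        rs = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            random_state=rs,
            tol=1e-6,
        )
        w = model.fit_transform(x)
        if model.reconstruction_err_ < best_err:
            best_err = float(model.reconstruction_err_)
            best_w = w
    assert best_w is not None
    labels = _dense_relabel(np.argmax(best_w, axis=1))
    return ClusterResult(
        algorithm="nmf",
        labels=labels,
        params={"rank": rank, "nrun": nrun, "divergence": best_err},
        seed=seed,
    )


def dbscan(
    data: np.ndarray | DistanceMatrix,
    eps: float = 0.5,
    min_pts: int = 20,
) -> ClusterResult:
    """Density clustering; ``min_pts`` counts the point itself; noise = −1."""
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    if isinstance(data, DistanceMatrix):
        model = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed")
        labels = model.fit(data.d).labels_
    else:
        model = DBSCAN(eps=eps, min_samples=min_pts)
        labels = model.fit(np.asarray(data, dtype=float)).labels_
    return ClusterResult(
        algorithm="dbscan",
        labels=_dense_relabel(labels),
        params={"eps": eps, "min_pts": min_pts},
    )


def affinity_propagation(
    similarity: np.ndarray,
    damping: float = 0.5,
    max_iter: int = 1000,
    preference: float | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Responsibility/availability message passing on a similarity matrix.

    ``preference`` defaults to the median off-diagonal similarity, so the
    number of exemplars — and hence clusters — emerges from the data.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if s.shape[0] == 1:
        return ClusterResult(
            algorithm="affinity_propagation",
            labels=np.zeros(1, dtype=int),
            params={"preference": None, "converged": True},
            seed=seed,
        )
    if preference is None:
        off = s[~np.eye(s.shape[0], dtype=bool)]
        preference = float(np.median(off))
    model = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iter,
        preference=preference,
        random_state=seed,
    ).fit(s)
    converged = model.n_iter_ < max_iter and model.cluster_centers_indices_.size > 0
    return ClusterResult(
        algorithm="affinity_propagation",
        labels=_dense_relabel(model.labels_),
        params={
            "damping": damping,
            "preference": preference,
            "converged": bool(converged),
        },
        seed=seed,
    )


def _align_to(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to maximise overlap with ``reference`` (Hungarian)."""
    mask = (reference >= 0) & (labels >= 0)
    ref_ids = np.unique(reference[reference >= 0])
    lab_ids = np.unique(labels[labels >= 0])
    overlap = np.zeros((lab_ids.size, ref_ids.size))
    for i, a in enumerate(lab_ids):
        for j, b in enumerate(ref_ids):
            overlap[i, j] = np.count_nonzero(
                mask & (labels == a) & (reference == b)
            )
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(lab_ids[r]): int(ref_ids[c]) for r, c in zip(rows, cols)}
    next_free = int(max(ref_ids, default=-1)) + 1
    out = labels.copy()
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab in mapping:
            out[i] = mapping[lab]
        else:  # unmatched extra cluster keeps a fresh id
            mapping[lab] = next_free
            next_free += 1
            out[i] = mapping[lab]
    return out


def _pair_ari(a: np.ndarray, b: np.ndarray) -> float:
    keep = (a >= 0) & (b >= 0)
    if not keep.any():
        return float("nan")
    return float(adjusted_rand_score(a[keep], b[keep]))


def consensus(results: Sequence[ClusterResult]) -> ConsensusResult:
    """Majority partition after Hungarian label alignment.

    Noise points abstain; ties are resolved by the hierarchical result when
    present (deterministic given the matrix), else by the first algorithm.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 clusterings for a consensus")
    n = results[0].n
    if any(r.n != n for r in results):
        raise ValueError("clusterings cover different sequence sets")

    reference = results[0].labels
    aligned = np.vstack([_align_to(reference, r.labels) for r in results])

    m = len(results)
    agreement = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            agreement[i, j] = agreement[j, i] = _pair_ari(
                results[i].labels, results[j].labels
            )
    unanimous = bool(np.all(agreement == 1.0))

    tiebreak_idx = next(
        (i for i, r in enumerate(results) if r.algorithm == "hierarchical"), 0
    )
    cons = np.empty(n, dtype=int)
    ambiguous: list[int] = []
    for i in range(n):
        votes = aligned[:, i]
        votes = votes[votes >= 0]
        if votes.size == 0:
            cons[i] = -1
            ambiguous.append(i)
            continue
        vals, counts = np.unique(votes, return_counts=True)
        winners = vals[counts == counts.max()]
        if winners.size > 1:
            ambiguous.append(i)
            tb = aligned[tiebreak_idx, i]
            cons[i] = tb if tb in winners else int(winners[0])
        else:
            cons[i] = int(winners[0])
    return ConsensusResult(
        per_algorithm=list(results),
        agreement=agreement,
        consensus_labels=cons,
        unanimous=unanimous,
        ambiguous=np.asarray(ambiguous, dtype=int),
    )


def cluster_all(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    nmf_nrun: int = 1000,
    dbscan_eps: float = 0.5,
    dbscan_min_pts: int = 20,
    ap_damping: float = 0.5,
    kmeans_n_init: int = 10,
) -> ConsensusResult:
    """Run all five algorithms on one distance matrix and form the consensus.

    K-means/hierarchical/NMF receive the requested ``k``; DBSCAN (on the
    min–max scaled matrix) and affinity propagation find their own.
    """
    scaled = scale_matrix(dm)
    results = [
        kmeans(dm.d, k=k, seed=seed, n_init=kmeans_n_init),
        hierarchical_complete(dm, k=k),
        nmf_cluster(dm.d, rank=k, nrun=nmf_nrun, seed=seed),
        dbscan(scaled, eps=dbscan_eps, min_pts=dbscan_min_pts),
        affinity_propagation(pairwise_similarity(dm), damping=ap_damping, seed=seed),
    ]
    return consensus(results)
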