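"""Cluster-number selection: SSE/elbow, mean silhouette, gap statistic.

Three criteria evaluated over a range of candidate cluster counts k:

* SSE — within-cluster sum of squared Euclidean errors,
  ``sum_i sum_{p in C_i} ||p − m_i||²``; the elbow is formalised as the k
  with the largest second forward difference of the SSE curve (a visual
  "inflection point" made computable).
* mean silhouette — s_i = (b_i − a_i) / max(a_i, b_i) with a_i the mean
  within-cluster distance (excluding self) and b_i the smallest mean
  distance to another cluster; singleton clusters score s_i = 0.
* gap statistic — gap(k) = E*[log W_k] − log W_k, where the expectation is
  a Monte-Carlo average over B reference datasets drawn uniformly over each
  feature's observed range; selected by the 1-standard-error rule
  (smallest k with gap(k) ≥ gap(k+1) − se(k+1)).

The final choice is the majority over the three criteria, with the elbow
breaking ties.  The full curves are always reported — the gap curve in
particular can have several local maxima, and inspecting it beats trusting
a single argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .distances import DistanceMatrix

__all__ = [
    "ValidityCurve",
    "sse",
    "silhouette",
    "gap_statistic",
    "validity_curve",
    "choose_k",
]


@dataclass
class ValidityCurve:
    """SSE, mean silhouette, and gap statistic per candidate k."""

    k_values: np.ndarray
    sse: np.ndarray
    mean_silhouette: np.ndarray  # NaN at k=1 (undefined)
    gap: np.ndarray
    gap_se: np.ndarray
    b_samples: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "sse": self.sse,
                "mean_silhouette": self.mean_silhouette,
                "gap": self.gap,
                "gap_se": self.gap_se,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sse(features: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to centroids."""
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.shape[0] == 0:
        raise ValueError("no data rows")
    if x.shape[0] != labels.size:
        raise ValueError("one label per row required")
    total = 0.0
    for lab in np.unique(labels):
        members = x[labels == lab]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {lab!r}")
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total


def silhouette(
    data: DistanceMatrix | np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-point silhouette values and their mean.

    ``data`` is either a precomputed :class:`DistanceMatrix` or a feature
    matrix (Euclidean distances are derived).  Points in singleton clusters
    score 0.  Noise labels (−1) are excluded from the mean and from other
    points' neighbour sets.
    """
    if isinstance(data, DistanceMatrix):
        d = data.d
    else:
        x = np.asarray(data, dtype=float)
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    labels = np.asarray(labels)
    n = labels.size
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    clusters = [c for c in np.unique(labels) if c >= 0]
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    for i in range(n):
        if labels[i] < 0:
            s[i] = np.nan
            continue
        own = (labels == labels[i]) & (np.arange(n) != i)
        if not own.any():  # singleton cluster
            s[i] = 0.0
            continue
        a_i = d[i, own].mean()
        b_i = min(
            d[i, labels == c].mean() for c in clusters if c != labels[i]
        )
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    mean = float(np.nanmean(s))
    return s, mean


def _pooled_wk(features: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        return sse(features, np.zeros(features.shape[0], dtype=int))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(features)
    return float(km.inertia_)


def gap_statistic(
    features: np.ndarray,
    k_range,
    b: int = 100,
    seed: int = 0,
    reference: str = "pca",
) -> tuple[np.ndarray, np.ndarray]:
    """Gap statistic and its Monte-Carlo standard error per k.

    With ``reference="pca"`` (the default, matching R ``clusGap``'s
    ``spaceH0="scaledPCA"``) the null datasets are drawn uniformly over the
    ranges of the principal-axis-rotated data and rotated back — the
    reference box follows the data's main axes, which keeps the null
    honest when features are strongly correlated (as distance-matrix rows
    are).  ``reference="uniform"`` draws uniformly over each raw feature's
    observed range instead.  W_k comes from K-means at each k;
    se = sd · sqrt(1 + 1/b).
    """
    x = np.asarray(features, dtype=float)
    if b < 1:
        raise ValueError("need at least one reference sample")
    if reference not in ("pca", "uniform"):
        raise ValueError(f"unknown reference distribution {reference!r}")
    lo_raw, hi_raw = x.min(axis=0), x.max(axis=0)
    if np.all(hi_raw == lo_raw):
        raise ValueError("degenerate data: all rows identical")
    if reference == "pca":
        center = x.mean(axis=0)
        _, _, vt = np.linalg.svd(x - center, full_matrices=False)
        rotated = (x - center) @ vt.T
        lo, hi = rotated.min(axis=0), rotated.max(axis=0)
    else:
        vt = None
        center = None
        lo, hi = lo_raw, hi_raw
    rng = np.random.default_rng(seed)
    k_range = list(k_range)
    log_wk = np.empty(len(k_range))
    for ki, k in enumerate(k_range):
        w = _pooled_wk(x, k, seed)
        log_wk[ki] = np.log(w) if w > 0 else -np.inf
    ref_log = np.empty((b, len(k_range)))
    for rep in range(b):
        draw = rng.uniform(lo, hi, size=(x.shape[0], lo.size))
        ref = draw @ vt + center if vt is not None else draw
        rs = int(rng.integers(0, 2**31 - 1))
        for ki, k in enumerate(k_range):
            ref_log[rep, ki] = np.log(_pooled_wk(ref, k, rs))
    gap = ref_log.mean(axis=0) - log_wk
    sd = ref_log.std(axis=0)  # population sd, as in the canonical recipe
    gap_se = sd * np.sqrt(1.0 + 1.0 / b)
    return gap, gap_se


def validity_curve(
    dm: DistanceMatrix,
    k_range=range(1, 9),
    b: int = 100,
    seed: int = 0,
) -> ValidityCurve:
    """Evaluate all three criteria over ``k_range``.

    Rows of the distance matrix serve as the K-means feature space (each
    sequence described by its distance profile); silhouettes use the
    precomputed p-distances directly.
    """
    features = dm.d
    k_values = np.array(sorted(k_range))
    sse_vals = np.empty(k_values.size)
    sil_vals = np.full(k_values.size, np.nan)
    for ki, k in enumerate(k_values):
        if k == 1:
            sse_vals[ki] = sse(features, np.zeros(dm.n, dtype=int))
            continue
        km = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit(
            features
        )
        sse_vals[ki] = float(km.inertia_)
        _, sil_vals[ki] = silhouette(dm, km.labels_)
    gap, gap_se = gap_statistic(features, k_values, b=b, seed=seed)
    return ValidityCurve(
        k_values=k_values,
        sse=sse_vals,
        mean_silhouette=sil_vals,
        gap=gap,
        gap_se=gap_se,
        b_samples=b,
        seed=seed,
    )


def choose_k(curve: ValidityCurve) -> tuple[int, dict]:
    """Pick the cluster count by majority over elbow, silhouette and gap.

    elbow      — k maximising the second forward difference of SSE;
    silhouette — argmax of the mean silhouette;
    gap        — smallest k with gap(k) ≥ gap(k+1) − se(k+1) (1-SE rule).

    Ties (no majority) fall back on the elbow.  A flat SSE curve leaves the
    elbow undefined (None).
    """
    k = np.asarray(curve.k_values)
    if k.size < 3:
        raise ValueError("need at least 3 k values for elbow detection")

    d2 = curve.sse[:-2] - 2 * curve.sse[1:-1] + curve.sse[2:]
    if np.allclose(curve.sse, curve.sse[0]):
        k_elbow = None
    else:
        k_elbow = int(k[1:-1][int(np.argmax(d2))])

    if np.all(np.isnan(curve.mean_silhouette)):
        k_sil = None
    else:
        k_sil = int(k[int(np.nanargmax(curve.mean_silhouette))])

    k_gap = None
    for ki in range(k.size - 1):
        if curve.gap[ki] >= curve.gap[ki + 1] - curve.gap_se[ki + 1]:
            k_gap = int(k[ki])
            break
    if k_gap is None and k.size:
        k_gap = int(k[-1])

    per_criterion = {"elbow": k_elbow, "silhouette": k_sil, "gap": k_gap}
    votes = [v for v in per_criterion.values() if v is not None]
    if not votes:
        raise ValueError("no criterion produced a cluster count")
    vals, counts = np.unique(votes, return_counts=True)
    if counts.max() > 1:
        k_best = int(vals[np.argmax(counts)])
    else:
        k_best = k_elbow if k_elbow is not None else votes[0]
    return k_best, per_criterion
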