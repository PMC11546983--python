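"""Pairwise p-distances with pairwise deletion, scaling and group summaries.

The p-distance between two aligned sequences is the proportion of differing
nucleotide sites among the sites compared.  "Ambiguous positions" — gaps and
non-ACGT IUPAC codes — are removed independently for each sequence pair
(pairwise deletion, MEGA semantics), so every pair carries its own count of
valid sites.

Distances are proportions in [0, 1] throughout; percentages appear only in
reports.  For display and for density clustering the distances can be
min–max scaled, ScaleD_i = (D_i − min D) / (max D − min D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = [
    "DistanceMatrix",
    "GroupDistanceSummary",
    "ScaledDistances",
    "UndefinedDistanceError",
    "p_distance",
    "distance_matrix",
    "scale_distances",
    "scale_matrix",
    "group_distance_sets",
    "pairwise_similarity",
]

_VALID = frozenset(b"ACGT")


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no unambiguous overlapping sites."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with per-pair valid-site counts."""

    ids: list[str]
    d: np.ndarray
    n_valid: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=int)
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_valid.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("p-distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (id_a, id_b, distance, n_valid)."""
        rows = [
            (self.ids[i], self.ids[j], self.d[i, j], int(self.n_valid[i, j]))
            for i, j in combinations(range(self.n), 2)
        ]
        return pd.DataFrame(
            rows, columns=["id_a", "id_b", "distance", "n_valid"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class ScaledDistances:
    """Min–max scaled values with the raw extremes used."""

    values: np.ndarray
    min_raw: float
    max_raw: float


@dataclass
class GroupDistanceSummary:
    """Within- and between-group p-distance sets and their averages.

    ``within[g]`` holds the off-diagonal entries of group g's block of the
    distance matrix — m(m−1) values for m members, i.e. every ordered pair,
    the convention used when a full symmetric block is plotted (18 members
    → 306 data points).  ``between[(a, b)]`` holds the |a|·|b| cross-pair
    distances.  ``averages`` maps the same keys to arithmetic means
    (unaffected by the symmetric duplication).  Singleton groups contribute
    no within list.
    """

    within: dict[str, np.ndarray]
    between: dict[tuple[str, str], np.ndarray]
    averages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.averages:
            self.averages = {
                k: float(np.mean(v))
                for k, v in {**self.within, **self.between}.items()
                if len(v)
            }


def _encode_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    mask = np.zeros(arr.shape, dtype=bool)
    for b in _VALID:
        mask |= arr == b
    return mask


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of differing sites between two aligned sequences.

    Sites where either sequence carries a gap or an ambiguous base are
    excluded for this pair (pairwise deletion).

    Returns
    -------
    (distance, n_valid)
        ``distance`` = mismatches / ``n_valid`` over the retained sites.

    Raises
    ------
    UndefinedDistanceError
        If no unambiguous overlapping site remains.
    ValueError
        If the sequences differ in length.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = _encode_bytes(seq_a.upper())
    b = _encode_bytes(seq_b.upper())
    keep = _valid_mask(a) & _valid_mask(b)
    n_valid = int(keep.sum())
    if n_valid == 0:
        raise UndefinedDistanceError(
            "no overlapping unambiguous sites between the two sequences"
        )
    diff = int(np.count_nonzero(a[keep] != b[keep]))
    return diff / n_valid, n_valid


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs pairwise-deletion p-distances for an alignment."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    enc = np.vstack([_encode_bytes(s) for s in aln.seqs])
    valid = _valid_mask(enc)
    n = aln.n
    d = np.zeros((n, n))
    nv = np.full((n, n), aln.length, dtype=int)
    for i in range(n):
        keep = valid[i] & valid[i + 1 :]
        counts = keep.sum(axis=1)
        zero = np.nonzero(counts == 0)[0]
        if zero.size:
            j = int(zero[0]) + i + 1
            raise UndefinedDistanceError(
                f"no overlapping unambiguous sites between "
                f"{aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        diffs = ((enc[i] != enc[i + 1 :]) & keep).sum(axis=1)
        d[i, i + 1 :] = diffs / counts
        nv[i, i + 1 :] = counts
    d = d + d.T
    nv = np.minimum(nv, nv.T)
    np.fill_diagonal(nv, valid.sum(axis=1))
    return DistanceMatrix(ids=list(aln.ids), d=d, n_valid=nv)


def scale_distances(values) -> ScaledDistances:
    """Min–max scale values into [0, 1]: (v − min) / (max − min).

    A constant vector (max == min) maps to all zeros: it carries no
    contrast, and an error here would break pipelines on trivial inputs.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty value list")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return ScaledDistances(np.zeros_like(v), lo, hi)
    return ScaledDistances((v - lo) / (hi - lo), lo, hi)


def scale_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Min–max scale the off-diagonal entries of a distance matrix.

    The diagonal stays 0 and the extremes are taken over off-diagonal
    entries only, so self-distances do not pin the minimum.
    """
    off = dm.condensed()
    scaled = scale_distances(off)
    n = dm.n
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = scaled.values
    out = out + out.T
    return DistanceMatrix(ids=list(dm.ids), d=out, n_valid=dm.n_valid.copy())


def group_distance_sets(
    dm: DistanceMatrix, labels: dict[str, str]
) -> GroupDistanceSummary:
    """Split the pairwise distances into within- and between-group sets.

    ``labels`` maps every id in ``dm`` to its group.  Between-group keys are
    ordered tuples (first-seen group order) so each unordered group pair
    appears once.
    """
    unknown = [sid for sid in dm.ids if sid not in labels]
    if unknown:
        raise ValueError(f"ids without a group label: {', '.join(unknown)}")
    groups: dict[str, list[int]] = {}
    for idx, sid in enumerate(dm.ids):
        groups.setdefault(labels[sid], []).append(idx)
    within: dict[str, np.ndarray] = {}
    for g, members in groups.items():
        if len(members) >= 2:
            block = dm.d[np.ix_(members, members)]
            within[g] = block[~np.eye(len(members), dtype=bool)]
    between: dict[tuple[str, str], np.ndarray] = {}
    names = list(groups)
    for a, b in combinations(names, 2):
        vals = dm.d[np.ix_(groups[a], groups[b])].ravel()
        between[(a, b)] = vals
    return GroupDistanceSummary(within=within, between=between)


def pairwise_similarity(dm: DistanceMatrix) -> np.ndarray:
    """Similarity matrix 1 − d: unit diagonal, monotone-decreasing in d."""
    return 1.0 - dm.d
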