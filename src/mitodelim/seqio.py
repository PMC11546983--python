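"""Aligned-FASTA input/output and ordinal encoding.

An :class:`Alignment` is the package's central container: equal-length,
uppercase DNA sequences (gaps ``-`` and IUPAC ambiguity codes allowed) with
unique identifiers and optional per-sequence group labels.

For machine-learning stages the alignment is ordinal-encoded column by
column: A=1, T=2, C=3, G=4, gap=0.  Ambiguity codes (N, R, Y, ...) also map
to 0 — the encoding defines only five symbols and 0 is its missing-data
sink; inventing an ordinal rank for ambiguous bases would impose a spurious
ordering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "EncodedMatrix",
    "AlignmentError",
    "read_alignment",
    "write_fasta",
    "read_labels",
    "write_labels",
    "encode_ordinal",
]

#: ordinal code per base; everything else (N, IUPAC ambiguity) encodes to 0
ORDINAL_CODE = {"A": 1, "T": 2, "C": 3, "G": 4, "-": 0}

#: symbols treated as ambiguous/missing in pairwise comparisons
_UNAMBIGUOUS = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, ...)."""


@dataclass
class Alignment:
    """Equal-length DNA sequences with unique ids and optional group labels."""

    ids: list[str]
    seqs: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError(
                f"{len(self.ids)} ids but {len(self.seqs)} sequences"
            )
        if not self.seqs:
            raise AlignmentError("empty alignment")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise AlignmentError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
        length = len(self.seqs[0])
        if length == 0:
            raise AlignmentError("zero-length sequences")
        ragged = [
            sid for sid, s in zip(self.ids, self.seqs) if len(s) != length
        ]
        if ragged:
            raise AlignmentError(
                "sequences not all of length "
                f"{length}; offending ids: {', '.join(ragged)}"
            )
        if self.labels is not None and len(self.labels) != len(self.ids):
            raise AlignmentError("labels length does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns (bp)."""
        return len(self.seqs[0])

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.seqs == other.seqs
            and self.labels == other.labels
        )

    def with_labels(self, labels: dict[str, str]) -> "Alignment":
        """Return a copy carrying per-sequence labels from an id->label map."""
        missing = [sid for sid in self.ids if sid not in labels]
        if missing:
            raise AlignmentError(f"no label for ids: {', '.join(missing)}")
        return Alignment(
            ids=list(self.ids),
            seqs=list(self.seqs),
            labels=[labels[sid] for sid in self.ids],
        )


@dataclass
class EncodedMatrix:
    """Ordinal-encoded alignment: integers in {0..4}, one row per sequence."""

    values: np.ndarray
    column_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.column_map is None:
            self.column_map = np.arange(self.values.shape[1])
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > 4:
            raise ValueError("encoded entries must lie in {0..4}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are case-folded to uppercase and RNA ``U`` is mapped to ``T``.
    The id is the first whitespace-delimited token of the header.

    Raises
    ------
    AlignmentError
        On ragged sequence lengths (message names the offending ids),
        duplicate ids, or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    seqs = [_clean(str(r.seq)) for r in records]
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write an alignment as FASTA (fixed line wrap for determinism)."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV into an id->label map."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise AlignmentError(f"malformed label row: {row!r}")
            labels[row[0]] = row[1]
    return labels


def write_labels(ids: list[str], labels: list, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, lab in zip(ids, labels):
            w.writerow([sid, lab])


def encode_ordinal(aln: Alignment) -> EncodedMatrix:
    """Ordinal-encode an alignment: A=1, T=2, C=3, G=4, gap/ambiguity=0."""
    table = np.zeros(128, dtype=np.int8)
    for base, code in ORDINAL_CODE.items():
        table[ord(base)] = code
    rows = [
        table[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        for s in aln.seqs
    ]
    return EncodedMatrix(values=np.vstack(rows))


def decode_ordinal(values: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_ordinal` on unambiguous columns (0 -> '-')."""
    rev = {v: k for k, v in ORDINAL_CODE.items()}
    return ["".join(rev[int(v)] for v in row) for row in np.asarray(values)]
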