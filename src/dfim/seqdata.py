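"""Sequence encoding, coordinate conventions and FASTA/BED I/O.

All coordinates are 0-based internally; BED intervals are 0-based
half-open.  One-hot matrices are 4 x L with fixed row order A, C, G, T —
the only supported convention.  Ambiguity codes (including N) are
rejected: attribution scores on imputed bases would be silently wrong.
Only the forward strand is represented; reverse-complement handling is
the caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "BASE_INDEX",
    "OneHotSequence",
    "FeatureLocus",
    "one_hot_encode",
    "decode",
    "read_fasta",
    "write_fasta",
    "read_feature_bed",
]


class SequenceError(ValueError):
    """Invalid sequence content or coordinates."""


@dataclass
class OneHotSequence:
    """A DNA sequence as a real-valued 4 x L matrix (rows A, C, G, T).

    Entries are 0/1 for a natural sequence; columns may hold fractional
    values in [0, 1] after a GC-background mutation, but every column
    always sums to 1.
    """

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] == 0:
            raise SequenceError(
                f"one-hot matrix must be 4 x L with L >= 1, got shape {self.matrix.shape}"
            )
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise SequenceError("one-hot entries must lie in [0, 1]")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise SequenceError(f"column {bad} sums to {colsums[bad]!r}, expected 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def is_one_hot(self) -> bool:
        """True when every column is a strict 0/1 indicator."""
        return bool(np.all((self.matrix == 0.0) | (self.matrix == 1.0)))

    def observed_base(self, position: int) -> str:
        """Base with the largest weight at ``position`` (ties -> A<C<G<T)."""
        if not 0 <= position < self.length:
            raise SequenceError(f"position {position} out of range [0, {self.length})")
        return BASES[int(np.argmax(self.matrix[:, position]))]

    def copy(self) -> "OneHotSequence":
        return OneHotSequence(self.id, self.matrix.copy())


@dataclass(frozen=True)
class FeatureLocus:
    """A source/target feature: one nucleotide or a contiguous motif span.

    ``positions`` are 0-based and, for motifs, contiguous; ``bases`` holds
    the observed base(s). Forward strand only.
    """

    kind: str  # "nucleotide" | "motif"
    positions: tuple[int, ...]
    bases: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "motif"):
            raise SequenceError(f"unknown locus kind {self.kind!r}")
        if len(self.positions) == 0:
            raise SequenceError("empty locus")
        if self.kind == "nucleotide" and len(self.positions) != 1:
            raise SequenceError("nucleotide locus must cover exactly one position")
        if len(self.positions) != len(self.bases):
            raise SequenceError("positions and bases differ in length")
        if any(b not in BASE_INDEX for b in self.bases):
            raise SequenceError(f"invalid base in locus: {self.bases!r}")
        if self.strand != "+":
            raise SequenceError("only the + strand is supported")
        diffs = np.diff(self.positions)
        if len(diffs) and not np.all(diffs == 1):
            raise SequenceError("motif span must be contiguous and ascending")

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        """Exclusive end, BED-style."""
        return self.positions[-1] + 1

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def overlaps(self, other: "FeatureLocus") -> bool:
        return self.start < other.end and other.start < self.end

    def validate_against(self, x: OneHotSequence) -> None:
        if self.start < 0 or self.end > x.length:
            raise SequenceError(
                f"locus {self.span} out of range for sequence {x.id!r} of length {x.length}"
            )
        for pos, base in zip(self.positions, self.bases):
            if x.observed_base(pos) != base:
                raise SequenceError(
                    f"locus base {base} at position {pos} disagrees with observed "
                    f"{x.observed_base(pos)} in sequence {x.id!r}"
                )


def nucleotide_locus(base: str, position: int) -> FeatureLocus:
    return FeatureLocus("nucleotide", (position,), base)


def motif_locus(x: OneHotSequence, start: int, end: int) -> FeatureLocus:
    """Motif locus over [start, end) with bases read off ``x``."""
    if not (0 <= start < end <= x.length):
        raise SequenceError(
            f"span [{start}, {end}) out of range for sequence {x.id!r} of length {x.length}"
        )
    bases = "".join(x.observed_base(p) for p in range(start, end))
    kind = "nucleotide" if end - start == 1 else "motif"
    return FeatureLocus(kind, tuple(range(start, end)), bases)


def one_hot_encode(seq: str, id: str = "seq") -> OneHotSequence:
    """Encode a DNA string as a 4 x L one-hot matrix (rows A, C, G, T)."""
    if not seq:
        raise SequenceError("empty sequence")
    seq = seq.upper()
    L = len(seq)
    matrix = np.zeros((4, L))
    for p, base in enumerate(seq):
        row = BASE_INDEX.get(base)
        if row is None:
            raise SequenceError(
                f"invalid character {base!r} at position {p} (only A/C/G/T supported)"
            )
        matrix[row, p] = 1.0
    return OneHotSequence(id, matrix)


def decode(x: OneHotSequence) -> str:
    """Invert :func:`one_hot_encode`; defined only for strict one-hot input."""
    if not x.is_one_hot():
        raise SequenceError(
            f"sequence {x.id!r} has fractional columns; decoding a "
            "background-mutated sequence is undefined"
        )
    return "".join(BASES[i] for i in np.argmax(x.matrix, axis=0))


def read_fasta(path: str | Path) -> list[OneHotSequence]:
    """Read a multi-record FASTA into one-hot sequences.

    Duplicate ids, empty records and ambiguity codes are all rejected.
    """
    seqs: list[OneHotSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise SequenceError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        raw = str(record.seq).upper()
        if not raw:
            raise SequenceError(f"empty FASTA record {record.id!r} in {path}")
        for p, base in enumerate(raw):
            if base not in BASE_INDEX:
                raise SequenceError(
                    f"record {record.id!r}: invalid character {base!r} at offset {p}"
                )
        seqs.append(one_hot_encode(raw, id=record.id))
    if not seqs:
        raise SequenceError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Iterable[OneHotSequence], path: str | Path) -> None:
    """Write one-hot sequences as FASTA, wrapped at 80 columns."""
    records = [SeqRecord(Seq(decode(x)), id=x.id, description="") for x in seqs]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=80).write_file(records)


def read_feature_bed(
    path: str | Path, seqs: Sequence[OneHotSequence]
) -> list[tuple[FeatureLocus, str, str]]:
    """Read a BED3+ file of feature intervals against ``seqs``.

    Returns ``(locus, sequence_id, name)`` triples; ``name`` is the
    optional 4th BED column ("." when absent).  Intervals are 0-based
    half-open; bases are filled from the referenced sequence.
    """
    by_id = {x.id: x for x in seqs}
    out: list[tuple[FeatureLocus, str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise SequenceError(f"{path} line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            if chrom not in by_id:
                raise SequenceError(f"{path} line {lineno}: unknown sequence id {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise SequenceError(f"{path} line {lineno}: non-integer coordinates") from exc
            x = by_id[chrom]
            if not (0 <= start < end <= x.length):
                raise SequenceError(
                    f"{path} line {lineno}: interval [{start}, {end}) out of range "
                    f"for {chrom!r} of length {x.length}"
                )
            name = fields[3] if len(fields) > 3 else "."
            out.append((motif_locus(x, start, end), chrom, name))
    return out
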