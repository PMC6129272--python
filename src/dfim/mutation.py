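"""Perturbation operators: point mutation, GC-background motif mutation,
and the dinucleotide-preserving shuffle used to build empirical nulls.

All operators are pure — the input object is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import BASE_INDEX, BASES, FeatureLocus, OneHotSequence, SequenceError

__all__ = [
    "MutationSpec",
    "apply_point_mutation",
    "apply_background_mutation",
    "apply_mutation",
    "dinucleotide_shuffle",
]

# rows C and G in the A,C,G,T convention
_GC_ROWS = (1, 2)
_AT_ROWS = (0, 3)


@dataclass(frozen=True)
class MutationSpec:
    """How a source feature is perturbed.

    ``point``: flip the single observed base to ``mutant_base``.
    ``motif_background``: replace every column of a motif span with the
    fractional background composition implied by ``f_gc``.
    """

    kind: str  # "point" | "motif_background"
    source: FeatureLocus
    mutant_base: str | None = None
    f_gc: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.source.kind != "nucleotide":
                raise SequenceError("point mutation requires a nucleotide locus")
            if self.mutant_base not in BASE_INDEX:
                raise SequenceError(f"invalid mutant base {self.mutant_base!r}")
            if self.mutant_base == self.source.bases:
                raise SequenceError(
                    f"mutant base {self.mutant_base} equals the observed base"
                )
        elif self.kind == "motif_background":
            if self.f_gc is None or not 0.0 < self.f_gc < 1.0:
                raise SequenceError("f_gc must lie in (0, 1)")
        else:
            raise SequenceError(f"unknown mutation kind {self.kind!r}")


def apply_point_mutation(x: OneHotSequence, s: int, mutant_base: str) -> OneHotSequence:
    """Switch the observed base at position ``s`` to ``mutant_base``.

    All other columns are bit-identical to the input.
    """
    if not 0 <= s < x.length:
        raise SequenceError(f"position {s} out of range [0, {x.length})")
    col = x.matrix[:, s]
    if not np.all((col == 0.0) | (col == 1.0)):
        raise SequenceError(f"column {s} is fractional; point mutation undefined")
    observed = x.observed_base(s)
    if mutant_base not in BASE_INDEX:
        raise SequenceError(f"invalid mutant base {mutant_base!r}")
    if mutant_base == observed:
        raise SequenceError(f"mutant base {mutant_base} equals observed base at {s}")
    matrix = x.matrix.copy()
    matrix[:, s] = 0.0
    matrix[BASE_INDEX[mutant_base], s] = 1.0
    return OneHotSequence(x.id, matrix)


def apply_background_mutation(
    x: OneHotSequence, span: FeatureLocus, f_gc: float
) -> OneHotSequence:
    """Replace a motif span with the expected GC-background composition.

    Every column in the span gets C and G rows set to f_gc/2 and A and T
    rows to (1 - f_gc)/2, so the column still sums to 1 and its total
    C+G mass equals f_gc.  Columns outside the span are untouched.
    """
    if not 0.0 < f_gc < 1.0:
        raise SequenceError("f_gc must lie in (0, 1)")
    span.validate_against(x)
    matrix = x.matrix.copy()
    cols = list(span.positions)
    for r in _GC_ROWS:
        matrix[r, cols] = f_gc / 2.0
    for r in _AT_ROWS:
        matrix[r, cols] = (1.0 - f_gc) / 2.0
    return OneHotSequence(x.id, matrix)


def apply_mutation(x: OneHotSequence, spec: MutationSpec) -> OneHotSequence:
    """Dispatch a :class:`MutationSpec` to the matching operator."""
    if spec.kind == "point":
        return apply_point_mutation(x, spec.source.start, spec.mutant_base)
    return apply_background_mutation(x, spec.source, spec.f_gc)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """All 16 dinucleotide counts (absent pairs counted as 0)."""
    counts = {a + b: 0 for a in BASES for b in BASES}
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    return counts


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Shuffle ``seq`` preserving all 16 dinucleotide counts exactly.

    Euler-path construction (Altschul & Erickson): the sequence is a
    walk on the 4-base graph whose edges are its dinucleotides.  A
    random final-exit edge per vertex is drawn until those edges form an
    arborescence into the terminal base; remaining out-edges are then
    permuted and the walk replayed.  First and last nucleotides are
    therefore preserved — the shuffle is not full randomization.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise SequenceError("dinucleotide shuffle requires length >= 2")
    for p, b in enumerate(seq):
        if b not in BASE_INDEX:
            raise SequenceError(f"invalid character {b!r} at position {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out_edges: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        out_edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    vertices = list(out_edges)

    def _reaches_last(final_exit: dict[str, str]) -> bool:
        for v in final_exit:
            node, seen = v, {v}
            while node != last:
                node = final_exit.get(node)
                if node is None or node in seen:
                    return False
                seen.add(node)
        return True

    # choose the designated final exit edge of every non-terminal vertex
    final_exit: dict[str, str] = {}
    while True:
        final_exit = {
            v: edges[rng.integers(len(edges))]
            for v, edges in out_edges.items()
            if v != last
        }
        if _reaches_last(final_exit):
            break

    shuffled: dict[str, list[str]] = {}
    for v, edges in out_edges.items():
        pool = list(edges)
        tail: list[str] = []
        if v != last:
            pool.remove(final_exit[v])
            tail = [final_exit[v]]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        shuffled[v] = pool + tail

    # replay the Euler walk
    result = [seq[0]]
    cursors = {v: 0 for v in shuffled}
    node = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[node][cursors[node]]
        cursors[node] += 1
        result.append(nxt)
        node = nxt
    return "".join(result)
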