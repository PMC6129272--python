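"""Importance-score backends.

A backend turns (model, sequence) into a 4 x L importance matrix C_X:
the contribution of each observed nucleotide to the model output Y.
Two backends are built in:

``grad_input``
    Saliency x input: the gradient dY/dX evaluated at X, multiplied
    elementwise by X.  For a one-hot sequence only observed bases can be
    non-zero.  This is the first-order Taylor decomposition of Y around X.

``ref_diff``
    Reference-based contributions via integrated gradients: the path
    integral of the gradient from a neutral reference sequence to X,
    multiplied by (X - reference), averaged over references.  References
    are dinucleotide-shuffled versions of the sequence, or a constant
    fixed-GC composition matrix.  External attribution implementations
    (e.g. DeepLIFT) can be registered as plug-in backends through the
    same signature.

Every backend counts its importance evaluations, which is how the
engine's O(F) complexity contract is asserted.
"""

from __future__ import annotations

import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .models import ModelContractError, SequenceModel
from .mutation import dinucleotide_shuffle
from .seqdata import BASES, FeatureLocus, OneHotSequence, SequenceError

__all__ = [
    "ImportanceMatrix",
    "ReferenceSpec",
    "AttributionBackend",
    "GradInputBackend",
    "RefDiffBackend",
    "grad_input_importance",
    "ref_diff_importance",
    "importance_of_locus",
    "get_backend",
    "register_backend",
]


@dataclass
class ImportanceMatrix:
    """Per-nucleotide contribution scores C_X for one sequence."""

    scores: np.ndarray  # (4, L)
    sequence_id: str
    backend: str
    reference_spec: "ReferenceSpec | None" = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ModelContractError(
                f"non-finite importance scores for sequence {self.sequence_id!r}"
            )


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference construction for reference-based backends.

    mode ``dinuc_shuffle`` draws ``n_references`` dinucleotide-preserving
    shuffles of the sequence (seeded; for a fractional input the shuffle
    operates on the argmax-decoded string).  Mode ``fixed_gc`` uses a
    single constant matrix with C/G rows f_gc/2 and A/T rows (1-f_gc)/2.
    ``m_steps`` is the number of path-integral interpolation points.
    """

    mode: str = "dinuc_shuffle"
    n_references: int = 10
    shuffle_seed: int = 0
    m_steps: int = 50
    f_gc: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dinuc_shuffle", "fixed_gc"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.n_references < 1:
            raise ValueError("n_references must be >= 1")
        if self.m_steps < 1:
            raise ValueError("m_steps must be >= 1")
        if self.mode == "fixed_gc" and (self.f_gc is None or not 0 < self.f_gc < 1):
            raise ValueError("fixed_gc mode requires f_gc in (0, 1)")


class AttributionBackend(ABC):
    """Stateful wrapper holding a name and an evaluation counter."""

    name: str = ""

    def __init__(self) -> None:
        self.n_evaluations = 0

    def reset_counter(self) -> None:
        self.n_evaluations = 0

    def importance(self, model: SequenceModel, x: OneHotSequence) -> ImportanceMatrix:
        self.n_evaluations += 1
        return self._compute(model, x)

    @abstractmethod
    def _compute(self, model: SequenceModel, x: OneHotSequence) -> ImportanceMatrix:
        ...


class GradInputBackend(AttributionBackend):
    name = "grad_input"

    def _compute(self, model, x):
        return grad_input_importance(model, x, _tag=self.name)


class RefDiffBackend(AttributionBackend):
    """Integrated-gradients backend; ``batch_size`` chunks the interpolation
    points fed to the model per call (results are bit-identical for any
    chunking, which is part of the contract)."""

    name = "ref_diff"

    def __init__(self, reference_spec: ReferenceSpec, batch_size: int | None = None):
        super().__init__()
        self.reference_spec = reference_spec
        self.batch_size = batch_size

    def _compute(self, model, x):
        return ref_diff_importance(
            model, x, self.reference_spec, batch_size=self.batch_size
        )


def grad_input_importance(
    model: SequenceModel, x: OneHotSequence, _tag: str = "grad_input"
) -> ImportanceMatrix:
    """Gradient-times-input importance: C_X = (dY/dX at X) * X."""
    grad = np.asarray(model.input_gradient(x.matrix), dtype=float)
    if not np.all(np.isfinite(grad)):
        raise ModelContractError(
            f"model returned non-finite gradient for sequence {x.id!r}"
        )
    return ImportanceMatrix(grad * x.matrix, x.id, _tag)


def _argmax_string(x: OneHotSequence) -> str:
    return "".join(BASES[i] for i in np.argmax(x.matrix, axis=0))


def _build_references(x: OneHotSequence, spec: ReferenceSpec) -> np.ndarray:
    """(R, 4, L) stack of reference matrices for ``x``."""
    L = x.length
    if spec.mode == "fixed_gc":
        ref = np.empty((4, L))
        ref[(1, 2), :] = spec.f_gc / 2.0
        ref[(0, 3), :] = (1.0 - spec.f_gc) / 2.0
        return ref[None, :, :]
    base_string = _argmax_string(x)
    # per-sequence deterministic stream: spec seed + content hash
    rng = np.random.default_rng(
        [spec.shuffle_seed, zlib.crc32(base_string.encode()) & 0x7FFFFFFF]
    )
    refs = np.empty((spec.n_references, 4, L))
    from .seqdata import one_hot_encode  # local import to avoid cycle at module load

    for r in range(spec.n_references):
        refs[r] = one_hot_encode(dinucleotide_shuffle(base_string, rng)).matrix
    return refs


def ref_diff_importance(
    model: SequenceModel,
    x: OneHotSequence,
    reference_spec: ReferenceSpec,
    batch_size: int | None = None,
) -> ImportanceMatrix:
    """Integrated-gradients contributions against neutral references.

    For each reference r the midpoint Riemann sum of the gradient along
    the straight path r -> x is multiplied elementwise by (x - r); the
    result is averaged over references.  For a linear model this reduces
    exactly to w * (x - mean reference) regardless of the step count.
    """
    refs = _build_references(x, reference_spec)
    if refs.shape[1:] != x.matrix.shape:
        raise SequenceError(
            f"reference shape {refs.shape[1:]} does not match sequence {x.matrix.shape}"
        )
    R, m = refs.shape[0], reference_spec.m_steps
    diffs = x.matrix[None, :, :] - refs                     # (R, 4, L)
    ts = (np.arange(m) + 0.5) / m
    points = refs[:, None, :, :] + ts[None, :, None, None] * diffs[:, None, :, :]
    points = points.reshape(R * m, *x.matrix.shape)
    if batch_size is None or batch_size >= R * m:
        grads = np.asarray(model.input_gradient(points), dtype=float)
    else:
        grads = np.concatenate(
            [
                np.asarray(model.input_gradient(points[i : i + batch_size]), dtype=float)
                for i in range(0, R * m, batch_size)
            ]
        )
    if not np.all(np.isfinite(grads)):
        raise ModelContractError(
            f"model returned non-finite gradient for sequence {x.id!r}"
        )
    avg_grad = grads.reshape(R, m, *x.matrix.shape).mean(axis=1)
    scores = (diffs * avg_grad).mean(axis=0)
    return ImportanceMatrix(scores, x.id, "ref_diff", reference_spec)


def importance_of_locus(C: ImportanceMatrix, locus: FeatureLocus) -> float:
    """Sum of importance scores over the locus' (base, position) pairs."""
    from .seqdata import BASE_INDEX

    L = C.scores.shape[1]
    if locus.start < 0 or locus.end > L:
        raise SequenceError(f"locus {locus.span} out of range for length {L}")
    return float(
        sum(C.scores[BASE_INDEX[b], p] for b, p in zip(locus.bases, locus.positions))
    )


_BACKEND_FACTORIES: dict[str, type] = {
    "grad_input": GradInputBackend,
    "ref_diff": RefDiffBackend,
}


def register_backend(name: str, factory) -> None:
    """Register a plug-in backend class under ``name``.

    The factory must produce objects satisfying the
    :class:`AttributionBackend` interface and the
    :class:`ImportanceMatrix` contract.
    """
    _BACKEND_FACTORIES[name] = factory


def get_backend(name: str, reference_spec: ReferenceSpec | None = None) -> AttributionBackend:
    factory = _BACKEND_FACTORIES.get(name)
    if factory is None:
        raise ValueError(
            f"unknown backend {name!r}; registered: {sorted(_BACKEND_FACTORIES)}"
        )
    if name == "ref_diff":
        if reference_spec is None:
            raise ValueError(f"backend {name!r} requires a reference_spec")
        return factory(reference_spec)
    return factory() if reference_spec is None else factory(reference_spec)
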