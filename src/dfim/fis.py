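"""Feature Interaction Scores and per-sequence interaction maps.

The interaction score FIS(target | source mutation) is the drop in the
target feature's importance when the source feature is perturbed and
everything else is held fixed:

    FIS((beta, t) | (alpha, gamma, s)) = C_X[beta, t] - C_X'[beta, t]

where C_X and C_X' are backend importance matrices for the original
sequence X and the mutated sequence X' (source base alpha at position s
switched to gamma), and beta is the base observed at target position t
(unchanged by the mutation).  Motif-resolution scores sum the target
importances over a span; a motif *source* is perturbed with a single
GC-background mutation rather than by enumerating point mutants.

Because one backend evaluation yields the importance of every position
at once, the FIS of one source against all targets costs two
evaluations, an all-pairs map costs 3L + 1, and F pre-specified source
features cost F + 1 — linear in F.  FIS is directional: FIS(t|s) and
FIS(s|t) are computed independently and never symmetrized.

The pairwise in-silico-mutagenesis (ISM) interaction — the joint
mutation effect minus the sum of single effects — is included as the
model-output-level comparison oracle; it is symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .attribution import AttributionBackend, ImportanceMatrix, importance_of_locus
from .models import SequenceModel
from .mutation import (
    MutationSpec,
    apply_background_mutation,
    apply_mutation,
    apply_point_mutation,
)
from .seqdata import BASE_INDEX, BASES, FeatureLocus, OneHotSequence, SequenceError

__all__ = [
    "FISRecord",
    "DFIMMap",
    "fis_nucleotide",
    "fis_profile",
    "max_fis",
    "dfim_map",
    "fis_motif_target",
    "fis_motif_motif",
    "interaction_profiles",
    "pairwise_ism_interaction",
    "records_to_dataframe",
    "records_to_tsv",
    "dfim_maps_to_hdf5",
]

MAX_FIS_POLICIES = ("signed", "abs")


@dataclass(frozen=True)
class FISRecord:
    """One signed interaction score with provenance."""

    sequence_id: str
    source: FeatureLocus
    mutation: str  # mutant base, or "background:<f_gc>"
    target: FeatureLocus
    score: float
    backend: str

    @property
    def abs_score(self) -> float:
        return abs(self.score)


@dataclass
class DFIMMap:
    """L x L matrix of policy-maximal FIS; entry (s, t) is the score of
    target position t under the best mutation of source position s.

    The diagonal is masked: after mutating s the observed target base at
    s changes, so the score is ill-posed there.
    """

    sequence_id: str
    scores: np.ndarray          # (L, L), NaN where masked
    mask: np.ndarray            # (L, L) bool, True = masked/invalid
    policy: str
    backend: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores[~self.mask])):
            raise ValueError("unmasked DFIM entries must be finite")


def _check_source(x: OneHotSequence, s: int, gamma: str) -> str:
    if not 0 <= s < x.length:
        raise SequenceError(f"source position {s} out of range [0, {x.length})")
    alpha = x.observed_base(s)
    if gamma not in BASE_INDEX:
        raise SequenceError(f"invalid mutant base {gamma!r}")
    if gamma == alpha:
        raise SequenceError(f"mutant base {gamma} equals observed base at {s}")
    return alpha


def fis_nucleotide(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    s: int,
    gamma: str,
    t: int,
    base_importance: ImportanceMatrix | None = None,
) -> float:
    """FIS of the observed target nucleotide at t under mutating s to gamma."""
    if t == s:
        raise SequenceError("self-interaction (t == s) is undefined")
    if not 0 <= t < x.length:
        raise SequenceError(f"target position {t} out of range [0, {x.length})")
    profile = fis_profile(model, backend, x, s, gamma, base_importance)
    beta = x.observed_base(t)
    return float(profile[BASE_INDEX[beta], t])


def fis_profile(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    s: int,
    gamma: str,
    base_importance: ImportanceMatrix | None = None,
) -> np.ndarray:
    """4 x L FIS of every target under one source mutation (s -> gamma).

    Column s is NaN (self-interaction undefined).  Costs two backend
    evaluations, or one when ``base_importance`` is passed in.
    """
    _check_source(x, s, gamma)
    if base_importance is None:
        base_importance = backend.importance(model, x)
    mutated = apply_point_mutation(x, s, gamma)
    mut_importance = backend.importance(model, mutated)
    profile = base_importance.scores - mut_importance.scores
    profile = profile.copy()
    profile[:, s] = np.nan
    return profile


def _policy_best(scores_per_gamma: list[tuple[str, float]], policy: str) -> tuple[float, str]:
    """Best (score, gamma) under a maxFIS policy; ties keep alphabetical gamma."""
    if policy not in MAX_FIS_POLICIES:
        raise ValueError(f"unknown maxFIS policy {policy!r}")
    best_gamma, best_score = None, None
    for gamma, score in scores_per_gamma:  # alphabetical iteration order
        key = score if policy == "signed" else abs(score)
        best_key = None if best_score is None else (
            best_score if policy == "signed" else abs(best_score)
        )
        if best_key is None or key > best_key:
            best_gamma, best_score = gamma, score
    return best_score, best_gamma


def max_fis(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    s: int,
    t: int,
    policy: str = "abs",
    base_importance: ImportanceMatrix | None = None,
) -> tuple[float, str]:
    """FIS marginalized over the three mutant bases at the source.

    ``signed`` returns the maximum signed score; ``abs`` the score of
    largest magnitude (sign retained).  Ties break alphabetically.
    """
    if t == s:
        raise SequenceError("self-interaction (t == s) is undefined")
    alpha = x.observed_base(s)
    if base_importance is None:
        base_importance = backend.importance(model, x)
    pairs = []
    for gamma in BASES:
        if gamma == alpha:
            continue
        pairs.append(
            (gamma, fis_nucleotide(model, backend, x, s, gamma, t, base_importance))
        )
    return _policy_best(pairs, policy)


def dfim_map(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    policy: str = "abs",
) -> DFIMMap:
    """All-pairs interaction map: row s holds the policy-maximal FIS of
    every target position under the best mutation of source position s.

    Costs exactly 3L + 1 backend evaluations (3 mutants per source plus
    one shared evaluation of the unperturbed sequence).
    """
    if policy not in MAX_FIS_POLICIES:
        raise ValueError(f"unknown maxFIS policy {policy!r}")
    L = x.length
    base = backend.importance(model, x)
    obs_rows = np.argmax(x.matrix, axis=0)
    cols = np.arange(L)
    scores = np.full((L, L), np.nan)
    for s in range(L):
        alpha = x.observed_base(s)
        best = None
        for gamma in BASES:
            if gamma == alpha:
                continue
            profile = fis_profile(model, backend, x, s, gamma, base)
            target_scores = profile[obs_rows, cols]
            if best is None:
                best = target_scores
            else:
                if policy == "signed":
                    take = target_scores > best
                else:
                    take = np.abs(target_scores) > np.abs(best)
                best = np.where(take, target_scores, best)
        scores[s] = best
    mask = np.eye(L, dtype=bool)
    scores[mask] = np.nan
    return DFIMMap(x.id, scores, mask, policy, backend.name)


def _require_disjoint(a: FeatureLocus, b: FeatureLocus) -> None:
    if a.overlaps(b):
        raise SequenceError(
            f"source {a.span} and target {b.span} overlap; the score is undefined"
        )


def fis_motif_target(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    s: int,
    gamma: str,
    target_motif: FeatureLocus,
    base_importance: ImportanceMatrix | None = None,
) -> float:
    """FIS of a target motif with a source nucleotide (e.g. a regulatory SNV).

    The difference of summed target importances between the original and
    point-mutated sequence; identical to summing the per-position FIS.
    """
    if target_motif.start <= s < target_motif.end:
        raise SequenceError(
            f"source position {s} lies inside the target span {target_motif.span}"
        )
    _check_source(x, s, gamma)
    target_motif.validate_against(x)
    if base_importance is None:
        base_importance = backend.importance(model, x)
    mutated = apply_point_mutation(x, s, gamma)
    mut_importance = backend.importance(model, mutated)
    return importance_of_locus(base_importance, target_motif) - importance_of_locus(
        mut_importance, target_motif
    )


def fis_motif_motif(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    source_motif: FeatureLocus,
    f_gc: float,
    target_motif: FeatureLocus,
    base_importance: ImportanceMatrix | None = None,
) -> float:
    """FIS of a target motif with a source motif.

    Enumerating point mutants of a long source is infeasible, so the
    whole source span is mutated once to the expected GC background
    (C/G rows f_gc/2, A/T rows (1-f_gc)/2): exactly two backend
    evaluations regardless of motif lengths.
    """
    _require_disjoint(source_motif, target_motif)
    source_motif.validate_against(x)
    target_motif.validate_against(x)
    if base_importance is None:
        base_importance = backend.importance(model, x)
    mutated = apply_background_mutation(x, source_motif, f_gc)
    mut_importance = backend.importance(model, mutated)
    return importance_of_locus(base_importance, target_motif) - importance_of_locus(
        mut_importance, target_motif
    )


def interaction_profiles(
    model: SequenceModel,
    backend: AttributionBackend,
    x: OneHotSequence,
    mutations: list[MutationSpec],
) -> list[np.ndarray]:
    """4 x L FIS profiles for F pre-specified source mutations.

    The unperturbed importance is evaluated once and shared, so the
    total cost is F + 1 backend evaluations — the O(F) path for
    pre-determined features (known motif instances, SNVs).  Source
    columns are NaN-masked in each profile.
    """
    base = backend.importance(model, x)
    profiles = []
    for spec in mutations:
        mutated = apply_mutation(x, spec)
        mut_importance = backend.importance(model, mutated)
        profile = base.scores - mut_importance.scores
        profile[:, list(spec.source.positions)] = np.nan
        profiles.append(profile)
    return profiles


def pairwise_ism_interaction(
    model: SequenceModel,
    x: OneHotSequence,
    source_spec: MutationSpec,
    target_spec: MutationSpec,
) -> float:
    """ISM-based interaction: joint-mutation effect minus the sum of the
    single-mutation effects, all measured on the model output Y.

    ISM(f) = Y(X) - Y(mutate(X, f)).  Symmetric in its two arguments;
    needs three extra forward passes per pair, hence O(F^2) for all
    pairs — the brute-force comparison for the backpropagation-based
    scores.
    """
    _require_disjoint(source_spec.source, target_spec.source)
    y0 = float(model.predict(x.matrix))
    ism_source = y0 - float(model.predict(apply_mutation(x, source_spec).matrix))
    ism_target = y0 - float(model.predict(apply_mutation(x, target_spec).matrix))
    joint = apply_mutation(apply_mutation(x, source_spec), target_spec)
    ism_joint = y0 - float(model.predict(joint.matrix))
    return ism_joint - (ism_source + ism_target)


# ---------------------------------------------------------------------------
# Serialization

RECORD_COLUMNS = [
    "sequence_id",
    "source_start",
    "source_end",
    "source_bases",
    "mutant",
    "target_start",
    "target_end",
    "target_bases",
    "score",
    "abs_score",
    "backend",
]


def records_to_dataframe(records: list[FISRecord]) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "source_start": r.source.start,
            "source_end": r.source.end,
            "source_bases": r.source.bases,
            "mutant": r.mutation,
            "target_start": r.target.start,
            "target_end": r.target.end,
            "target_bases": r.target.bases,
            "score": r.score,
            "abs_score": r.abs_score,
            "backend": r.backend,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def records_to_tsv(records: list[FISRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def dfim_maps_to_hdf5(maps: list[DFIMMap], path: str | Path) -> None:
    """One HDF5 group per sequence: scores, mask, policy/backend attrs."""
    with h5py.File(path, "w") as fh:
        for m in maps:
            grp = fh.create_group(m.sequence_id)
            grp.create_dataset("scores", data=m.scores)
            grp.create_dataset("mask", data=m.mask)
            grp.attrs["policy"] = m.policy
            grp.attrs["backend"] = m.backend
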