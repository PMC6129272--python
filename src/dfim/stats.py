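"""Cross-sequence aggregation of interaction scores and the
empirical-null significance procedure.

Significance of an interaction score is judged against an empirical
null built from dinucleotide-shuffled versions of the input sequences:
shuffling preserves composition (all 16 dinucleotide counts) while
destroying the planted arrangement, so interaction scores computed on
shuffles estimate what the backend produces by chance.  A Gaussian is
fitted to the pooled null scores; records get two-sided p-values and
Benjamini-Hochberg q-values, and a record is called significant when
q <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .attribution import AttributionBackend
from .fis import FISRecord, fis_profile, records_to_dataframe
from .models import SequenceModel
from .mutation import dinucleotide_shuffle
from .seqdata import BASES, OneHotSequence, decode, one_hot_encode

__all__ = [
    "AggregateMap",
    "MarginalizedMap",
    "NullModel",
    "NullScope",
    "DegenerateNullError",
    "aggregate_fis",
    "marginalized_aggregate_map",
    "build_null",
    "gaussian_pvalues",
    "significance_table",
    "significance",
]


class DegenerateNullError(RuntimeError):
    """The null scores have zero spread; more shuffles (or a richer
    scope) are needed before a Gaussian can be fitted."""


@dataclass
class NullModel:
    """Gaussian (mu, sigma) fitted to null interaction scores."""

    mu: float
    sigma: float
    n_null: int

    MIN_NULL = 1000

    @classmethod
    def fit(cls, scores: np.ndarray, min_n: int | None = None) -> "NullModel":
        scores = np.asarray(scores, dtype=float)
        scores = scores[np.isfinite(scores)]
        min_n = cls.MIN_NULL if min_n is None else min_n
        if scores.size < min_n:
            raise ValueError(
                f"only {scores.size} null scores; need at least {min_n} "
                "(lower min_n explicitly for toy problems)"
            )
        mu = float(np.mean(scores))
        sigma = float(np.std(scores))  # MLE (ddof=0)
        if sigma == 0.0:
            raise DegenerateNullError(
                "null scores have zero variance; increase n_shuffles or widen the scope"
            )
        return cls(mu, sigma, scores.size)


@dataclass(frozen=True)
class NullScope:
    """Which pairs are scored on each shuffled sequence.

    ``all_pairs`` runs every source position; ``subsample`` draws
    ``n_source_positions`` random sources per shuffled sequence (all
    targets are always scored, since they come for free from the same
    profiles).  Subsampling is the tractable default: the full O(L^2)
    scope costs 3L+1 backend evaluations per shuffle.
    """

    kind: str = "subsample"
    n_source_positions: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("all_pairs", "subsample"):
            raise ValueError(f"unknown null scope {self.kind!r}")


def build_null(
    model: SequenceModel,
    backend: AttributionBackend,
    sequences: list[OneHotSequence],
    n_shuffles: int = 10,
    seed: int = 0,
    scope: NullScope = NullScope(),
    policy: str = "abs",
    min_n: int | None = None,
) -> NullModel:
    """Fit the Gaussian null from nucleotide-pair FIS on shuffled inputs.

    Each input sequence is dinucleotide-shuffled ``n_shuffles`` times;
    for every scoped source position the policy-maximal FIS against all
    targets is collected, and the pooled scores across all sequences and
    shuffles are fitted by maximum likelihood.
    """
    rng = np.random.default_rng(seed)
    null_scores: list[np.ndarray] = []
    for x in sequences:
        base_string = decode(x)
        for _ in range(n_shuffles):
            shuffled = one_hot_encode(dinucleotide_shuffle(base_string, rng), id=x.id)
            L = shuffled.length
            if scope.kind == "all_pairs":
                sources = np.arange(L)
            else:
                k = min(scope.n_source_positions, L)
                sources = rng.choice(L, size=k, replace=False)
            base = backend.importance(model, shuffled)
            obs_rows = np.argmax(shuffled.matrix, axis=0)
            cols = np.arange(L)
            for s in sources:
                alpha = shuffled.observed_base(int(s))
                best = None
                for gamma in BASES:
                    if gamma == alpha:
                        continue
                    prof = fis_profile(model, backend, shuffled, int(s), gamma, base)
                    target_scores = prof[obs_rows, cols]
                    if best is None:
                        best = target_scores
                    elif policy == "signed":
                        best = np.where(target_scores > best, target_scores, best)
                    else:
                        best = np.where(
                            np.abs(target_scores) > np.abs(best), target_scores, best
                        )
                null_scores.append(best[np.isfinite(best)])
    pooled = np.concatenate(null_scores) if null_scores else np.empty(0)
    return NullModel.fit(pooled, min_n=min_n)


def gaussian_pvalues(scores: np.ndarray, null: NullModel) -> np.ndarray:
    """Two-sided p-values under the fitted Gaussian null."""
    z = np.abs(np.asarray(scores, dtype=float) - null.mu) / null.sigma
    return 2.0 * sps.norm.sf(z)


def significance_table(
    scores: np.ndarray, null: NullModel, alpha: float = 0.05
) -> pd.DataFrame:
    """p, BH q and a significance call for a family of scores.

    The family is exactly the scores passed in one call; callers control
    the correction family by batching.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty record set: nothing to test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = gaussian_pvalues(scores, null)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"score": scores, "p": p, "q": q, "significant": q <= alpha})


def significance(
    records: list[FISRecord], null: NullModel, alpha: float = 0.05
) -> pd.DataFrame:
    """Annotate FIS records with p, q and a significance call."""
    df = records_to_dataframe(records)
    if df.empty:
        raise ValueError("empty record set: nothing to test")
    table = significance_table(df["score"].to_numpy(), null, alpha)
    df[["p", "q", "significant"]] = table[["p", "q", "significant"]].to_numpy()
    return df


# ---------------------------------------------------------------------------
# Aggregation

DEFAULT_CONTEXT = (
    "source_bases",
    "source_start",
    "mutant",
    "target_bases",
    "target_start",
)


@dataclass
class AggregateMap:
    """Mean FIS / mean |FIS| per sequence-context cell.

    A cell's context is the combination of grouping columns (by default
    source base+position, mutant base and target base+position); its n
    is the number of records whose sequences match that context.
    """

    table: pd.DataFrame
    context: tuple[str, ...]

    def cell(self, **context_values) -> tuple[float, float, int]:
        """(mean FIS, mean |FIS|, n) for one context; (nan, nan, 0) when no
        sequence matches the context."""
        mask = np.ones(len(self.table), dtype=bool)
        for key, value in context_values.items():
            mask &= (self.table[key] == value).to_numpy()
        sub = self.table[mask]
        if sub.empty:
            return float("nan"), float("nan"), 0
        if len(sub) > 1:
            raise KeyError(f"context {context_values} does not identify a single cell")
        row = sub.iloc[0]
        return float(row["mean_fis"]), float(row["mean_abs_fis"]), int(row["n"])

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for col in self.table.columns:
                data = self.table[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                fh.create_dataset(col, data=data)
            fh.attrs["context"] = ",".join(self.context)


def aggregate_fis(
    records: list[FISRecord] | pd.DataFrame,
    context: tuple[str, ...] = DEFAULT_CONTEXT,
) -> AggregateMap:
    """Mean and mean-absolute FIS over sequences sharing a context.

    Sequences enter a cell when they carry identical source bases at the
    source position and identical target bases at the target position
    (plus any further context columns requested).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    if df["backend"].nunique() > 1:
        raise ValueError(
            f"records mix backends {sorted(df['backend'].unique())}; aggregate per backend"
        )
    grouped = (
        df.groupby(list(context), sort=True)["score"]
        .agg(mean_fis="mean", mean_abs_fis=lambda s: s.abs().mean(), n="size")
        .reset_index()
    )
    return AggregateMap(grouped, tuple(context))


@dataclass
class MarginalizedMap:
    """(4P x 4P) aggregate map marginalized over the mutant base.

    Rows are (source base, source position), columns (target base,
    target position); a cell holds the max over the 3 mutant bases of
    the per-mutant mean |FIS|, with the supporting sequence count.
    """

    matrix: np.ndarray
    counts: np.ndarray
    labels: list[str]

    def top_cell(self, off_diagonal: bool = True) -> tuple[str, str, float]:
        """(source label, target label, value) of the largest cell."""
        m = self.matrix.copy()
        if off_diagonal:
            P = len(self.labels) // 4
            pos = np.array([int(l[1:]) for l in self.labels])
            same_pos = pos[:, None] == pos[None, :]
            m[same_pos] = -np.inf
        m[~np.isfinite(m)] = -np.inf
        i, j = np.unravel_index(int(np.argmax(m)), m.shape)
        return self.labels[i], self.labels[j], float(self.matrix[i, j])


def marginalized_aggregate_map(
    records: list[FISRecord] | pd.DataFrame, n_positions: int
) -> MarginalizedMap:
    """Marginalized aggregate map over a fixed-length sequence collection.

    For each (source base, source position, target base, target
    position) the mean |FIS| is computed per mutant base over the
    matching sequences, then the max over the 3 mutant bases is taken.
    With 4 bases and P positions the result is a 4P x 4P matrix.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    widths = (df["source_end"] - df["source_start"]).unique()
    if not np.array_equal(widths, [1]) or not np.array_equal(
        (df["target_end"] - df["target_start"]).unique(), [1]
    ):
        raise ValueError("marginalized maps require nucleotide-resolution records")
    if (df["source_start"] >= n_positions).any() or (df["target_start"] >= n_positions).any():
        raise ValueError("record positions exceed the stated sequence length")
    per_mutant = (
        df.assign(abs_score=df["score"].abs())
        .groupby(
            ["source_bases", "source_start", "target_bases", "target_start", "mutant"],
            sort=True,
        )["abs_score"]
        .agg(["mean", "size"])
        .reset_index()
    )
    labels = [f"{b}{p}" for b in BASES for p in range(n_positions)]
    index = {lab: i for i, lab in enumerate(labels)}
    size = 4 * n_positions
    matrix = np.full((size, size), np.nan)
    counts = np.zeros((size, size), dtype=int)
    marg = (
        per_mutant.groupby(
            ["source_bases", "source_start", "target_bases", "target_start"], sort=True
        )
        .agg(value=("mean", "max"), n=("size", "max"))
        .reset_index()
    )
    for row in marg.itertuples(index=False):
        i = index[f"{row.source_bases}{row.source_start}"]
        j = index[f"{row.target_bases}{row.target_start}"]
        matrix[i, j] = row.value
        counts[i, j] = row.n
    return MarginalizedMap(matrix, counts, labels)


def render_heatmap(matrix: np.ndarray, labels: list[str], path, title: str = "") -> None:
    """Save a basic heatmap image of an aggregate map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix, cmap="RdBu_r", interpolation="nearest")
    step = max(1, len(labels) // 40)
    ticks = np.arange(0, len(labels), step)
    ax.set_xticks(ticks, [labels[i] for i in ticks], rotation=90, fontsize=5)
    ax.set_yticks(ticks, [labels[i] for i in ticks], fontsize=5)
    ax.set_xlabel("target (base, position)")
    ax.set_ylabel("source (base, position)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
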