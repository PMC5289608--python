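"""Per-sample regulator activity scoring (iRAS).

The score follows the BASE (Binding Association with Sorted Expression)
scheme.  For one sample, genes are sorted by descending relative
expression and two non-decreasing cumulative curves are built over that
ordering: a *foreground* curve F accumulating the expression magnitude of
the regulator's listed targets and a *background* curve B doing the same
for all other genes.  The preliminary score is the signed maximum
deviation between the two curves — the Kolmogorov-Smirnov D-statistic of
targets against background, weighted by expression magnitude.  A positive
score means the targets concentrate among the most highly (relatively)
expressed genes of that sample; a negative score means they concentrate
among the most repressed.

The preliminary score is then normalized into the individual Regulatory
Activity Score (iRAS) by dividing by the mean absolute preliminary score
of randomly permuted target lists of the same size, so that |iRAS| ~ 1
corresponds to no enrichment beyond chance for a set of that size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import (
    ActivityMatrix,
    ChannelMode,
    ExpressionMatrix,
    GeneSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "CurvePair",
    "ActivityProfile",
    "normalize_expression",
    "make_weight_vector",
    "sample_curves",
    "preliminary_score",
    "compute_iras",
    "score_collection",
]

Weighting = Literal["abs", "uniform"]


@dataclass(frozen=True)
class WeightVector:
    """0/1 target-membership vector aligned to an expression matrix's genes."""

    values: np.ndarray  # int8, 1 = target, 0 = non-target
    n_targets_effective: int
    dropped: tuple[str, ...] = ()  # listed symbols absent from the matrix

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("weights must be 0 or 1")
        n_on = int(values.sum())
        if n_on != self.n_targets_effective:
            raise ValueError("n_targets_effective inconsistent with weights")
        if n_on < 1:
            raise ValueError("at least one effective target is required")
        if n_on >= values.size:
            raise ValueError("background is empty: every gene is a target")


@dataclass(frozen=True)
class CurvePair:
    """Foreground/background cumulative curves for one sample.

    ``order`` is the permutation of gene indices that sorts the sample's
    expression in descending order (ties broken by ascending gene index);
    ``foreground[k]`` and ``background[k]`` are the curve values after the
    first k+1 genes of that ordering.  Both curves end at 1.
    """

    foreground: np.ndarray
    background: np.ndarray
    order: np.ndarray


@dataclass(frozen=True)
class ActivityProfile:
    """Per-sample scores of one regulator: iRAS = preliminary / null_mean_abs."""

    regulator: str
    scores: np.ndarray
    preliminary: np.ndarray
    null_mean_abs: np.ndarray
    n_permutations: int
    seed: int


def normalize_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a raw matrix to relative (within-gene) expression.

    One-channel intensities have each gene's across-sample median
    subtracted; two-channel log-ratios are already relative to their
    internal reference and pass through unchanged, as do pre-normalized
    matrices.  The result is always marked ``pre_normalized``.
    """
    if matrix.channel_mode is ChannelMode.one_channel:
        values = matrix.values - np.median(matrix.values, axis=1, keepdims=True)
    else:
        values = matrix.values
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        values=values,
        channel_mode=ChannelMode.pre_normalized,
    )


def make_weight_vector(gene_set: GeneSet, matrix: ExpressionMatrix) -> WeightVector:
    """Encode a target list as a 0/1 vector over the matrix's gene universe.

    Listed symbols absent from the matrix are dropped with a warning.
    Raises if no listed gene is present, or if every matrix gene is a
    target (the background would be empty).
    """
    index = matrix.gene_index()
    values = np.zeros(matrix.n_genes, dtype=np.int8)
    dropped: list[str] = []
    for symbol in gene_set.members:
        j = index.get(symbol)
        if j is None:
            dropped.append(symbol)
        else:
            values[j] = 1
    if dropped:
        logger.warning(
            "set %r: %d listed gene(s) absent from the matrix: %s",
            gene_set.name, len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    n_on = int(values.sum())
    if n_on == 0:
        raise ValueError(f"set {gene_set.name!r}: no listed gene is in the matrix")
    if n_on == matrix.n_genes:
        raise ValueError(f"set {gene_set.name!r}: all matrix genes are targets")
    return WeightVector(values=values, n_targets_effective=n_on, dropped=tuple(dropped))


def _descending_order(column: np.ndarray) -> np.ndarray:
    # stable argsort of -e: ties resolved by ascending gene index
    return np.argsort(-column, kind="stable")


def sample_curves(
    weights: WeightVector, expression_column: np.ndarray, weighting: Weighting = "abs"
) -> CurvePair:
    """Build the foreground/background curves for one sample.

    Increments are proportional to |e| of each gene (``weighting="abs"``,
    the default) so the curves encapsulate expression activity, or uniform
    steps (``weighting="uniform"``) for sensitivity checks.  If all |e| of
    a class are zero the class falls back to equal increments.
    """
    e = np.asarray(expression_column, dtype=float)
    if e.shape != (weights.values.size,):
        raise ValueError("expression column not aligned to weight vector")
    order = _descending_order(e)
    w = weights.values[order].astype(float)
    if weighting == "abs":
        a = np.abs(e)[order]
    elif weighting == "uniform":
        a = np.ones_like(e)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def cumulative(mask: np.ndarray) -> np.ndarray:
        inc = a * mask
        total = inc.sum()
        if total == 0.0:
            inc = mask
            total = mask.sum()
        return np.cumsum(inc) / total

    return CurvePair(
        foreground=cumulative(w), background=cumulative(1.0 - w), order=order
    )


def preliminary_score(curves: CurvePair) -> float:
    """Signed maximum-magnitude deviation between the two curves.

    Returns D(k*) for D = F - B and k* = argmax |D| (ties -> smallest k);
    positive iff targets concentrate among the highest relative expression.
    """
    d = curves.foreground - curves.background
    k = int(np.argmax(np.abs(d)))
    return float(d[k])


def _candidate_scores(
    a_sorted: np.ndarray, ca: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Preliminary scores for a batch of target-position sets, all samples.

    The deviation D(k) = F(k) - B(k) can only increase at a target
    position and decreases (weakly) everywhere else, so its extrema lie
    at target positions (local maxima) and just before them (local
    minima); evaluating D at those 2m candidates per set is equivalent to
    scanning all n prefixes but costs O(m) instead of O(n).

    a_sorted: (S, n) per-sample expression magnitudes in descending
    order; ca: its cumulative sum; pos: (P, S, m) ascending rank
    positions of each set's targets.  Returns (P, S) signed scores.
    Degenerate classes (zero total magnitude) fall back to uniform
    increments, matching sample_curves.
    """
    P, S, m = pos.shape
    n = a_sorted.shape[1]
    srange = np.arange(S)[None, :, None]
    av = a_sorted[srange, pos]  # (P, S, m) target magnitudes, rank order
    cav = np.cumsum(av, axis=2)  # foreground mass through target i
    tf = cav[:, :, -1]
    ta = ca[:, -1]
    tb = ta[None, :] - tf
    # background mass up to each target position (unchanged at the target
    # index itself, so it serves both the at- and before-target candidates)
    cb = ca[srange, pos] - cav

    degen_f = tf == 0.0
    if degen_f.any():
        unit = np.broadcast_to(np.arange(1.0, m + 1.0), cav.shape)
        cav = np.where(degen_f[:, :, None], unit, cav)
        av = np.where(degen_f[:, :, None], 1.0, av)
        tf = np.where(degen_f, float(m), tf)
    degen_b = tb == 0.0
    if degen_b.any():
        counts = (pos - np.arange(m)).astype(float)
        cb = np.where(degen_b[:, :, None], counts, cb)
        tb = np.where(degen_b, float(n - m), tb)

    b = cb / tb[:, :, None]
    f_at = cav / tf[:, :, None]
    f_before = (cav - av) / tf[:, :, None]
    # interleave so candidate order is ascending in k (ties -> smallest k)
    d = np.empty((P, S, 2 * m))
    d[:, :, 0::2] = f_before - b
    d[:, :, 1::2] = f_at - b
    k = np.argmax(np.abs(d), axis=2)
    return np.take_along_axis(d, k[:, :, None], axis=2)[:, :, 0]


def _permutation_indices(
    rng: np.random.Generator, n_permutations: int, n_genes: int, n_targets: int
) -> np.ndarray:
    """(P, m) gene indices; each row a uniform draw of n_targets genes
    without replacement."""
    idx = np.empty((n_permutations, n_targets), dtype=np.intp)
    for p in range(n_permutations):
        idx[p] = rng.choice(n_genes, size=n_targets, replace=False)
    return idx


def compute_iras(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    weighting: Weighting = "abs",
) -> ActivityProfile:
    """Permutation-normalized per-sample activity of one regulator.

    For each sample the observed preliminary score is divided by the mean
    absolute preliminary score of ``n_permutations`` random target lists
    of the same effective size, drawn uniformly without replacement over
    the matrix's genes.  One shared collection of permuted lists is reused
    across all samples so that scores stay comparable between samples.

    The matrix must already be relative expression (``pre_normalized``);
    apply :func:`normalize_expression` first.
    """
    if matrix.channel_mode is not ChannelMode.pre_normalized:
        raise ValueError(
            "matrix must be normalized before scoring; call normalize_expression"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    weights = make_weight_vector(gene_set, matrix)
    n, s = matrix.n_genes, matrix.n_samples

    cols = matrix.values.T  # (S, n)
    orders = np.argsort(-cols, axis=1, kind="stable")
    if weighting == "abs":
        a_sorted = np.take_along_axis(np.abs(cols), orders, axis=1)
    elif weighting == "uniform":
        a_sorted = np.ones_like(cols)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    ca = np.cumsum(a_sorted, axis=1)
    rank = np.argsort(orders, axis=1)  # gene index -> rank position, per sample

    obs_idx = np.flatnonzero(weights.values)
    pos_obs = np.sort(rank[:, obs_idx], axis=1)[None, :, :]  # (1, S, m)
    preliminary = _candidate_scores(a_sorted, ca, pos_obs)[0]

    rng = np.random.default_rng(seed)
    m = weights.n_targets_effective
    perm_idx = _permutation_indices(rng, n_permutations, n, m)

    # chunk permutations to bound the (P, S, m) workspace
    chunk = max(1, int(2.5e7 // max(1, m * s)))
    abs_sum = np.zeros(s)
    for start in range(0, n_permutations, chunk):
        block = perm_idx[start : start + chunk]
        pos = np.sort(rank[:, block].transpose(1, 0, 2), axis=2)
        abs_sum += np.abs(_candidate_scores(a_sorted, ca, pos)).sum(axis=0)
    null_mean_abs = abs_sum / n_permutations

    if (null_mean_abs == 0.0).any():
        bad = matrix.sample_ids[int(np.argmax(null_mean_abs == 0.0))]
        raise ValueError(f"degenerate permutation null (0) for sample {bad!r}")

    return ActivityProfile(
        regulator=gene_set.name,
        scores=preliminary / null_mean_abs,
        preliminary=preliminary,
        null_mean_abs=null_mean_abs,
        n_permutations=n_permutations,
        seed=seed,
    )


def score_collection(
    sets: Sequence[GeneSet],
    matrix: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    weighting: Weighting = "abs",
) -> ActivityMatrix:
    """iRAS for every gene set in a collection, one row per regulator.

    Each set is scored with a sub-seed derived deterministically from
    ``seed`` and the set name, so a set's scores do not depend on which
    other sets are in the batch.
    """
    from .refine import _subseed  # shared seed-derivation convention

    rows = []
    for gs in sets:
        profile = compute_iras(
            gs, matrix, n_permutations=n_permutations,
            seed=_subseed(seed, gs.name), weighting=weighting,
        )
        rows.append(profile.scores)
    return ActivityMatrix(
        regulator_names=tuple(gs.name for gs in sets),
        sample_ids=matrix.sample_ids,
        scores=np.vstack(rows) if rows else np.empty((0, matrix.n_samples)),
        n_permutations=n_permutations,
        seed=seed,
    )
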