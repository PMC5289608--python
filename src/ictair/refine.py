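"""Iterative contextual refinement of regulator target gene lists.

One refinement cycle scores the regulator's per-sample activity (iRAS)
from its current target list, computes the Spearman rank correlation
between each listed target's expression and that activity vector across
samples, and drops every target whose correlation falls strictly below
the minimum-correlation threshold.  Cycles repeat until (i) the list
would shrink below the minimum allowable length, (ii) membership
stabilizes, or (iii) the maximum number of iterations is reached.

Defaults mirror the published operating point: minimum Spearman
correlation 0.1, minimum list length 20, at most 10 iterations, 1000
permutations per activity calculation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .activity import ActivityProfile, Weighting, compute_iras
from .io_formats import ChannelMode, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "RefineParams",
    "IterationRecord",
    "RefinementResult",
    "RefinementFailure",
    "spearman_rho",
    "refine_once",
    "ictair",
    "refine_collection",
]


@dataclass(frozen=True)
class RefineParams:
    """Tuning knobs of the refinement loop.

    min_rho: targets with Spearman correlation strictly below this are
    dropped (kept at equality).  min_size: refinement never returns a
    list shorter than this.  max_iterations: hard cap on refine cycles.
    """

    min_rho: float = 0.1
    min_size: int = 20
    max_iterations: int = 10
    n_permutations: int = 1000
    seed: int = 0
    weighting: Weighting = "abs"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_rho <= 1.0:
            raise ValueError("min_rho must be in [0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class IterationRecord:
    """Trace entry for one refine cycle."""

    iteration: int
    size_before: int
    size_after: int
    dropped: tuple[str, ...]
    correlations: dict[str, float]  # per-target rho before pruning (NaN = undefined)
    iras_mean: float
    iras_sd: float


@dataclass(frozen=True)
class RefinementResult:
    regulator: str
    final_set: GeneSet
    iterations_run: int
    trace: tuple[IterationRecord, ...]
    termination: str  # "stable" | "floor" | "max_iterations"


@dataclass(frozen=True)
class RefinementFailure:
    """Recorded per-set error from a batch refinement."""

    regulator: str
    error: str


def _subseed(seed: int, *keys: int | str) -> int:
    """Deterministic 31-bit sub-seed from a master seed and context keys."""
    ints = tuple(
        k if isinstance(k, int) else zlib.crc32(k.encode("utf-8")) for k in keys
    )
    ss = np.random.SeedSequence(entropy=seed, spawn_key=ints)
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Without ties this equals the classical 1 - 6*sum(d_i^2) / (s(s^2-1))
    over the s paired observations; with ties it is the product-moment
    correlation of the average-rank vectors.  Returns NaN (an "undefined"
    marker) when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _spearman_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of each matrix row against y (vectorized).

    Constant rows (or constant y) yield NaN, matching spearman_rho.
    """
    ry = stats.rankdata(y)
    rr = stats.rankdata(rows, axis=1)
    ry_c = ry - ry.mean()
    rr_c = rr - rr.mean(axis=1, keepdims=True)
    denom = np.sqrt((rr_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rr_c @ ry_c) / denom
    rho[denom == 0.0] = np.nan
    return rho


def _effective_members(gene_set: GeneSet, matrix: ExpressionMatrix) -> list[str]:
    index = matrix.gene_index()
    return [g for g in gene_set.members if g in index]


def refine_once(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    params: RefineParams,
    seed: int | None = None,
) -> tuple[GeneSet, dict[str, float], ActivityProfile]:
    """One refine cycle: score, correlate, prune.

    Returns the pruned set, the per-target correlations that informed the
    pruning (NaN for targets whose correlation is undefined — those are
    dropped: a constant expression row cannot evidence co-activity), and
    the activity profile.  Raises if pruning would leave the set empty.
    """
    kept, rho_map, profile = _prune(gene_set, matrix, params, seed)
    if not kept:
        raise ValueError(
            f"set {gene_set.name!r}: no target meets the correlation threshold"
        )
    return (
        GeneSet(gene_set.name, gene_set.description, tuple(kept)),
        rho_map,
        profile,
    )


def _prune(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    params: RefineParams,
    seed: int | None,
) -> tuple[list[str], dict[str, float], ActivityProfile]:
    if matrix.channel_mode is not ChannelMode.pre_normalized:
        raise ValueError("matrix must be normalized before refinement")
    effective = _effective_members(gene_set, matrix)
    if len(effective) < 2:
        raise ValueError(f"set {gene_set.name!r}: fewer than 2 effective targets")
    profile = compute_iras(
        gene_set,
        matrix,
        n_permutations=params.n_permutations,
        seed=params.seed if seed is None else seed,
        weighting=params.weighting,
    )
    index = matrix.gene_index()
    rows = matrix.values[[index[g] for g in effective]]
    rho = _spearman_rows(rows, profile.scores)
    rho_map = dict(zip(effective, (float(r) for r in rho)))
    undefined = [g for g, r in rho_map.items() if np.isnan(r)]
    if undefined:
        logger.warning(
            "set %r: undefined correlation for %d constant gene(s), dropped: %s",
            gene_set.name, len(undefined), ", ".join(undefined[:10]),
        )
    # strict drop below threshold; NaN compares False and is dropped too
    kept = [g for g, r in rho_map.items() if r >= params.min_rho]
    return kept, rho_map, profile


def ictair(
    gene_set: GeneSet, matrix: ExpressionMatrix, params: RefineParams
) -> RefinementResult:
    """Run refine cycles until a termination condition fires.

    Termination is ``stable`` when a cycle leaves membership unchanged,
    ``floor`` when the pruned list would fall below ``params.min_size``
    (the previous, compliant list is returned), and ``max_iterations``
    after ``params.max_iterations`` cycles.  Iteration k draws its
    permutation null from a deterministic sub-seed of ``params.seed``, so
    runs are exactly reproducible.
    """
    effective = _effective_members(gene_set, matrix)
    if len(effective) < params.min_size:
        raise ValueError(
            f"set {gene_set.name!r}: only {len(effective)} effective targets, "
            f"below min_size={params.min_size}"
        )
    current = GeneSet(gene_set.name, gene_set.description, tuple(effective))
    trace: list[IterationRecord] = []
    termination = "max_iterations"
    iterations_run = 0

    for k in range(1, params.max_iterations + 1):
        kept, rho_map, profile = _prune(
            current, matrix, params, seed=_subseed(params.seed, k)
        )
        dropped = tuple(g for g in current.members if g not in set(kept))
        record = IterationRecord(
            iteration=k,
            size_before=len(current),
            size_after=len(kept),
            dropped=dropped,
            correlations=rho_map,
            iras_mean=float(np.mean(profile.scores)),
            iras_sd=float(np.std(profile.scores)),
        )
        trace.append(record)
        iterations_run = k
        if len(kept) < params.min_size:
            termination = "floor"
            logger.info(
                "set %r: iteration %d would shrink list to %d (< %d); "
                "keeping previous list of %d",
                gene_set.name, k, len(kept), params.min_size, len(current),
            )
            break
        candidate = GeneSet(current.name, current.description, tuple(kept))
        if candidate.member_set == current.member_set:
            current = candidate
            termination = "stable"
            break
        current = candidate

    logger.info(
        "set %r: %d iteration(s), termination=%s, final size %d",
        gene_set.name, iterations_run, termination, len(current),
    )
    return RefinementResult(
        regulator=gene_set.name,
        final_set=current,
        iterations_run=iterations_run,
        trace=tuple(trace),
        termination=termination,
    )


def refine_collection(
    sets: Sequence[GeneSet], matrix: ExpressionMatrix, params: RefineParams
) -> list[RefinementResult | RefinementFailure]:
    """Refine each set independently, in input order.

    Each set runs under a sub-seed derived from ``params.seed`` and the
    set name, so results match refining that set alone with the same
    sub-seed and are invariant to batch composition.  Per-set errors are
    recorded as :class:`RefinementFailure` entries, not raised.
    """
    results: list[RefinementResult | RefinementFailure] = []
    for gs in sets:
        sub = RefineParams(
            min_rho=params.min_rho,
            min_size=params.min_size,
            max_iterations=params.max_iterations,
            n_permutations=params.n_permutations,
            seed=_subseed(params.seed, gs.name),
            weighting=params.weighting,
        )
        try:
            results.append(ictair(gs, matrix, sub))
        except ValueError as exc:
            logger.error("set %r failed: %s", gs.name, exc)
            results.append(RefinementFailure(regulator=gs.name, error=str(exc)))
    return results
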