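"""Readers and writers for the plain-text formats the tool touches.

Gene sets travel as GMT (the Broad/MSigDB dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``), expression and activity
matrices as TSV with a sample-ID header row and gene/regulator symbols in
the first column, and network edge lists as three-column TSV.

Gene identifiers are opaque, case-sensitive strings; no symbol aliasing is
performed.  Missing expression values are rejected rather than imputed,
because imputation would silently change the expression ranks every
downstream score depends on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelMode",
    "FormatError",
    "GeneSet",
    "ExpressionMatrix",
    "ActivityMatrix",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_activity",
    "write_activity",
    "write_edges",
    "read_edges",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ChannelMode(str, Enum):
    """Normalization convention of an expression matrix.

    ``one_channel``: absolute intensities; each gene is median-centered
    across samples before scoring.  ``two_channel``: log-ratios to an
    internal reference; already relative, used as-is.  ``pre_normalized``:
    values are already relative expression.
    """

    one_channel = "one_channel"
    two_channel = "two_channel"
    pre_normalized = "pre_normalized"


@dataclass(frozen=True)
class GeneSet:
    """A named regulator target gene list (one GMT line).

    ``members`` is an ordered, duplicate-free tuple of gene symbols; the
    description field is carried verbatim but never interpreted.
    """

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.member_set


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values ``e[j, i]``."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    channel_mode: ChannelMode

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "channel_mode", ChannelMode(self.channel_mode))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers must be unique")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index()[gene]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ActivityMatrix:
    """Regulators x samples matrix of per-sample activity scores (iRAS)."""

    regulator_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    scores: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "regulator_names", tuple(self.regulator_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if scores.shape != (len(self.regulator_names), len(self.sample_ids)):
            raise ValueError("score matrix shape inconsistent with labels")
        if not np.isfinite(scores).all():
            raise ValueError("activity scores must be finite")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets, in file order.

    Duplicate member symbols within a line are deduplicated (first
    occurrence kept) with a warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            if name in seen_names:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen_names.add(name)
            members: list[str] = []
            seen_genes: set[str] = set()
            for g in genes:
                if g in seen_genes:
                    logger.warning(
                        "%s: line %d: duplicate member %r in set %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen_genes.add(g)
                members.append(g)
            sets.append(GeneSet(name=name, description=description, members=tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets in canonical GMT form (round-trips with read_gmt)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            if not gs.members:
                raise ValueError(f"gene set {gs.name!r} has no members")
            fh.write("\t".join((gs.name, gs.description, *gs.members)) + "\n")


# ---------------------------------------------------------------------------
# Expression / activity TSV

_FLOAT_FMT = "%.12g"  # >= 10 significant digits so matrices round-trip


def read_expression(path: str | Path, channel_mode: ChannelMode | str) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample IDs, column 1 = gene).

    Rejects missing values, non-numeric cells, duplicate gene rows and
    duplicate sample columns: any of these would silently corrupt ranks.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dup_samples = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup_samples:
        raise FormatError(f"{path}: duplicate sample IDs: {sorted(dup_samples)}")

    df = pd.read_csv(path, sep="\t", index_col=0)
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise FormatError(f"{path}: duplicate gene rows: {dup_genes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}"
            )
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values are not allowed")
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
        channel_mode=ChannelMode(channel_mode),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


def write_activity(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write an activity matrix as TSV, regulators as rows, in input order."""
    df = pd.DataFrame(
        matrix.scores, index=list(matrix.regulator_names), columns=list(matrix.sample_ids)
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="regulator")


def read_activity(
    path: str | Path, n_permutations: int = 1, seed: int = 0
) -> ActivityMatrix:
    """Read an activity TSV back; permutation metadata is not stored in the
    file and must be supplied by the caller (defaults are placeholders)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        regulator_names=tuple(str(r) for r in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        scores=df.to_numpy(dtype=float),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Edge lists

_EDGE_HEADER = "source\ttarget\tis_autoregulatory"


def write_edges(edges: Iterable[tuple[str, str, bool]], path: str | Path) -> None:
    """Write directed regulator->regulatee edges, sorted lexicographically."""
    rows = sorted((src, dst, bool(auto)) for src, dst, auto in edges)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_EDGE_HEADER + "\n")
        for src, dst, auto in rows:
            fh.write(f"{src}\t{dst}\t{'true' if auto else 'false'}\n")


def read_edges(path: str | Path) -> list[tuple[str, str, bool]]:
    edges: list[tuple[str, str, bool]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _EDGE_HEADER:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[2] not in ("true", "false"):
                raise FormatError(f"{path}: line {lineno}: malformed edge row")
            edges.append((fields[0], fields[1], fields[2] == "true"))
    return edges
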