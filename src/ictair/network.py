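"""Regulator-to-regulator network construction from refined target lists.

A motif A annotated to regulator symbol r_A gains a directed edge
r_A -> r_B whenever the gene symbol r_B of another annotated motif B
appears in A's (refined) target list — A is deemed a regulator of B's
regulator.  Motifs redundant on the same regulator symbol are collapsed
to a single node carrying the union of edges; a regulator whose own list
contains its own symbol yields an autoregulatory self-loop.

Unclassified motifs carry no regulator symbol and therefore can neither
regulate nor be targeted; the annotation table (motif, symbol, class) may
map one motif to several symbols (e.g. multi-miRNA motif names), each
becoming its own node.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io_formats import FormatError, GeneSet

__all__ = [
    "RegulatorClass",
    "MotifAnnotation",
    "RegulatorNetwork",
    "read_annotations",
    "build_network",
    "degree_summary",
]


class RegulatorClass(str, Enum):
    TF = "TF"
    miRNA = "miRNA"
    unclassified = "unclassified"


@dataclass(frozen=True)
class MotifAnnotation:
    """Maps a motif name to the gene symbol of its regulator (TF/miRNA).

    Unclassified motifs have an empty symbol.  A motif annotated to
    several regulators appears as several rows sharing the motif name.
    """

    motif_name: str
    regulator_symbol: str
    regulator_class: RegulatorClass

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "regulator_class", RegulatorClass(self.regulator_class)
        )
        if self.regulator_class is RegulatorClass.unclassified:
            if self.regulator_symbol:
                raise ValueError(
                    f"motif {self.motif_name!r}: unclassified motifs carry no symbol"
                )
        elif not self.regulator_symbol:
            raise ValueError(f"motif {self.motif_name!r}: missing regulator symbol")


class RegulatorNetwork:
    """Directed regulator -> target-regulator graph (thin networkx wrapper)."""

    def __init__(self, graph: nx.DiGraph) -> None:
        self.graph = graph

    @property
    def nodes(self) -> dict[str, RegulatorClass]:
        return {n: d["regulator_class"] for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> list[tuple[str, str, bool]]:
        """(source, target, is_autoregulatory) triples, sorted."""
        return sorted(
            (u, v, bool(d["autoregulatory"]))
            for u, v, d in self.graph.edges(data=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatorNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def read_annotations(path: str | Path) -> list[MotifAnnotation]:
    """Read a motif annotation TSV with columns motif, symbol, class.

    The symbol column may be empty (unclassified motifs only).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"motif", "symbol", "class"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out = []
    for motif, symbol, cls_name in zip(df["motif"], df["symbol"], df["class"]):
        try:
            cls = RegulatorClass(cls_name)
        except ValueError as exc:
            raise FormatError(f"{path}: bad regulator class {cls_name!r}") from exc
        out.append(MotifAnnotation(motif, symbol, cls))
    return out


def build_network(
    refined_sets: Sequence[GeneSet],
    annotations: Iterable[MotifAnnotation],
    restrict_to: set[str] | None = None,
) -> RegulatorNetwork:
    """Build the regulator->regulatee graph from refined target lists.

    Every refined set must have at least one annotation row (error naming
    the motif otherwise).  When ``restrict_to`` is given, only motifs in
    it are eligible as regulators and as targets; unclassified motifs are
    excluded from targeting in either case because they carry no symbol.
    """
    by_motif: dict[str, list[MotifAnnotation]] = {}
    for ann in annotations:
        by_motif.setdefault(ann.motif_name, []).append(ann)

    missing = [gs.name for gs in refined_sets if gs.name not in by_motif]
    if missing:
        raise KeyError(f"no annotation for motif(s): {', '.join(sorted(missing))}")

    eligible = [
        gs for gs in refined_sets if restrict_to is None or gs.name in restrict_to
    ]

    graph = nx.DiGraph()
    # collapse motifs to the regulator-symbol level
    symbol_class: dict[str, RegulatorClass] = {}
    for gs in eligible:
        for ann in by_motif[gs.name]:
            if ann.regulator_class is RegulatorClass.unclassified:
                continue
            symbol_class.setdefault(ann.regulator_symbol, ann.regulator_class)
    for symbol, cls in sorted(symbol_class.items()):
        graph.add_node(symbol, regulator_class=cls)

    target_symbols = set(symbol_class)
    for gs in eligible:
        members = gs.member_set
        sources = [
            ann.regulator_symbol
            for ann in by_motif[gs.name]
            if ann.regulator_class is not RegulatorClass.unclassified
        ]
        for r_b in target_symbols & members:
            for r_a in sources:
                graph.add_edge(r_a, r_b, autoregulatory=(r_a == r_b))
    return RegulatorNetwork(graph)


def degree_summary(network: RegulatorNetwork) -> pd.DataFrame:
    """Out-/in-degree per collapsed regulator node, ordered by node name."""
    g = network.graph
    rows = [
        {"node": n, "out_degree": g.out_degree(n), "in_degree": g.in_degree(n)}
        for n in sorted(g.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "out_degree", "in_degree"])
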