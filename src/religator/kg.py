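"""Knowledge-graph store with direct/indirect path semantics.

The graph holds chemical/disease (and intermediate) concepts connected by
predicates.  An edge is either one-directional (causal) or two-directional
(non-causal), and carries provenance: per-source record counts.  Paths
between two concepts are either *direct* (a single edge, in either role) or
*indirect* (one intermediate node; every one-directional edge on the chain
must point away from the first concept and towards the second, i.e. a -> x
and x -> b).  Direct paths suppress indirect ones.

Per pair, the features are the path type, a confidence score, the number of
paths, the set of predicates involved, and a provenance count.  Over multiple
paths of the same kind, score and provenance aggregate as the maximum; an
indirect path's own provenance is the minimum over its two edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .stemming import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class KGEdge:
    subject: str
    predicate: str
    object: str
    directed: bool
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError("self-loops are not allowed")
        if any(count < 1 for count in self.provenance.values()):
            raise ValueError("provenance counts must be >= 1")

    @property
    def total_provenance(self) -> int:
        """Total record count, summed across sources."""
        return sum(self.provenance.values())

    def joins(self, a: str, b: str) -> bool:
        return {self.subject, self.object} == {a, b}

    def oriented_from(self, node: str) -> bool:
        """True if the edge may be traversed leaving ``node``."""
        return not self.directed or self.subject == node


class KnowledgeGraph:
    """Multi-edge store with endpoint indexes."""

    def __init__(self, edges: Iterable[KGEdge] = ()) -> None:
        self.edges: list[KGEdge] = []
        self._by_node: dict[str, list[KGEdge]] = {}
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: KGEdge) -> None:
        self.edges.append(edge)
        self._by_node.setdefault(edge.subject, []).append(edge)
        self._by_node.setdefault(edge.object, []).append(edge)

    def edges_of(self, node: str) -> list[KGEdge]:
        return self._by_node.get(node, [])

    def edges_between(self, a: str, b: str) -> list[KGEdge]:
        return [e for e in self.edges_of(a) if e.joins(a, b)]

    def neighbors(self, node: str) -> set[str]:
        return {
            e.object if e.subject == node else e.subject
            for e in self.edges_of(node)
        }

    def __len__(self) -> int:
        return len(self.edges)


class KGParseError(ValueError):
    """Raised for a malformed edge-list row."""


def load_graph(path, delimiter: str = "\t") -> KnowledgeGraph:
    """Read a delimited edge list.

    Columns: subject, predicate, object, directed (0/1), source, count.
    Rows sharing (subject, predicate, object, directed) merge into one edge
    with a per-source provenance map; a repeated source on the same edge has
    its counts summed with a warning.
    """
    merged: dict[tuple[str, str, str, bool], dict[str, int]] = {}
    order: list[tuple[str, str, str, bool]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != 6:
                raise KGParseError(
                    f"line {lineno}: expected 6 fields, got {len(fields)}"
                )
            subject, predicate, obj, directed, source, count = fields
            try:
                key = (subject, predicate, obj, bool(int(directed)))
                n = int(count)
            except ValueError as exc:
                raise KGParseError(f"line {lineno}: {exc}") from exc
            if key not in merged:
                merged[key] = {}
                order.append(key)
            if source in merged[key]:
                logger.warning(
                    "line %d: duplicate source %r for edge %s-%s->%s; "
                    "counts summed",
                    lineno,
                    source,
                    subject,
                    predicate,
                    obj,
                )
            merged[key][source] = merged[key].get(source, 0) + n
    graph = KnowledgeGraph()
    for subject, predicate, obj, directed in order:
        graph.add_edge(
            KGEdge(
                subject=subject,
                predicate=predicate,
                object=obj,
                directed=directed,
                provenance=merged[(subject, predicate, obj, directed)],
            )
        )
    return graph


def save_graph(graph: KnowledgeGraph, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for edge in graph.edges:
            for source, count in edge.provenance.items():
                handle.write(
                    delimiter.join(
                        [
                            edge.subject,
                            edge.predicate,
                            edge.object,
                            "1" if edge.directed else "0",
                            source,
                            str(count),
                        ]
                    )
                    + "\n"
                )


DIRECT = "direct"
INDIRECT = "indirect"
NO_PATH = "none"


@dataclass(frozen=True)
class KGPath:
    kind: str  # DIRECT or INDIRECT
    edges: tuple[KGEdge, ...]
    intermediate: str | None = None
    forward: bool = True  # for a directed direct edge: oriented a -> b?

    def __post_init__(self) -> None:
        if (self.kind == DIRECT) != (len(self.edges) == 1):
            raise ValueError("direct paths have exactly one edge")

    @property
    def provenance_count(self) -> int:
        if self.kind == DIRECT:
            return self.edges[0].total_provenance
        return min(e.total_provenance for e in self.edges)

    @property
    def predicates(self) -> frozenset[str]:
        return frozenset(e.predicate for e in self.edges)


def find_paths(graph: KnowledgeGraph, a: str, b: str) -> list[KGPath]:
    """All direct paths between ``a`` and ``b``; indirect only if none direct.

    A one-directional edge counts as a direct path regardless of which of the
    two concepts is its subject (the orientation is recorded); on an indirect
    chain a one-directional edge must point towards the intermediate from
    ``a``'s side and away from it on ``b``'s side.
    """
    if a == b:
        return []
    direct = [
        KGPath(kind=DIRECT, edges=(e,), forward=(not e.directed) or e.subject == a)
        for e in graph.edges_between(a, b)
    ]
    if direct:
        return direct
    paths: list[KGPath] = []
    for x in sorted(graph.neighbors(a) & graph.neighbors(b)):
        if x in (a, b):
            continue
        first = [e for e in graph.edges_between(a, x) if e.oriented_from(a)]
        second = [e for e in graph.edges_between(x, b) if e.oriented_from(x)]
        for e1 in first:
            for e2 in second:
                paths.append(KGPath(kind=INDIRECT, edges=(e1, e2), intermediate=x))
    return paths


Scorer = Callable[[KGPath], float]


def _log_provenance(path: KGPath) -> float:
    return sum(math.log(1 + e.total_provenance) for e in path.edges)


def _raw_provenance(path: KGPath) -> float:
    return float(sum(e.total_provenance for e in path.edges))


_SCORERS: dict[str, Scorer] = {
    "log-provenance": _log_provenance,
    "raw-provenance": _raw_provenance,
    "constant-1": lambda path: 1.0,
}


def get_scorer(name: str) -> Scorer:
    try:
        return _SCORERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scorer {name!r}; known: {sorted(_SCORERS)}"
        ) from None


def score_path(path: KGPath, scorer: str | Scorer = "log-provenance") -> float:
    if isinstance(scorer, str):
        scorer = get_scorer(scorer)
    return scorer(path)


@dataclass(frozen=True)
class PathFeatures:
    path_type: str  # DIRECT, INDIRECT or NO_PATH
    score: float
    n_paths: int
    predicates: frozenset[str]
    provenance_count: int

    @classmethod
    def empty(cls) -> "PathFeatures":
        return cls(NO_PATH, 0.0, 0, frozenset(), 0)


def path_features(
    graph: KnowledgeGraph,
    a: str,
    b: str,
    scorer: str | Scorer = "log-provenance",
) -> PathFeatures:
    """Aggregate path evidence for one concept pair.

    Over the (same-kind) paths returned by :func:`find_paths`: score and
    provenance count aggregate as the maximum over paths, predicates as the
    union, n_paths as the count.
    """
    paths = find_paths(graph, a, b)
    if not paths:
        return PathFeatures.empty()
    if isinstance(scorer, str):
        scorer = get_scorer(scorer)
    return PathFeatures(
        path_type=paths[0].kind,
        score=max(scorer(p) for p in paths),
        n_paths=len(paths),
        predicates=frozenset().union(*(p.predicates for p in paths)),
        provenance_count=max(p.provenance_count for p in paths),
    )


def kb_baseline_predict(
    graph: KnowledgeGraph,
    pairs: Iterable[tuple[str, str]],
    treatment_predicates: Iterable[str],
) -> set[tuple[str, str]]:
    """Knowledge-base baseline: positive iff directly connected by a
    non-treatment predicate."""
    treatment = set(treatment_predicates)
    predicted = set()
    for chem, dis in pairs:
        if any(
            e.predicate not in treatment for e in graph.edges_between(chem, dis)
        ):
            predicted.add((chem, dis))
    return predicted
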