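"""Independent brute-force oracles used by the property tests.

Each oracle re-derives the expected result by exhaustive enumeration, without
touching the implementation's data structures or algorithms, so that
agreement is a meaningful check.
"""

from __future__ import annotations

import random

from religator.kg import DIRECT, INDIRECT, KGEdge, KnowledgeGraph
from religator.ner import TermIndex, Token
from religator.parses import ParsedToken, SentenceParse, is_verb


# ---------------------------------------------------------------------------
# Longest-match NER


def brute_force_match(
    tokens: list[Token], index: TermIndex, skip_stopwords: bool = True
) -> list[tuple[int, int, frozenset[str]]]:
    """Leftmost-longest matching by exhaustive key enumeration.

    Scans positions left to right; at each position tries *every* indexed
    key against the (stopword-skipped) token sequence and keeps the longest
    that matches; consumed tokens are skipped before resuming.
    """
    norm = index.normalizer
    spans = []
    n = len(tokens)
    i = 0
    while i < n:
        if skip_stopwords and tokens[i].text in index.stopwords:
            i += 1
            continue
        best = None  # (n_content_tokens, last_token_pos, concepts)
        for key, concepts in index.entries.items():
            positions = []
            j = i
            while j < n and len(positions) < len(key):
                if skip_stopwords and tokens[j].text in index.stopwords:
                    j += 1
                    continue
                positions.append(j)
                j += 1
            if len(positions) < len(key):
                continue
            if tuple(norm(tokens[p].text) for p in positions) == key:
                candidate = (len(key), positions[-1], concepts)
                if best is None or candidate[0] > best[0]:
                    best = candidate
        if best is None:
            i += 1
        else:
            _, last, concepts = best
            spans.append((tokens[i].start, tokens[last].end, concepts))
            i = last + 1
    return spans


# ---------------------------------------------------------------------------
# Knowledge-graph paths


def brute_force_paths(
    edges: list[KGEdge], a: str, b: str
) -> set[tuple[str, ...]]:
    """All length-1 and length-2 chains with the orientation filter.

    Returns a set of canonical path signatures: ("direct", edge index) or
    ("indirect", intermediate, first edge index, second edge index); indirect
    chains are suppressed whenever any direct chain exists.
    """
    nodes = {e.subject for e in edges} | {e.object for e in edges}
    direct = {
        ("direct", str(i))
        for i, e in enumerate(edges)
        if {e.subject, e.object} == {a, b}
    }
    if direct:
        return direct
    indirect = set()
    for x in nodes - {a, b}:
        for i, e1 in enumerate(edges):
            if {e1.subject, e1.object} != {a, x}:
                continue
            if e1.directed and e1.subject != a:
                continue
            for j, e2 in enumerate(edges):
                if {e2.subject, e2.object} != {x, b}:
                    continue
                if e2.directed and e2.subject != x:
                    continue
                indirect.add(("indirect", x, str(i), str(j)))
    return indirect


def path_signatures(graph: KnowledgeGraph, paths) -> set[tuple[str, ...]]:
    """Map implementation paths onto the oracle's signature space."""
    edge_index = {id(e): str(i) for i, e in enumerate(graph.edges)}
    out = set()
    for p in paths:
        if p.kind == DIRECT:
            out.add(("direct", edge_index[id(p.edges[0])]))
        else:
            assert p.kind == INDIRECT
            out.add(
                (
                    "indirect",
                    p.intermediate,
                    edge_index[id(p.edges[0])],
                    edge_index[id(p.edges[1])],
                )
            )
    return out


def random_graph(rng: random.Random, max_nodes: int = 12) -> KnowledgeGraph:
    n_nodes = rng.randint(2, max_nodes)
    nodes = [f"n{i}" for i in range(n_nodes)]
    predicates = ["causes", "treats", "affects"]
    graph = KnowledgeGraph()
    for _ in range(rng.randint(0, 2 * n_nodes)):
        a, b = rng.sample(nodes, 2)
        graph.add_edge(
            KGEdge(
                subject=a,
                predicate=rng.choice(predicates),
                object=b,
                directed=rng.random() < 0.6,
                provenance={"src": rng.randint(1, 9)},
            )
        )
    return graph


# ---------------------------------------------------------------------------
# Dependency trees


def brute_force_governing_verb(
    parse: SentenceParse, token_index: int, verb_tagset: str = "penn"
) -> int | None:
    """List the full ancestor chain, then scan it for the first verb."""
    chain = []
    current = parse.token(token_index).head
    while current != 0:
        chain.append(current)
        current = parse.token(current).head
    for node in chain:
        if is_verb(parse.token(node), verb_tagset):
            return node
    return None


def brute_force_relating_word(
    parse: SentenceParse, index_a: int, index_b: int
) -> int | None:
    """Intersect self-inclusive ancestor lists, nearest-to-tokens first."""

    def chain(idx: int) -> list[int]:
        out = [idx]
        current = parse.token(idx).head
        while current != 0:
            out.append(current)
            current = parse.token(current).head
        return out

    chain_a, chain_b = chain(index_a), chain(index_b)
    common = set(chain_a) & set(chain_b)
    for node in chain_a:
        if node in common:
            return node
    return None


def random_tree(rng: random.Random, max_tokens: int = 15) -> SentenceParse:
    """A random rooted tree over 1..n with random verb/noun tags."""
    n = rng.randint(1, max_tokens)
    order = list(range(1, n + 1))
    rng.shuffle(order)
    heads = {order[0]: 0}
    for i, node in enumerate(order[1:], start=1):
        heads[node] = order[rng.randrange(i)]
    tokens = [
        ParsedToken(
            index=i,
            word=f"w{i}",
            pos=rng.choice(["NN", "VBD", "VB", "IN", "RB", "JJ"]),
            head=heads[i],
            dep_label="dep",
        )
        for i in range(1, n + 1)
    ]
    return SentenceParse(sentence_index=0, tokens=tokens)
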