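"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools

import networkx as nx


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hamming_naive(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def nearest_candidate(observed: str, candidates: list[str], max_mismatches: int):
    """Brute-force unique-nearest-candidate search (ambiguity -> None)."""
    dists = [(hamming_naive(observed, c), c) for c in candidates]
    qualifying = [(d, c) for d, c in dists if d <= max_mismatches]
    if not qualifying:
        return None
    dmin = min(d for d, _ in qualifying)
    hits = [c for d, c in qualifying if d == dmin]
    return hits[0] if len(hits) == 1 else None


def adjacency_partition(umi_counts: dict[str, int], edits: int = 1) -> set[frozenset]:
    """Directed-adjacency UMI clustering via explicit graph reachability.

    Edge u -> v when hamming(u, v) <= edits and count(u) >= 2*count(v) - 1;
    groups grow greedily from the highest-count unassigned root, absorbing
    every node reachable through still-unassigned nodes.
    """
    g = nx.DiGraph()
    g.add_nodes_from(umi_counts)
    for u, v in itertools.permutations(umi_counts, 2):
        if hamming_naive(u, v) <= edits and umi_counts[u] >= 2 * umi_counts[v] - 1:
            g.add_edge(u, v)
    unassigned = set(umi_counts)
    groups = []
    for root in sorted(umi_counts, key=lambda u: (-umi_counts[u], u)):
        if root not in unassigned:
            continue
        sub = g.subgraph(unassigned)
        comp = set(nx.descendants(sub, root)) | {root}
        groups.append(frozenset(comp))
        unassigned -= comp
    return set(groups)


def depth_by_stabbing(intervals: list[tuple[int, int]], length: int) -> list[int]:
    """Per-position coverage by naive interval stabbing."""
    return [sum(1 for s, e in intervals if s <= pos < e) for pos in range(length)]
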