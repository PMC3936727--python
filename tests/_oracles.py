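"""Independent brute-force oracles used by the test suite.

Each is written in a deliberately different formulation from the package
code it checks (jump-style DPs over aligned columns instead of three-state
band DPs, explicit union-find instead of graph components, explicit edge
traversals instead of cached leaf sets), so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import random as _random

import networkx as nx

from crisprpam.search import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH_SCORE,
    MISMATCH_SCORE,
)

_NEG = (-(10 ** 9), -(10 ** 9), -(10 ** 9))


def semiglobal_oracle(spacer: str, window: str) -> tuple[int, int, int]:
    """Best (score, matches, -gaps) over all semi-global alignments.

    Quartic jump DP over aligned columns: between consecutive aligned
    columns the skipped spacer/window runs are gap runs costing
    open + extend * run; spacer overhangs are gap runs, window overhangs
    are free.  Returns the lexicographic max tuple.
    """
    m, n = len(spacer), len(window)

    def gap_run(g: int) -> int:
        return 0 if g == 0 else GAP_OPEN + GAP_EXTEND * g

    def col(i: int, j: int) -> tuple[int, int]:
        if spacer[i] == window[j]:
            return MATCH_SCORE, 1
        return MISMATCH_SCORE, 0

    # E[i][j]: best (score, matches, -gaps) of an alignment whose last
    # aligned column is (i, j), spacer prefix fully accounted for.
    E = [[_NEG] * n for _ in range(m)]
    for i in range(m):
        for j in range(n):
            cs, cm = col(i, j)
            best = (cs - gap_run(i), cm, -i)  # start: spacer prefix gapped
            for ip in range(i):
                for jp in range(j):
                    e = E[ip][jp]
                    if e == _NEG:
                        continue
                    di, dj = i - ip - 1, j - jp - 1
                    cand = (
                        e[0] + cs - gap_run(di) - gap_run(dj),
                        e[1] + cm,
                        e[2] - di - dj,
                    )
                    if cand > best:
                        best = cand
            E[i][j] = best

    # close out: spacer suffix gapped, window suffix free
    total = (-gap_run(m), 0, -m)  # the all-gap alignment
    for i in range(m):
        tail = m - 1 - i
        for j in range(n):
            e = E[i][j]
            if e == _NEG:
                continue
            cand = (e[0] - gap_run(tail), e[1], e[2] - tail)
            if cand > total:
                total = cand
    return total


def sliding_window_hits(query: str, target: str, min_identity: float, max_gaps: int):
    """Exhaustive scan: align the query inside every window of the target.

    Yields (start, end, score, matches, gaps) spans passing the filters;
    the caller deduplicates.  Uses the package scorer on every window —
    the scorer itself is checked against :func:`semiglobal_oracle`.
    """
    from crisprpam.search import align_spacer

    L = len(query)
    n = len(target)
    out = []
    for s in range(n - L + 1):
        window = target[s : s + L + max_gaps]
        if len(window) < L:
            continue
        aln = align_spacer(query, window)
        if aln.identity >= min_identity and aln.gaps <= max_gaps:
            out.append(
                (s + aln.window_start, s + aln.window_end, aln.score, aln.matches, aln.gaps)
            )
    return out


def duplex_oracle(s1: str, s2: str, weights, gap_penalty: int, mismatch_penalty: int) -> int:
    """Best local duplex score by a jump DP over opposed columns.

    Columns oppose position i of strand 1 with position a of reversed
    strand 2; skipped positions between consecutive columns are bulges at
    the linear gap penalty; everything outside the duplex is free.
    """
    r2 = s2[::-1]
    n, m = len(s1), len(r2)
    table = {"CG": weights["GC"], "AU": weights["AU"], "GU": weights["GU"]}

    def col(i: int, a: int) -> int:
        return table.get("".join(sorted((s1[i], r2[a]))), mismatch_penalty)

    E = [[None] * m for _ in range(n)]
    best = 0
    for i in range(n):
        for a in range(m):
            v = col(i, a)
            for ip in range(i):
                for ap in range(a):
                    if E[ip][ap] is None:
                        continue
                    cand = col(i, a) + E[ip][ap] + gap_penalty * ((i - ip - 1) + (a - ap - 1))
                    if cand > v:
                        v = cand
            E[i][a] = v
            if v > best:
                best = v
    return best


def union_find_components(ids, edges):
    """Connected components by explicit union-find."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted((tuple(sorted(g)) for g in groups.values()), key=lambda c: (-len(c), c))


def random_additive_tree(n_leaves: int, rng: _random.Random):
    """A random unrooted binary tree as a networkx graph with edge weights.

    Returns (graph, leaf labels).  Start from a star on three leaves, then
    repeatedly split a random edge to attach each new leaf.
    """
    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_leaves)]
    center = "i0"
    internal = 1
    for leaf in labels[:3]:
        g.add_edge(center, leaf, weight=rng.uniform(0.1, 1.0))
    for leaf in labels[3:]:
        u, v = rng.choice(list(g.edges()))
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"i{internal}"
        internal += 1
        split = rng.uniform(0.2, 0.8)
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=rng.uniform(0.1, 1.0))
    return g, labels


def tree_graph_distances(g, labels):
    """Leaf-to-leaf additive distances from the edge-weighted graph."""
    import numpy as np

    d = np.zeros((len(labels), len(labels)))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[i, j] = d[j, i] = lengths[a][b]
    return d


def tree_graph_bipartitions(g, labels):
    """Non-trivial leaf bipartitions of the graph tree, canonicalised.

    Removing each internal edge splits the leaves; the side not containing
    the lexicographically first leaf represents the split.
    """
    leaves = set(labels)
    anchor = min(leaves)
    out = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        side = set(nx.node_connected_component(h, u)) & leaves
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out
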