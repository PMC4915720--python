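"""Independent oracles used only by the test suite.

These re-derive expected values through a different route than the package:
a regex compiler for signature patterns and a textbook Gotoh dynamic program
for affine-gap global alignment scores.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Align import substitution_matrices

_AA = "ACDEFGHIKLMNPQRSTVWY"


def pattern_to_regex(text: str) -> re.Pattern:
    """Translate either pattern dialect to a regular expression, independently.

    Wildcards become a class over the standard residues plus X (the package's
    contract is that only wildcards admit X).
    """
    text = text.strip()
    wild = f"[{_AA}X]"

    def group_to_class(body: str) -> str:
        return "[" + "".join(a.strip().upper() for a in body.split("/")) + "]"

    depth = 0
    dashed = False
    for ch in text:
        depth += ch == "("
        depth -= ch == ")"
        if ch == "-" and depth == 0:
            dashed = True
    parts: list[str] = []
    if dashed:
        for tok in text.split("-"):
            tok = tok.strip()
            if tok.startswith("(") and tok.endswith(")"):
                tok = tok[1:-1]
            if "/" in tok:
                parts.append(group_to_class(tok))
            elif tok in ("x", "y", "z", "X"):
                parts.append(wild)
            else:
                parts.append(tok.upper())
    else:
        i = 0
        while i < len(text):
            if text[i] == "(":
                j = text.index(")", i)
                parts.append(group_to_class(text[i + 1 : j]))
                i = j + 1
            elif text[i] in ("x", "y", "z", "X"):
                parts.append(wild)
                i += 1
            else:
                parts.append(text[i].upper())
                i += 1
    return re.compile("".join(parts))


def regex_matches(text: str, window: str) -> bool:
    return pattern_to_regex(text).fullmatch(window.upper()) is not None


def regex_search_starts(text: str, sequence: str) -> list[int]:
    """1-based start positions of overlapping matches."""
    rx = pattern_to_regex(text)
    return [m.start() + 1 for m in re.finditer(f"(?=({rx.pattern}))", sequence.upper())]


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(a: str, b: str, open_cost: float = 10.0, extend_cost: float = 1.0) -> float:
    """Affine-gap global alignment score by the three-matrix Gotoh DP.

    Gap convention matches the package aligner: the first gap position costs
    ``open_cost``, each further position ``extend_cost``.
    """
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Y[0, j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - extend_cost,
                          Y[i - 1, j] - open_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - extend_cost,
                          X[i, j - 1] - open_cost)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def random_additive_matrix(rng: np.random.Generator, n_taxa: int = 6):
    """A random additive distance matrix plus its generating bipartitions.

    Builds a random unrooted binary topology by sequential leaf attachment
    with strictly positive branch lengths and returns (labels, matrix,
    set-of-frozensets bipartitions over the leaf set).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # graph as adjacency: node -> {neighbor: length}
    adj: dict[int, dict[int, float]] = {}
    next_node = n_taxa

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    blen = lambda: float(rng.uniform(0.05, 1.0))  # noqa: E731
    add_edge(0, 1, blen())
    for leaf in range(2, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u][v]
        mid = next_node
        next_node += 1
        drop_edge(u, v)
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, blen())

    def dists_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        return seen

    mat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = dists_from(i)
        for j in range(n_taxa):
            mat[i, j] = d[j]
    # bipartitions: remove each edge, collect the leaf labels on u's side
    parts = set()
    full = frozenset(labels)
    for u in list(adj):
        for v in list(adj[u]):
            if u < v:
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if (x, y) == (u, v):
                            continue
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                side = frozenset(labels[i] for i in seen if i < n_taxa)
                if 2 <= len(side) <= n_taxa - 2:
                    parts.add(canonical_bipart(side, full))
    return labels, mat, parts


def canonical_bipart(side: frozenset, full: frozenset) -> frozenset:
    return min(side, full - side, key=sorted)
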