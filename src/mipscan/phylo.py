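"""p-distance matrices and Neighbor-Joining trees.

Distances are the proportion of differing residues over compared columns of a
pairwise global alignment (pairwise deletion: columns with a gap in either
sequence are excluded for that pair).  Trees are built with the Saitou-Nei
Neighbor-Joining agglomeration, deterministically: ties on the Q criterion are
broken by the lexicographically smallest taxon-label pair, and negative branch
lengths are clamped to zero with the remainder shifted to the sister edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Clade:
    """A node of an (un)rooted tree with branch length to its parent."""

    name: str | None = None
    branch_length: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        names: list[str] = []
        for child in self.children:
            names.extend(child.leaf_names())
        return names

    def edge_count(self) -> int:
        n = 0
        for child in self.children:
            n += 1 + child.edge_count()
        return n


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with taxon labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("nonzero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def p_distance(a: str, b: str) -> float:
    """p-distance between two *aligned* sequences (pairwise deletion).

    ``a`` and ``b`` must be equal length; positions where either has a gap
    ('-') are excluded.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    compared = mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns")
    return mismatch / compared


def p_distance_matrix(records, aligner=None) -> DistanceMatrix:
    """Pairwise p-distance matrix; unaligned inputs are aligned globally.

    ``records`` is a sequence of objects with ``id`` and ``residues``
    attributes (or ``(id, residues)`` tuples).  Pairwise global alignments are
    computed internally with the package's standard scoring.
    """
    from .extract import make_aligner  # local import to avoid a cycle

    items = []
    for rec in records:
        if hasattr(rec, "id"):
            items.append((rec.id, rec.residues))
        else:
            items.append((rec[0], rec[1]))
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [name for name, _ in items]
    if aligner is None:
        aligner = make_aligner()
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(items[i][1], items[j][1])[0]
            sa, sb = str(aln[0]), str(aln[1])
            mat[i, j] = mat[j, i] = p_distance(sa, sb)
    return DistanceMatrix(labels, mat)


def _nj_branch_pair(d_ij: float, r_i: float, r_j: float, n: int) -> tuple[float, float]:
    li = 0.5 * d_ij + (r_i - r_j) / (2 * (n - 2))
    lj = d_ij - li
    # clamp a negative length to 0, moving the remainder to the sister edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def build_nj_tree(matrix: DistanceMatrix) -> Clade:
    """Saitou-Nei Neighbor-Joining on a distance matrix.

    Returns an unrooted binary tree represented with a trifurcating root
    (the standard convention), so an n-leaf tree has 2n - 3 edges.
    """
    if len(matrix.labels) < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[str, Clade] = {lab: Clade(name=lab) for lab in matrix.labels}
    # active distances keyed by frozenset of working labels
    labels = list(matrix.labels)
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(matrix.values[i, j])

    counter = 0
    while len(labels) > 3:
        n = len(labels)
        r = {a: sum(dist[frozenset((a, b))] for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la, lb = _nj_branch_pair(d_ab, r[a], r[b], n)
        new_label = f"_nj{counter}"
        counter += 1
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.branch_length, child_b.branch_length = la, lb
        nodes[new_label] = Clade(children=[child_a, child_b])
        new_d = {}
        for c in labels:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - d_ab
            )
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        dist = {
            k: v for k, v in dist.items() if not (k & {a, b})
        }
        for c, v in new_d.items():
            dist[frozenset((new_label, c))] = v

    a, b, c = sorted(labels)
    d_ab = dist[frozenset((a, b))]
    d_ac = dist[frozenset((a, c))]
    d_bc = dist[frozenset((b, c))]
    la = max(0.0, 0.5 * (d_ab + d_ac - d_bc))
    lb = max(0.0, 0.5 * (d_ab + d_bc - d_ac))
    lc = max(0.0, 0.5 * (d_ac + d_bc - d_ab))
    root = Clade()
    for lab, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(lab)
        node.branch_length = length
        root.children.append(node)
    return root


def bootstrap_support(aligned: dict[str, str], n_replicates: int, rng: np.random.Generator):
    """Bootstrap clade support from an alignment (column resampling).

    ``aligned`` maps taxon label to an aligned (equal-length) sequence.
    Returns a dict mapping a frozenset of leaf names (a bipartition side) to
    the fraction of replicates containing that clade.
    """
    labels = list(aligned)
    length = len(next(iter(aligned.values())))
    if any(len(s) != length for s in aligned.values()):
        raise ValueError("aligned sequences must share one length")
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [(lab, "".join(aligned[lab][c] for c in cols)) for lab in labels]
        n = len(labels)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = p_distance(resampled[i][1], resampled[j][1])
        tree = build_nj_tree(DistanceMatrix(labels, mat))
        for clade in _internal_biparts(tree):
            counts[clade] = counts.get(clade, 0) + 1
    return {k: v / n_replicates for k, v in counts.items()}


def _internal_biparts(tree: Clade) -> set[frozenset]:
    parts = set()

    def walk(node: Clade):
        for child in node.children:
            if not child.is_leaf:
                parts.add(frozenset(child.leaf_names()))
            walk(child)

    walk(tree)
    return parts


def tree_to_newick(tree: Clade) -> str:
    """Serialize to Newick with branch lengths."""

    def fmt_name(name: str) -> str:
        if any(ch in name for ch in " ()[]:;,'"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def walk(node: Clade) -> str:
        if node.is_leaf:
            if not node.name:
                raise ValueError("unnamed leaf")
            body = fmt_name(node.name)
        else:
            body = "(" + ",".join(walk(c) for c in node.children) + ")"
            if node.name:
                body += fmt_name(node.name)
        if node.branch_length is not None:
            if math.isnan(node.branch_length):
                raise ValueError("NaN branch length")
            body += f":{node.branch_length:g}"
        return body

    return walk(tree) + ";"
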