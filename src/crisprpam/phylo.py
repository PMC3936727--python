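"""Distance-based phylogenetic grouping.

A deliberately transparent stand-in for likelihood tree inference: select
informative alignment columns (low gap fraction, some variation), compute
Poisson-corrected distances d = -ln(1 - p) from pairwise mismatch fractions,
build an unrooted binary tree by canonical neighbor joining (Saitou–Nei Q
criterion, deterministic tie-breaks, negative branch lengths clamped to 0),
and attach column-bootstrap supports.  What this pipeline asserts about a
tree is grouping — which leaves fall on which side of which edge — not
branch-length fidelity, and NJ is exact on additive distances, so grouping
claims are testable against ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord

log = logging.getLogger(__name__)

GAP = "-"
MAX_POISSON_DISTANCE = 10.0


class PhyloUsageError(ValueError):
    """Bad arguments to the tree routines."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows keyed by sequence id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PhyloUsageError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloUsageError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloUsageError(f"rows have unequal lengths {sorted(lengths)}")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        return cls(tuple(r.id for r in records), tuple(r.residues for r in records))

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(self.ids, tuple("".join(row[i] for i in indices) for row in self.rows))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.labels), len(self.labels)):
            raise PhyloUsageError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise PhyloUsageError("matrix not symmetric")
        if (d < 0).any():
            raise PhyloUsageError("negative distances")
        if not np.allclose(np.diag(d), 0):
            raise PhyloUsageError("nonzero diagonal")


class TreeNode:
    """One node of an unrooted tree serialised with a root trifurcation."""

    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.children: list[TreeNode] = []
        self.length = length
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return frozenset(out)


class Tree:
    """Unrooted leaf-labelled tree with branch lengths and optional supports."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._canonicalise(root)

    def _canonicalise(self, node: TreeNode) -> None:
        for c in node.children:
            self._canonicalise(c)
        node.children.sort(key=lambda c: min(c.leaf_labels()))

    @property
    def leaves(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def _internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf and n is not self.root:
                out.append(n)
            stack.extend(n.children)
        return out

    def bipartitions(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Canonical edge bipartitions: the side NOT containing the first leaf.

        Each internal edge splits the leaves in two; the side excluding the
        lexicographically first leaf represents the split, making sets
        comparable across differently rooted serialisations.
        """
        all_leaves = self.leaves
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        stack = [c for c in self.root.children]
        while stack:
            n = stack.pop()
            stack.extend(n.children)
            side = n.leaf_labels()
            if anchor in side:
                side = all_leaves - side
            if nontrivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out.add(frozenset(side))
        return out

    def check_monophyly(self, group: Iterable[str]) -> bool:
        """True iff one edge separates exactly ``group`` from the rest.

        By convention the full leaf set and singletons are monophyletic
        (the trivial bipartitions at the root and at a leaf edge).
        """
        group = frozenset(group)
        all_leaves = self.leaves
        unknown = group - all_leaves
        if unknown:
            raise PhyloUsageError(f"labels not in tree: {sorted(unknown)}")
        if not group:
            raise PhyloUsageError("empty group")
        if group == all_leaves or len(group) == 1:
            return True
        sides: set[frozenset[str]] = set()
        stack = list(self.root.children)
        while stack:
            n = stack.pop()
            stack.extend(n.children)
            sides.add(n.leaf_labels())
        return group in sides or (all_leaves - group) in sides

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf patristic distances (sum of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in walk(c).items()}
                child_maps.append(cm)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for a, da in child_maps[i].items():
                        for b, db in child_maps[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
                below = {k: v for cm in child_maps for k, v in cm.items()}
            return below

        walk(self.root)
        return dists

    def newick(self, include_supports: bool = True) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_supports and node.support is not None:
                label = f"{node.support:.3g}"
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6g}"

        return fmt(self.root, top=True) + ";"


def select_informative_columns(
    alignment: Alignment,
    max_gap_fraction: float = 0.5,
    require_variation: bool = True,
) -> tuple[Alignment, list[int]]:
    """Keep columns with gap fraction <= threshold and, optionally, variation.

    'Informative' here means confidently comparable: mostly ungapped, and
    (by default) showing at least two distinct non-gap residues.  The kept
    indices are returned for audit.
    """
    n = len(alignment.ids)
    if n == 0:
        raise PhyloUsageError("empty alignment")
    kept = []
    for i in range(alignment.length):
        col = alignment.column(i)
        gaps = col.count(GAP)
        if gaps / n > max_gap_fraction:
            continue
        if require_variation and len(set(col) - {GAP}) < 2:
            continue
        kept.append(i)
    if not kept:
        raise PhyloUsageError(
            "no columns retained; relax max_gap_fraction or disable require_variation"
        )
    return alignment.take_columns(kept), kept


def distance_matrix(alignment: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise p-distance or Poisson-corrected distance over shared columns.

    p = mismatches / compared positions, over columns where neither row is
    gapped; poisson applies d = -ln(1 - p), capped with a warning as p -> 1.
    """
    if model not in ("p", "poisson"):
        raise PhyloUsageError(f"unknown model {model!r}")
    n = len(alignment.ids)
    if n < 3:
        raise PhyloUsageError("need >= 3 sequences for a tree")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment.rows[i], alignment.rows[j]
            compared = mismatches = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                compared += 1
                if x != y:
                    mismatches += 1
            if compared == 0:
                raise PhyloUsageError(
                    f"no comparable positions between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
                )
            p = mismatches / compared
            if model == "p":
                dist = p
            elif p >= 1.0:
                log.warning("saturated pair %s/%s (p = 1); distance capped",
                            alignment.ids[i], alignment.ids[j])
                dist = MAX_POISSON_DISTANCE
            else:
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(alignment.ids), d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining (Saitou–Nei).

    Labels are processed in sorted order so permuting the input changes
    nothing; ties in the Q criterion break toward the first (i, j) pair in
    that order; negative branch lengths are clamped to 0.  The final three
    lineages join at a root trifurcation with closed-form lengths, so every
    internal node of the unrooted tree has degree 3.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloUsageError("need >= 3 labels")

    order = sorted(range(n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()

    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin over (i, j), i < j in current active order
        best = (np.inf, -1, -1)
        for ai in range(k):
            for aj in range(ai + 1, k):
                if q[ai, aj] < best[0] - 1e-12:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        vj = dij - vi
        vi, vj = max(0.0, vi), max(0.0, vj)

        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.children = [nodes[i], nodes[j]]

        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for am in active:
            if am in (i, j):
                continue
            dist = max(0.0, 0.5 * (d[i, am] + d[j, am] - dij))
            d[new_idx, am] = d[am, new_idx] = dist
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new_idx]

    # join the final three lineages at a trifurcating root
    a, b, c = active
    root = TreeNode()
    nodes[a].length = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    nodes[b].length = max(0.0, 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    nodes[c].length = max(0.0, 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    root.children = [nodes[a], nodes[b], nodes[c]]
    return Tree(root)


def bootstrap_support(
    alignment: Alignment,
    B: int = 100,
    seed: int = 0,
    model: str = "poisson",
    max_gap_fraction: float = 0.5,
    require_variation: bool = True,
) -> Tree:
    """Point NJ tree with per-edge column-bootstrap support frequencies.

    Columns of the informative alignment are resampled with replacement B
    times; each replicate is re-joined and each point-tree bipartition's
    support is the fraction of replicates containing it.  Deterministic for
    a given seed.
    """
    if B < 1:
        raise PhyloUsageError("B must be >= 1")
    informative, _ = select_informative_columns(alignment, max_gap_fraction, require_variation)
    point = nj_tree(distance_matrix(informative, model=model))

    rng = np.random.default_rng(seed)
    ncols = informative.length
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    effective = 0
    for _ in range(B):
        idx = rng.integers(0, ncols, size=ncols)
        replicate = informative.take_columns(list(idx))
        try:
            rep_tree = nj_tree(distance_matrix(replicate, model=model))
        except PhyloUsageError as exc:
            log.warning("bootstrap replicate skipped: %s", exc)
            continue
        effective += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if effective == 0:
        raise PhyloUsageError("all bootstrap replicates failed")

    all_leaves = point.leaves
    anchor = min(all_leaves)
    stack = list(point.root.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            continue
        side = node.leaf_labels()
        if anchor in side:
            side = all_leaves - side
        if frozenset(side) in counts:
            node.support = counts[frozenset(side)] / effective
    return point


def robinson_foulds(tree_a: Tree, tree_b: Tree) -> int:
    """Symmetric bipartition-set difference between two trees on one leaf set."""
    if tree_a.leaves != tree_b.leaves:
        raise PhyloUsageError("trees have different leaf sets")
    return len(tree_a.bipartitions() ^ tree_b.bipartitions())
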