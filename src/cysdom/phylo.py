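"""Distance matrices, Neighbor-Joining, Newick serialization, bipartitions.

Neighbor-Joining follows Saitou & Nei's classical agglomeration on the
Q-criterion; it is exact on additive matrices. Ties in Q are broken by the
smallest (i, j) pair of label indices and negative branch lengths are
clamped to zero (and logged), which makes the output deterministic.
The tree is unrooted, represented with one trifurcating root.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .align import Msa
from .jtt import corrected_identity_distance, jtt_ml_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric matrix of evolutionary distances (subs/site)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")

    def to_phylip(self) -> str:
        """Square PHYLIP format (tab-separated values)."""
        lines = [str(len(self.labels))]
        for label, row in zip(self.labels, self.d):
            lines.append(label + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def distance_matrix(msa: Msa, method: str = "ml") -> DistanceMatrix:
    """All pairwise JTT distances of an MSA (computed once per pair).

    ``method``: ``"ml"`` (maximum-likelihood, default) or ``"identity"``
    (inversion of the JTT expected-identity curve on the p-distance).
    """
    if method == "ml":
        fn = jtt_ml_distance
    elif method == "identity":
        fn = corrected_identity_distance
    else:
        raise ValueError(f"unknown distance method {method!r}")
    n = len(msa.labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(msa.rows[i], msa.rows[j])
    # distances at the optimizer's lower bound are numerically ~1e-6; report 0
    d[d <= 2e-6] = 0.0
    return DistanceMatrix(labels=msa.labels, d=d)


@dataclass
class TreeNode:
    """A node of an (unrooted) phylogeny; the root is a trifurcation."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths in substitutions/site."""

    root: TreeNode

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets under each internal edge (non-trivial splits only)."""
        all_leaves = self.leaf_labels
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                splits.add(below)
            return below

        walk(self.root)
        return splits

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        labels = sorted(self.leaf_labels)
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for child, bl in node.children:
                cm = {k: v + bl for k, v in walk(child).items()}
                child_maps.append(cm)
            for a_i, cm_a in enumerate(child_maps):
                for cm_b in child_maps[a_i + 1 :]:
                    for la, va in cm_a.items():
                        for lb, vb in cm_b.items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = va + vb
                below.update({k: v for cm in child_maps for k, v in cm.items()})
            return below

        walk(self.root)
        return DistanceMatrix(labels=tuple(labels), d=d)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical Saitou–Nei Neighbor-Joining.

    Deterministic: Q-ties resolved by the smallest (i, j) label-index pair;
    negative branch lengths clamped to 0 with a log message.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(D.labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def clamp(bl: float, context: str) -> float:
        if bl < 0:
            logger.info("clamping negative branch length %.6g to 0 (%s)", bl, context)
            return 0.0
        return bl

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * get(i, j) - row_sum[i] - row_sum[j]
                if best is None or q < best - 1e-15:
                    best, best_pair = q, (i, j)
        i, j = best_pair
        dij = get(i, j)
        li = 0.5 * dij + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = dij - li
        li = clamp(li, f"join of {i},{j}")
        lj = clamp(lj, f"join of {i},{j}")
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    root = TreeNode(
        children=[
            (nodes[i], clamp(li, "final join")),
            (nodes[j], clamp(lj, "final join")),
            (nodes[k], clamp(lk, "final join")),
        ]
    )
    return PhyloTree(root=root)


_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>]")


def _format_label(label: str) -> str:
    if label == "" or _NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree, decimals: int = 6) -> str:
    """Newick string with branch lengths; labels quoted only when needed."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _format_label(node.label or "")
        inner = ",".join(
            f"{fmt(child)}:{bl:.{decimals}f}" for child, bl in node.children
        )
        return f"({inner})"

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (labels, optional branch lengths, quotes)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def error(msg: str):
        raise ValueError(f"Newick parse error at offset {pos}: {msg}")

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            error("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".-+eE"):
                pos += 1
            return float(s[start:pos])
        return 0.0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                error("expected ')'")
            pos += 1
            label = parse_label()  # internal label, kept if present
            node = TreeNode(label=label or None, children=children)
            return node, parse_length()
        label = parse_label()
        if not label:
            error("empty leaf label")
        return TreeNode(label=label), parse_length()

    node, _ = parse_node()
    if pos != len(s):
        error("trailing characters")
    return PhyloTree(root=node)


def has_bipartition(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """True iff some internal edge splits the leaves into ``taxa`` | rest."""
    taxa = frozenset(taxa)
    leaves = tree.leaf_labels
    if not taxa < leaves:
        raise ValueError("taxa set is not a proper subset of the leaf set")
    if not 1 < len(taxa) < len(leaves) - 1:
        raise ValueError("taxa set must have size in (1, n-1)")
    splits = tree.bipartitions()
    return taxa in splits or (leaves - taxa) in splits


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def ascii_tree(tree: PhyloTree) -> str:
    """A minimal text rendering of the tree for logs and reports."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, bl: float | None) -> None:
        tag = node.label if node.is_leaf else "+"
        if bl is None:
            lines.append(f"{prefix}{tag}")
        else:
            lines.append(f"{prefix}{tag} ({bl:.4f})")
        for child, length in node.children:
            walk(child, prefix + "  ", length)

    walk(tree.root, "", None)
    return "\n".join(lines) + "\n"
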