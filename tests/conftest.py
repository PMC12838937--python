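"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, closed forms) and share no code with the package paths they
check.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from cysdom.seq_core import SequenceRecord
from cysdom.signature import CysteineSignature, DomainMatch

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# oracle: brute-force signature matching over all cysteine-index tuples

def brute_force_matches(
    seq: str, sig: CysteineSignature, allow_cys_in_spacer: bool = False
) -> list[tuple[int, ...]]:
    """All complete skeleton-position tuples, by exhaustive enumeration.

    Walks every combination of cysteine positions of the right length and
    keeps those whose consecutive spacings fall in the signature's ranges,
    whose spacers are cysteine-free when required, and which leave room for
    the trailing gap. Exponential in principle; fine at test scale.
    """
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    k = sig.n_cys
    results: list[tuple[int, ...]] = []

    def recurse(chosen: list[int], remaining: list[int]) -> None:
        if len(chosen) == k:
            if len(seq) - chosen[-1] - 1 >= sig.trailing_gap[0]:
                results.append(tuple(chosen))
            return
        lo, hi = sig.gaps[len(chosen) - 1]
        for idx, pos in enumerate(remaining):
            gap = pos - chosen[-1] - 1
            if gap > hi:
                break
            if gap < lo:
                continue
            if not allow_cys_in_spacer and any(chosen[-1] < c < pos for c in cys):
                continue  # another cysteine sits inside the spacer
            recurse(chosen + [pos], remaining[idx + 1 :])

    for i, start in enumerate(cys):
        recurse([start], cys[i + 1 :])
    return sorted(results)


def brute_force_best_subset(matches: list[DomainMatch]) -> tuple[int, list]:
    """Maximum-cardinality non-overlapping subset by trying all subsets."""
    best_n = 0
    best_keys = None
    items = sorted(matches, key=lambda m: (m.start, m.end))
    for r in range(len(items), 0, -1):
        if best_n >= r:
            break
        for combo in itertools.combinations(items, r):
            ok = all(
                a.end <= b.start
                for a, b in itertools.combinations(
                    sorted(combo, key=lambda m: m.start), 2
                )
            )
            if ok:
                keys = sorted((m.start, m.end) for m in combo)
                if r > best_n or (r == best_n and keys < best_keys):
                    best_n, best_keys = r, keys
        if best_keys is not None and best_n == r:
            break
    return best_n, best_keys or []


def random_protein(rng: random.Random, length: int, cys_frac: float) -> str:
    non_cys = AA20.replace("C", "")
    return "".join(
        "C" if rng.random() < cys_frac else rng.choice(non_cys)
        for _ in range(length)
    )


# ---------------------------------------------------------------------------
# oracle: random additive trees and their path-length matrices

def random_additive_case(rng: random.Random, n_taxa: int):
    """A random binary tree (as splits) and its additive distance matrix."""
    labels = [f"T{i}" for i in range(n_taxa)]
    # build an unrooted binary tree by sequential leaf attachment
    # edges: dict node -> dict neighbor -> length
    edges: dict[int, dict[int, float]] = {}
    node_label: dict[int, str] = {}

    def add_edge(a: int, b: int, w: float) -> None:
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    def blen() -> float:
        return rng.uniform(0.1, 2.0)

    node_label[0] = labels[0]
    node_label[1] = labels[1]
    add_edge(0, 1, blen())
    next_node = 2
    internal_start = n_taxa
    internal = internal_start
    for i in range(2, n_taxa):
        # pick a random edge and attach the new leaf in its middle
        all_edges = [(a, b) for a in edges for b in edges[a] if a < b]
        a, b = rng.choice(all_edges)
        w = edges[a][b]
        mid = internal + 1000  # distinct id space for internal nodes
        internal += 1
        split = rng.uniform(0.2, 0.8)
        del edges[a][b]
        del edges[b][a]
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        leaf = next_node
        next_node += 1
        node_label[leaf] = labels[i]
        add_edge(mid, leaf, blen())

    # path distances between leaves
    leaf_nodes = {node_label[n]: n for n in node_label}
    D = np.zeros((n_taxa, n_taxa))

    def dists_from(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    for i, la in enumerate(labels):
        dmap = dists_from(leaf_nodes[la])
        for j, lb in enumerate(labels):
            D[i, j] = dmap[leaf_nodes[lb]]

    # non-trivial bipartitions: leaves on each side of every internal edge
    splits: set[frozenset[str]] = set()
    for a in edges:
        for b in edges[a]:
            if a < b:
                # leaves reachable from a without crossing (a, b)
                seen = {a, b}
                stack = [a]
                side: set[str] = set()
                while stack:
                    u = stack.pop()
                    if u in node_label:
                        side.add(node_label[u])
                    for v in edges[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                if 1 < len(side) < n_taxa - 1:
                    splits.add(frozenset(side))
    return labels, D, splits


@pytest.fixture(scope="session")
def standins():
    from cysdom.standins import reference_standins

    return reference_standins()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(42)
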