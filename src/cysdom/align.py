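"""Global pairwise alignment and a small progressive multiple aligner.

Pairwise alignment is classical Needleman–Wunsch/Gotoh with affine gap
penalties and a fully deterministic traceback (tie order: diagonal > up >
left). A gap of length L costs ``gap_open + L * gap_extend``, the BLAST
convention. Substitution matrices come from Biopython
(``Bio.Align.substitution_matrices``); BLOSUM62 with 11/1 is the default.

The multiple aligner is intentionally modest — antistasin-like domains share
a fixed cysteine skeleton and near-equal lengths, so a guide tree from
pairwise identity distances followed by sequential profile merges is
sufficient. The consensus line follows the Clustal convention as used in the
figure legends of this field: ``*`` identical column, ``:`` all residues in
one strong similarity group, ``.`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import substitution_matrices

from .seq_core import SequenceRecord

NEG_INF = float("-inf")

#: Clustal "strong" similarity groups for the ':' consensus symbol.
STRONG_GROUPS = [
    frozenset(g)
    for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
]


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("all-gap column in alignment")

    @property
    def degapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def degapped_b(self) -> str:
        return self.aligned_b.replace("-", "")


def _matrix(matrix_name: str):
    try:
        return substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps, deterministic traceback.

    ``gap_open`` and ``gap_extend`` are positive penalties; a gap of length
    L costs ``gap_open + L * gap_extend``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if not gap_open >= gap_extend >= 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    mat = _matrix(matrix_name)

    def s(x: str, y: str) -> float:
        return float(mat[x, y])

    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gapped position
    # DP states: M diagonal, X gap in b (consumes a, "up"), Y gap in a ("left")
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    # traceback: for M the predecessor state; for X/Y whether the gap opened here
    bM = [[""] * (m + 1) for _ in range(n + 1)]
    bX = [[""] * (m + 1) for _ in range(n + 1)]
    bY = [[""] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
        bX[i][0] = "X" if i > 1 else "M"
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
        bY[0][j] = "Y" if j > 1 else "M"

    def argbest(m_val: float, x_val: float, y_val: float) -> tuple[float, str]:
        # preference on exact ties: diagonal (M) > up (X) > left (Y)
        best, state = m_val, "M"
        if x_val > best:
            best, state = x_val, "X"
        if y_val > best:
            best, state = y_val, "Y"
        return best, state

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = s(a[i - 1], b[j - 1])
            best, state = argbest(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best + sub
            bM[i][j] = state
            best, state = argbest(
                M[i - 1][j] - first, X[i - 1][j] - gap_extend, Y[i - 1][j] - first
            )
            X[i][j] = best
            bX[i][j] = state
            best, state = argbest(
                M[i][j - 1] - first, X[i][j - 1] - first, Y[i][j - 1] - gap_extend
            )
            Y[i][j] = best
            bY[i][j] = state

    score, state = argbest(M[n][m], X[n][m], Y[n][m])
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            prev = bM[i][j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == "X":
            prev = bX[i][j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = bY[i][j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


@dataclass(frozen=True)
class Msa:
    """A rectangular multiple alignment."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate MSA labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MSA rows are not rectangular")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace("-", "")

    def consensus_line(self) -> str:
        out = []
        for k in range(self.n_cols):
            col = {r[k] for r in self.rows}
            if "-" in col:
                out.append(".")
            elif len(col) == 1:
                out.append("*")
            elif any(col <= g for g in STRONG_GROUPS):
                out.append(":")
            else:
                out.append(".")
        return "".join(out)

    def to_clustal(self, width: int = 60) -> str:
        """Clustal-style text with the ``*``/``:``/``.`` consensus line."""
        name_w = max(len(l) for l in self.labels) + 2
        cons = self.consensus_line()
        blocks = []
        for start in range(0, self.n_cols, width):
            lines = [
                f"{label:<{name_w}}{row[start:start + width]}"
                for label, row in zip(self.labels, self.rows)
            ]
            lines.append(" " * name_w + cons[start : start + width])
            blocks.append("\n".join(lines))
        header = "Consensus: '*' identical, ':' strong group (STA NEQK NHQK NDEQ QHRK MILV MILF HY FYW), '.' otherwise\n"
        return header + "\n\n".join(blocks) + "\n"


def progressive_msa(
    domains: Sequence[SequenceRecord],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Progressive multiple alignment via identity-distance guide tree.

    Pairwise p-distances (1 − identical fraction over aligned columns) feed
    a UPGMA-style agglomeration; profiles are merged in that order by
    profile–profile Needleman–Wunsch with sum-of-pairs column scores.
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 sequences for an MSA")
    ids = [d.id for d in domains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [d.residues for d in domains]
    n = len(seqs)
    # pairwise identity distances
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], matrix_name, gap_open, gap_extend)
            ident = sum(x == y for x, y in zip(aln.aligned_a, aln.aligned_b))
            d = 1.0 - ident / len(aln.aligned_a)
            dist[i][j] = dist[j][i] = d
    # UPGMA-style merge order
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    cdist = {(i, j): dist[i][j] for i in range(n) for j in range(i + 1, n)}
    profiles: dict[int, list[tuple[int, str]]] = {
        i: [(i, seqs[i])] for i in range(n)
    }
    next_id = n
    while len(clusters) > 1:
        (ci, cj), _ = min(
            cdist.items(), key=lambda kv: (kv[1], kv[0])
        )
        merged = _merge_profiles(
            profiles[ci], profiles[cj], matrix_name, gap_open, gap_extend
        )
        members = clusters[ci] + clusters[cj]
        for k in (ci, cj):
            del clusters[k]
            del profiles[k]
        cdist = {key: v for key, v in cdist.items() if ci not in key and cj not in key}
        for other in list(clusters):
            d = sum(dist[x][y] for x in members for y in clusters[other]) / (
                len(members) * len(clusters[other])
            )
            cdist[(min(other, next_id), max(other, next_id))] = d
        clusters[next_id] = members
        profiles[next_id] = merged
        next_id += 1
    final = profiles[next_id - 1]
    by_index = dict(final)
    return Msa(labels=tuple(ids), rows=tuple(by_index[i] for i in range(n)))


def _merge_profiles(
    pa: list[tuple[int, str]],
    pb: list[tuple[int, str]],
    matrix_name: str,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[int, str]]:
    """Align two profiles (lists of (index, gapped row)) column-wise."""
    mat = _matrix(matrix_name)
    rows_a = [r for _, r in pa]
    rows_b = [r for _, r in pb]
    na, nb = len(rows_a[0]), len(rows_b[0])
    gap_col = -(gap_open + gap_extend)

    def col(rows: list[str], k: int) -> list[str]:
        return [r[k] for r in rows]

    def col_score(ca: list[str], cb: list[str]) -> float:
        total = 0.0
        cnt = 0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    total -= gap_extend
                else:
                    total += float(mat[x, y])
                cnt += 1
        return total / cnt

    # plain NW on profile columns (linear gap cost per inserted column)
    score = [[0.0] * (nb + 1) for _ in range(na + 1)]
    back = [[""] * (nb + 1) for _ in range(na + 1)]
    for i in range(1, na + 1):
        score[i][0] = score[i - 1][0] + gap_col
        back[i][0] = "U"
    for j in range(1, nb + 1):
        score[0][j] = score[0][j - 1] + gap_col
        back[0][j] = "L"
    cols_a = [col(rows_a, k) for k in range(na)]
    cols_b = [col(rows_b, k) for k in range(nb)]
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = score[i - 1][j - 1] + col_score(cols_a[i - 1], cols_b[j - 1])
            up = score[i - 1][j] + gap_col
            left = score[i][j - 1] + gap_col
            best, direction = diag, "D"
            if up > best:
                best, direction = up, "U"
            if left > best:
                best, direction = left, "L"
            score[i][j] = best
            back[i][j] = direction
    # traceback
    i, j = na, nb
    ops: list[str] = []
    while i > 0 or j > 0:
        d = back[i][j]
        ops.append(d)
        if d == "D":
            i -= 1
            j -= 1
        elif d == "U":
            i -= 1
        else:
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for d in ops:
        if d in ("D", "U"):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if d in ("D", "L"):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return [(idx, row) for (idx, _), row in zip(pa, out_a)] + [
        (idx, row) for (idx, _), row in zip(pb, out_b)
    ]


def write_aligned_fasta(msa: Msa, path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        for label, row in zip(msa.labels, msa.rows):
            fh.write(f">{label}\n{row}\n")
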