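"""Ranged-gap cysteine-signature scanning and domain-architecture annotation.

Antistasin-like domains are defined not by overall sequence similarity but by
a conserved *cysteine skeleton*: nine cysteines whose inter-cysteine spacings
fall in narrow ranges. This module implements

* a PROSITE-style mini-language for such signatures
  (``C-x(4)-C-x(5)-C-x(4,6)-...``),
* exhaustive enumeration of complete signature matches by backtracking over
  cysteine positions,
* deterministic selection of a maximum-cardinality non-overlapping domain
  architecture (interval-scheduling dynamic programming),
* detection of *disrupted* domains — regions matching only an N-terminal
  prefix of the skeleton before diverging,
* detection of the C-terminal motif (CTM): a C-X2-C pair followed by a
  downstream proline,
* GFF3 output of the resulting annotation.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .seq_core import SequenceRecord


class SignatureParseError(ValueError):
    """Raised for malformed signature pattern strings."""


@dataclass(frozen=True)
class CysteineSignature:
    """Ordered ranged-gap constraints between consecutive skeleton cysteines.

    ``gaps[k] = (lo, hi)`` constrains the number of residues between skeleton
    cysteine ``k`` and ``k+1`` (inclusive range); ``trailing_gap`` constrains
    the residues consumed after the final cysteine. The number of skeleton
    cysteines is ``len(gaps) + 1``.
    """

    gaps: tuple[tuple[int, int], ...]
    trailing_gap: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if len(self.gaps) < 1:
            raise SignatureParseError("signature needs at least 2 cysteines")
        for lo, hi in (*self.gaps, self.trailing_gap):
            if lo < 0 or lo > hi:
                raise SignatureParseError(f"invalid gap range ({lo},{hi})")

    @property
    def n_cys(self) -> int:
        return len(self.gaps) + 1

    @property
    def min_span(self) -> int:
        """Length of the shortest sequence matching the full signature."""
        return self.n_cys + sum(lo for lo, _ in self.gaps) + self.trailing_gap[0]

    def prefix(self, n_cys: int) -> "CysteineSignature":
        """Signature restricted to its first ``n_cys`` skeleton cysteines."""
        if not 2 <= n_cys <= self.n_cys:
            raise ValueError(f"prefix length {n_cys} out of range")
        return CysteineSignature(gaps=self.gaps[: n_cys - 1], trailing_gap=(0, 0))

    def to_spec(self) -> str:
        """Canonical pattern-string form (round-trips through the parser)."""
        def fmt(lo: int, hi: int) -> str:
            return f"x({lo})" if lo == hi else f"x({lo},{hi})"

        parts: list[str] = []
        for lo, hi in self.gaps:
            parts.append("C")
            parts.append(fmt(lo, hi))
        parts.append("C")
        parts.append(fmt(*self.trailing_gap))
        return "-".join(parts)


#: The antistasin-like domain signature: 9 skeleton cysteines,
#: C-x(4)-C-x(5)-C-x(4,6)-C-x(1)-C-x(4,5)-C-x(3,4)-C-x(9,10)-C-x(2,3)-C-x(1)
DEFAULT_SIGNATURE = CysteineSignature(
    gaps=((4, 4), (5, 5), (4, 6), (1, 1), (4, 5), (3, 4), (9, 10), (2, 3)),
    trailing_gap=(1, 1),
)

_TOKEN_RE = re.compile(r"C|x\((\d+)(?:,(\d+))?\)", re.IGNORECASE)


def parse_signature(spec: str) -> CysteineSignature:
    """Parse the ``C-x(a[,b])-C-...`` mini-language (case-insensitive).

    A single number means a fixed gap. The final ``x(...)`` is the trailing
    gap; if the spec ends on ``C`` the trailing gap is ``(0,0)``.
    """
    tokens: list[tuple[str, tuple[int, int] | None, int]] = []
    for offset, raw in _tokenize(spec):
        m = _TOKEN_RE.fullmatch(raw)
        if m is None:
            raise SignatureParseError(f"malformed token {raw!r} at offset {offset}")
        if raw.upper() == "C":
            tokens.append(("C", None, offset))
        else:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if lo > hi:
                raise SignatureParseError(
                    f"gap range ({lo},{hi}) has min>max at offset {offset}"
                )
            tokens.append(("x", (lo, hi), offset))

    gaps: list[tuple[int, int]] = []
    trailing = (0, 0)
    pending_gap: tuple[int, int] | None = None
    n_cys = 0
    for kind, rng, offset in tokens:
        if kind == "C":
            if n_cys > 0:
                if pending_gap is None:
                    raise SignatureParseError(
                        f"consecutive 'C' tokens without a gap at offset {offset}"
                    )
                gaps.append(pending_gap)
                pending_gap = None
            n_cys += 1
        else:
            if n_cys == 0:
                raise SignatureParseError(f"pattern must start with 'C' (offset {offset})")
            if pending_gap is not None:
                raise SignatureParseError(f"two consecutive gap tokens at offset {offset}")
            pending_gap = rng  # type: ignore[assignment]
    if n_cys < 2:
        raise SignatureParseError("signature needs at least 2 'C' positions")
    if pending_gap is not None:
        trailing = pending_gap
    return CysteineSignature(gaps=tuple(gaps), trailing_gap=trailing)


def _tokenize(spec: str) -> Iterable[tuple[int, str]]:
    offset = 0
    for raw in spec.split("-"):
        stripped = raw.strip()
        if stripped:
            yield offset, stripped
        offset += len(raw) + 1


@dataclass(frozen=True)
class DomainMatch:
    """One located (possibly partial) signature match."""

    seq_id: str
    start: int
    end: int
    cys_positions: tuple[int, ...]
    complete: bool
    prefix_len: int

    def overlaps(self, other: "DomainMatch") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class CtmAnnotation:
    """C-terminal motif call: C-X2-C pair plus a downstream proline."""

    present: bool
    cxxc_start: int = -1
    proline_pos: int = -1


@dataclass(frozen=True)
class DomainArchitecture:
    """The selected annotation of one protein."""

    seq_id: str
    domains: tuple[DomainMatch, ...]
    ctm: CtmAnnotation = CtmAnnotation(present=False)

    @property
    def complete_domains(self) -> tuple[DomainMatch, ...]:
        return tuple(d for d in self.domains if d.complete)

    @property
    def partial_domains(self) -> tuple[DomainMatch, ...]:
        return tuple(d for d in self.domains if not d.complete)

    @property
    def linkers(self) -> tuple[tuple[int, int], ...]:
        """Inter-domain intervals implied by the sorted domain list."""
        doms = sorted(self.domains, key=lambda d: d.start)
        out = []
        for a, b in zip(doms, doms[1:]):
            if a.end < b.start:
                out.append((a.end, b.start))
        return tuple(out)


def enumerate_matches(
    rec: SequenceRecord,
    sig: CysteineSignature = DEFAULT_SIGNATURE,
    allow_cys_in_spacer: bool = False,
) -> list[DomainMatch]:
    """Enumerate ALL complete signature matches (they may overlap).

    Every skeleton position anchors on a literal ``C``; spacer intervals
    between consecutive skeleton cysteines contain no ``C`` unless
    ``allow_cys_in_spacer``. At least ``trailing_gap[0]`` residues must
    follow the last cysteine; the match end consumes exactly that many.
    Matches are returned in lexicographic order of ``cys_positions`` (the
    natural order of a left-to-right depth-first search).
    """
    seq = rec.residues
    out: list[DomainMatch] = []
    for chain in _search_chains(seq, sig, allow_cys_in_spacer, complete_only=True):
        last = chain[-1]
        out.append(
            DomainMatch(
                seq_id=rec.id,
                start=chain[0],
                end=last + 1 + sig.trailing_gap[0],
                cys_positions=tuple(chain),
                complete=True,
                prefix_len=sig.n_cys,
            )
        )
    return out


def _search_chains(
    seq: str,
    sig: CysteineSignature,
    allow_cys_in_spacer: bool,
    complete_only: bool,
) -> Iterable[list[int]]:
    """Depth-first search over skeleton-cysteine position chains.

    Yields complete chains (length ``sig.n_cys``) when ``complete_only``;
    otherwise yields *maximal dead-end* chains (extendable by no next
    cysteine) of any length < ``sig.n_cys``, for partial-domain detection.
    """
    n = len(seq)
    chain: list[int] = []

    def extend(level: int, pos: int):
        # chain currently ends with cysteine at `pos`, holding level+1 cys
        if level + 1 == sig.n_cys:
            if n - pos - 1 >= sig.trailing_gap[0]:
                yield list(chain)
            elif not complete_only:
                # complete skeleton but no room for the trailing gap: for
                # partial reporting this still counts as a dead end below
                # full completion
                yield list(chain)
            return
        lo, hi = sig.gaps[level]
        extended = False
        for gap in range(lo, hi + 1):
            nxt = pos + gap + 1
            if nxt >= n or seq[nxt] != "C":
                continue
            if not allow_cys_in_spacer and "C" in seq[pos + 1 : nxt]:
                continue
            extended = True
            chain.append(nxt)
            yield from extend(level + 1, nxt)
            chain.pop()
        if not extended and not complete_only:
            yield list(chain)

    for start in range(n):
        if seq[start] != "C":
            continue
        chain.append(start)
        yield from extend(0, start)
        chain.pop()


def select_architecture(matches: Sequence[DomainMatch]) -> list[DomainMatch]:
    """Select a maximum-cardinality set of pairwise non-overlapping matches.

    Among maximum sets, the lexicographically leftmost by the sequence of
    ``(start, end)`` pairs is chosen. Interval-scheduling DP; deterministic.
    """
    if not matches:
        return []
    ids = {m.seq_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"matches from mixed sequences: {sorted(ids)}")
    return _select_intervals(matches, weight=lambda m: 1)


def _select_intervals(matches: Sequence[DomainMatch], weight) -> list[DomainMatch]:
    """Max-total-weight non-overlapping subset; leftmost (start, end) tie-break."""
    ms = sorted(matches, key=lambda m: (m.start, m.end, m.cys_positions))
    n = len(ms)
    # next index whose start >= end of i
    starts = [m.start for m in ms]
    nxt = [bisect.bisect_left(starts, ms[i].end) for i in range(n)]

    @lru_cache(maxsize=None)
    def best(i: int) -> tuple[int, tuple[tuple[int, int], ...]]:
        """(total weight, chosen (start,end) key sequence) for ms[i:].

        Key sequences compare so that larger weight wins; among equal
        weights the lexicographically smaller key sequence wins.
        """
        if i >= n:
            return (0, ())
        skip = best(i + 1)
        w_take, keys_take = best(nxt[i])
        take = (w_take + weight(ms[i]), ((ms[i].start, ms[i].end),) + keys_take)
        if take[0] > skip[0]:
            return take
        if skip[0] > take[0]:
            return skip
        return take if take[1] <= skip[1] else skip

    _, chosen_keys = best(0)
    best.cache_clear()
    # map keys back to matches (first match with each key, in order)
    out: list[DomainMatch] = []
    it = iter(ms)
    for key in chosen_keys:
        for m in it:
            if (m.start, m.end) == key:
                out.append(m)
                break
    return out


def find_partial_matches(
    rec: SequenceRecord,
    sig: CysteineSignature = DEFAULT_SIGNATURE,
    min_prefix: int = 4,
    mask: Sequence[tuple[int, int]] = (),
    allow_cys_in_spacer: bool = False,
) -> list[DomainMatch]:
    """Find maximal prefix matches (disrupted domains) outside ``mask``.

    A partial match anchors at least ``min_prefix`` skeleton cysteines with
    correct spacings but cannot be extended to a complete match. Partials
    intersecting any masked interval (the complete domains) are dropped;
    overlaps among the survivors are resolved by the same DP as complete
    domains, preferring larger total prefix length, then leftmost.
    """
    if not 2 <= min_prefix <= sig.n_cys - 1:
        raise ValueError(f"min_prefix must be in [2, {sig.n_cys - 1}]")
    seq = rec.residues
    candidates: list[DomainMatch] = []
    for chain in _search_chains(seq, sig, allow_cys_in_spacer, complete_only=False):
        if not min_prefix <= len(chain) < sig.n_cys:
            continue
        m = DomainMatch(
            seq_id=rec.id,
            start=chain[0],
            end=chain[-1] + 1,
            cys_positions=tuple(chain),
            complete=False,
            prefix_len=len(chain),
        )
        if any(m.start < hi and lo < m.end for lo, hi in mask):
            continue
        candidates.append(m)
    # drop prefixes strictly contained in a longer candidate with the same start
    maximal = [
        m
        for m in candidates
        if not any(
            o is not m
            and o.cys_positions[: len(m.cys_positions)] == m.cys_positions
            and o.prefix_len > m.prefix_len
            for o in candidates
        )
    ]
    return _select_intervals(maximal, weight=lambda m: m.prefix_len)


def detect_ctm(
    rec: SequenceRecord,
    domains: Sequence[DomainMatch] = (),
    window: int = 20,
    search_start_policy: str = "after_last_complete",
) -> CtmAnnotation:
    """Detect the C-terminal motif: C-X2-C then a proline within ``window``.

    The scan starts at the end of the last complete domain (or position 0 if
    there is none, or always 0 under ``search_start_policy="whole_sequence"``)
    and reports the first C-X2-C occurrence that has a proline at distance
    1..window after its second cysteine.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if search_start_policy not in ("after_last_complete", "whole_sequence"):
        raise ValueError(f"unknown search_start_policy {search_start_policy!r}")
    seq = rec.residues
    start = 0
    if search_start_policy == "after_last_complete":
        complete = [d for d in domains if d.complete]
        if complete:
            start = max(d.end for d in complete)
    for i in range(start, len(seq) - 3):
        if (
            seq[i] == "C"
            and seq[i + 3] == "C"
            and "C" not in seq[i + 1 : i + 3]
        ):
            tail = seq[i + 4 : i + 4 + window]
            p = tail.find("P")
            if p >= 0:
                return CtmAnnotation(present=True, cxxc_start=i, proline_pos=i + 4 + p)
    return CtmAnnotation(present=False)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner options with the package defaults."""

    allow_cys_in_spacer: bool = False
    min_prefix: int = 4
    ctm_window: int = 20
    find_partials: bool = True
    detect_ctm: bool = True
    ctm_search_start_policy: str = "after_last_complete"


def annotate(
    rec: SequenceRecord,
    sig: CysteineSignature = DEFAULT_SIGNATURE,
    config: ScanConfig = ScanConfig(),
) -> DomainArchitecture:
    """Full annotation: enumerate → select → partials → CTM."""
    matches = enumerate_matches(rec, sig, config.allow_cys_in_spacer)
    complete = select_architecture(matches)
    partials: list[DomainMatch] = []
    if config.find_partials:
        partials = find_partial_matches(
            rec,
            sig,
            min_prefix=config.min_prefix,
            mask=[(m.start, m.end) for m in complete],
            allow_cys_in_spacer=config.allow_cys_in_spacer,
        )
    ctm = CtmAnnotation(present=False)
    if config.detect_ctm:
        ctm = detect_ctm(
            rec, complete, window=config.ctm_window,
            search_start_policy=config.ctm_search_start_policy,
        )
    domains = tuple(sorted(complete + partials, key=lambda d: (d.start, d.end)))
    return DomainArchitecture(seq_id=rec.id, domains=domains, ctm=ctm)


# ---------------------------------------------------------------------------
# GFF3 output (1-based inclusive coordinates)

GFF_DOMAIN_TYPE = "antistasin_like_domain"
GFF_CTM_TYPE = "c_terminal_motif"


def write_gff3(architectures: Iterable[DomainArchitecture], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for arch in architectures:
            for d in sorted(arch.domains, key=lambda d: (d.start, d.end)):
                attrs = (
                    f"complete={'true' if d.complete else 'false'};"
                    f"prefix_len={d.prefix_len};"
                    f"cys_positions={','.join(str(p + 1) for p in d.cys_positions)}"
                )
                fh.write(
                    f"{arch.seq_id}\tcysdom\t{GFF_DOMAIN_TYPE}\t{d.start + 1}\t{d.end}\t"
                    f".\t.\t.\t{attrs}\n"
                )
            if arch.ctm.present:
                fh.write(
                    f"{arch.seq_id}\tcysdom\t{GFF_CTM_TYPE}\t{arch.ctm.cxxc_start + 1}\t"
                    f"{arch.ctm.proline_pos + 1}\t.\t.\t.\t"
                    f"cxxc_start={arch.ctm.cxxc_start + 1};proline={arch.ctm.proline_pos + 1}\n"
                )


def read_gff3(path: str | Path) -> dict[str, DomainArchitecture]:
    """Re-read a scanner GFF3 file into architectures (round-trip helper)."""
    archs: dict[str, dict] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seqid, _src, ftype, start, end, _score, _strand, _phase, attrs = line.split("\t")
            rec = archs.setdefault(seqid, {"domains": [], "ctm": CtmAnnotation(False)})
            kv = dict(item.split("=", 1) for item in attrs.split(";") if item)
            if ftype == GFF_DOMAIN_TYPE:
                cys = tuple(int(x) - 1 for x in kv["cys_positions"].split(","))
                rec["domains"].append(
                    DomainMatch(
                        seq_id=seqid,
                        start=int(start) - 1,
                        end=int(end),
                        cys_positions=cys,
                        complete=kv["complete"] == "true",
                        prefix_len=int(kv["prefix_len"]),
                    )
                )
            elif ftype == GFF_CTM_TYPE:
                rec["ctm"] = CtmAnnotation(
                    present=True,
                    cxxc_start=int(kv["cxxc_start"]) - 1,
                    proline_pos=int(kv["proline"]) - 1,
                )
    return {
        seqid: DomainArchitecture(
            seq_id=seqid, domains=tuple(d["domains"]), ctm=d["ctm"]
        )
        for seqid, d in archs.items()
    }
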