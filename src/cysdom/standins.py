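"""Synthetic stand-ins for the MCRA / CRA / antistasin reference proteins.

The real proteins live in public sequence databases; this module constructs
*synthetic* surrogates so the whole pipeline can be exercised and checked
offline. Each stand-in is built deterministically to match every property
of its reference that the analysis depends on:

``MCRA_STANDIN``
    242 residues, 41 cysteines (~17%), three complete antistasin-like
    domains, one disrupted domain in the DII position (skeleton conserved
    through the 5th cysteine, divergent tail), a C-terminal motif, and
    4 Trp / 9 Tyr (mass ≈ 28 kDa; molar extinction ≈ 36,700 M⁻¹cm⁻¹ with
    all cysteines paired).

``CRA_STANDIN``
    139 residues, 22 cysteines (~16%), two complete domains, a C-terminal
    motif, 2 Trp / 5 Tyr (molar extinction ≈ 19,100 M⁻¹cm⁻¹).

``ANS_STANDIN``
    Two complete domains, no C-terminal motif (antistasin lacks it).

Domain copies are derived from one ancestral domain by fixed substitution
sets encoding the duplication history: an early duplication producing the
two-domain form, then a second duplication producing the four-domain
protein. The complete CRA+MCRA domains therefore group as
{MCRA.D1, MCRA.D3, CRA.D1} versus {MCRA.D4, CRA.D2} in a distance tree.

These are synthetic sequences: they reproduce architecture and summary
statistics, not the residue-level identity of the real proteins.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .seq_core import SequenceRecord
from .signature import DEFAULT_SIGNATURE

#: Residues drawn for spacers: no Cys (skeleton stays unambiguous), no
#: Trp/Tyr (aromatics are placed explicitly so extinction is controlled).
_DRAW = "ADEFGHIKLMNPQRSTV"

_SEED = 20260915

#: Fixed (minimal-plus) gap realization of the 9-cysteine signature:
#: gaps 4,5,4,1,4,3,9,2 and one trailing residue -> 42-residue domain with
#: cysteines at 0,5,11,16,18,23,27,37,40.
_GAPS = (4, 5, 4, 1, 4, 3, 9, 2)
DOMAIN_CYS = (0, 5, 11, 16, 18, 23, 27, 37, 40)
DOMAIN_LEN = 42

# aromatic anchor positions (spacer positions after the 5th cysteine, so the
# disrupted-domain prefix carries no aromatics)
_W_POS = 20
_Y_POS = (25, 30)


def _draw(rng: np.random.Generator, k: int, pool: str = _DRAW) -> str:
    letters = list(pool)
    return "".join(letters[int(i)] for i in rng.integers(0, len(letters), k))


def _substitute(seq: str, subs: dict[int, str]) -> str:
    out = list(seq)
    for pos, res in subs.items():
        out[pos] = res
    return "".join(out)


@lru_cache(maxsize=1)
def _domains() -> dict[str, str]:
    """Ancestral domain and its five descendant copies plus two ANS copies."""
    rng = np.random.default_rng(_SEED)
    base = list(_draw(rng, DOMAIN_LEN))
    for c in DOMAIN_CYS:
        base[c] = "C"
    base[_W_POS] = "W"
    for y in _Y_POS:
        base[y] = "Y"
    ancestral = "".join(base)
    assert len(ancestral) == DOMAIN_LEN and ancestral.count("C") == 9

    mutable = [
        i
        for i in range(DOMAIN_LEN)
        if i not in DOMAIN_CYS and i != _W_POS and i not in _Y_POS
    ]
    order = list(rng.permutation(mutable))
    group_a_pos = order[:6]       # shared by CRA.D1, MCRA.D1, MCRA.D3
    group_b_pos = order[6:12]     # shared by CRA.D2, MCRA.D4
    unique_pos = {
        name: order[12 + 2 * i : 14 + 2 * i]
        for i, name in enumerate(["CRA.D1", "CRA.D2", "MCRA.D1", "MCRA.D3", "MCRA.D4"])
    }

    def new_residue(old: str) -> str:
        while True:
            res = _draw(rng, 1)
            if res != old:
                return res

    group_a = {int(p): new_residue(ancestral[p]) for p in group_a_pos}
    group_b = {int(p): new_residue(ancestral[p]) for p in group_b_pos}
    out = {"ancestral": ancestral}
    for name, upos in unique_pos.items():
        shared = group_a if name in ("CRA.D1", "MCRA.D1", "MCRA.D3") else group_b
        subs = dict(shared)
        for p in upos:
            subs[int(p)] = new_residue(ancestral[p])
        out[name] = _substitute(ancestral, subs)
    # distant two-domain relative (antistasin): heavier divergence
    for name in ("ANS.D1", "ANS.D2"):
        subs = {
            int(p): new_residue(ancestral[p])
            for p in rng.permutation(mutable)[:8]
        }
        out[name] = _substitute(ancestral, subs)
    return out


def _disrupted_domain(rng: np.random.Generator) -> str:
    """DII: ancestral skeleton through Cys5, then a divergent 25-residue tail.

    The tail carries five cysteines in a spacing incompatible with the
    signature (so the region scans as a prefix-only partial match), plus one
    Trp and two Tyr.
    """
    prefix = list(_domains()["ancestral"][: DOMAIN_CYS[4] + 1])
    # one private substitution in the conserved prefix
    prefix[3] = "H" if prefix[3] != "H" else "K"
    tail = list(_draw(rng, 25))
    for off in (2, 5, 12, 15, 22):   # local 21,24,31,34,41: gaps 2,6,2,6
        tail[off] = "C"
    tail[7] = "W"
    tail[9] = "Y"
    tail[17] = "Y"
    return "".join(prefix) + "".join(tail)


def _ctm_region(
    rng: np.random.Generator,
    pre: int,
    proline_gap: int,
    tail: int,
    tail_cys: tuple[int, int],
    tail_tyr: int,
) -> str:
    """C-terminal motif region: spacer, C-X2-C, proline, cysteine-pair tail."""
    pre_s = _draw(rng, pre)
    cxxc = "C" + _draw(rng, 2) + "C"
    gap_s = _draw(rng, proline_gap, pool=_DRAW.replace("P", ""))
    tail_l = list(_draw(rng, tail))
    for off in tail_cys:
        tail_l[off] = "C"
    tail_l[tail_tyr] = "Y"
    return pre_s + cxxc + gap_s + "P" + "".join(tail_l)


@lru_cache(maxsize=1)
def reference_standins() -> dict[str, SequenceRecord]:
    """The three synthetic reference proteins, keyed MCRA / CRA / ANS."""
    doms = _domains()
    rng = np.random.default_rng(_SEED + 1)
    linker = lambda: _draw(rng, 8)

    mcra = (
        doms["MCRA.D1"]
        + linker()
        + _disrupted_domain(rng)
        + linker()
        + doms["MCRA.D3"]
        + linker()
        + doms["MCRA.D4"]
        + _ctm_region(rng, pre=10, proline_gap=6, tail=27, tail_cys=(5, 10), tail_tyr=15)
    )
    cra = (
        doms["CRA.D1"]
        + linker()
        + doms["CRA.D2"]
        + _ctm_region(rng, pre=9, proline_gap=7, tail=26, tail_cys=(5, 10), tail_tyr=14)
    )
    ans = _draw(rng, 3) + doms["ANS.D1"] + linker() + doms["ANS.D2"] + _draw(rng, 5)

    records = {
        "MCRA": SequenceRecord(
            id="MCRA",
            residues=mcra,
            description="synthetic stand-in, four-domain cysteine-rich anticoagulant",
        ),
        "CRA": SequenceRecord(
            id="CRA",
            residues=cra,
            description="synthetic stand-in, two-domain cysteine-rich anticoagulant",
        ),
        "ANS": SequenceRecord(
            id="ANS",
            residues=ans,
            description="synthetic stand-in, antistasin (two domains, no CTM)",
        ),
    }
    assert len(records["MCRA"]) == 242 and records["MCRA"].residues.count("C") == 41
    assert len(records["CRA"]) == 139 and records["CRA"].residues.count("C") == 22
    return records
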