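"""Synthetic multi-domain cysteine-rich protein families with known truth.

The generator emulates the architecture of antistasin-like anticoagulants:
an N-terminal signal peptide, tandem 9-cysteine domains sampled from the
ranged-gap signature, inter-domain linkers, optionally one *disrupted*
domain (conserved skeleton prefix, divergent cysteine-free tail), and a
C-terminal motif (C-X2-C plus a downstream proline). Domains descend from a
single ancestral domain along a known duplication tree under the JTT
substitution process, with skeleton cysteines held fixed and no cysteines
introduced into spacers — so the signature scanner's ground truth is exact
by construction.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .jtt import AA_INDEX, transition_matrix
from .jtt_data import AA_ORDER
from .phylo import PhyloTree, TreeNode, parse_newick, to_newick
from .seq_core import SequenceRecord
from .signature import (
    DEFAULT_SIGNATURE,
    CtmAnnotation,
    CysteineSignature,
    DomainArchitecture,
    DomainMatch,
)

#: Spacer residues: all amino acids except cysteine.
SPACER_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated protein family.

    ``domains_per_protein[i]`` is the number of domain slots of protein
    ``P{i+1}``; ``disrupted_domain_index[i]`` (0-based, or None) marks which
    of those slots is disrupted. ``duplication_tree`` is a Newick string
    whose leaves are the domain slot labels ``P{i}.D{k}``; if omitted, a
    pectinate default over all slots is used. ``branch_time`` (substitutions
    per site) applies to every branch unless None, in which case the Newick
    branch lengths are used.
    """

    seed: int = 0
    domains_per_protein: tuple[int, ...] = (2, 4)
    disrupted_domain_index: tuple[Optional[int], ...] = (None, 1)
    linker_length: tuple[int, int] = (5, 25)
    signal_peptide_length: int = 20
    ctm: bool | tuple[bool, ...] = True
    duplication_tree: Optional[str] = None
    branch_time: Optional[float] = 0.2
    preserve_skeleton_cys: bool = True
    disrupted_prefix_cys: int = 5
    ctm_proline_gap: tuple[int, int] = (2, 10)
    ctm_tail_length: tuple[int, int] = (3, 8)
    spacer_alphabet: str = SPACER_ALPHABET
    signature: CysteineSignature = DEFAULT_SIGNATURE

    @property
    def n_proteins(self) -> int:
        return len(self.domains_per_protein)

    def protein_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_proteins)]

    def slot_labels(self) -> list[str]:
        return [
            f"P{i + 1}.D{k + 1}"
            for i, nd in enumerate(self.domains_per_protein)
            for k in range(nd)
        ]

    def ctm_flags(self) -> tuple[bool, ...]:
        if isinstance(self.ctm, bool):
            return tuple([self.ctm] * self.n_proteins)
        return tuple(self.ctm)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "domains_per_protein": list(self.domains_per_protein),
            "disrupted_domain_index": list(self.disrupted_domain_index),
            "linker_length": list(self.linker_length),
            "signal_peptide_length": self.signal_peptide_length,
            "ctm": list(self.ctm_flags()),
            "duplication_tree": self.duplication_tree,
            "branch_time": self.branch_time,
            "preserve_skeleton_cys": self.preserve_skeleton_cys,
            "disrupted_prefix_cys": self.disrupted_prefix_cys,
            "ctm_proline_gap": list(self.ctm_proline_gap),
            "ctm_tail_length": list(self.ctm_tail_length),
            "spacer_alphabet": self.spacer_alphabet,
            "signature": self.signature.to_spec(),
        }


@dataclass(frozen=True)
class SyntheticFamily:
    """Generated records plus exact ground truth."""

    records: tuple[SequenceRecord, ...]
    truth_architectures: dict[str, DomainArchitecture]
    true_tree: PhyloTree
    provenance: SimulationConfig


def default_duplication_tree(labels: Sequence[str]) -> str:
    """A pectinate (caterpillar) Newick topology over the given labels."""
    if len(labels) < 2:
        raise ValueError("need at least 2 domain slots")
    tree = labels[0]
    for lab in labels[1:]:
        tree = f"({tree},{lab})"
    return tree + ";"


def sample_domain(
    sig: CysteineSignature,
    rng: np.random.Generator,
    spacer_alphabet: str = SPACER_ALPHABET,
) -> tuple[str, tuple[int, ...]]:
    """Sample a string matching ``sig`` exactly; returns (seq, cys positions).

    Skeleton positions are 'C'; each gap length is uniform over its range;
    spacer and trailing residues are uniform over ``spacer_alphabet``.
    """
    if "C" in spacer_alphabet:
        raise ValueError("spacer alphabet must not contain 'C'")
    letters = list(spacer_alphabet)

    def spacer(k: int) -> str:
        return "".join(rng.choice(letters) for _ in range(k))

    parts = ["C"]
    positions = [0]
    pos = 0
    for lo, hi in sig.gaps:
        gap = int(rng.integers(lo, hi + 1))
        parts.append(spacer(gap))
        parts.append("C")
        pos += gap + 1
        positions.append(pos)
    lo, hi = sig.trailing_gap
    parts.append(spacer(int(rng.integers(lo, hi + 1))))
    return "".join(parts), tuple(positions)


def evolve_sequence(
    seq: str,
    t: float,
    rng: np.random.Generator,
    preserve_positions: Sequence[int] = (),
    forbid_new_cys: bool = True,
) -> str:
    """Evolve ``seq`` for time ``t`` under the JTT process.

    Residues at ``preserve_positions`` are held fixed. When
    ``forbid_new_cys``, substitutions into 'C' at unpreserved sites are
    redrawn from the conditional distribution excluding 'C' (keeping the
    cysteine skeleton unambiguous).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return seq
    P = transition_matrix(t)
    preserve = set(preserve_positions)
    c_idx = AA_INDEX["C"]
    out = []
    for pos, res in enumerate(seq):
        if pos in preserve or res not in AA_INDEX:
            out.append(res)
            continue
        row = P[AA_INDEX[res]]
        new = int(rng.choice(20, p=row))
        if forbid_new_cys and new == c_idx and res != "C":
            cond = row.copy()
            cond[c_idx] = 0.0
            cond /= cond.sum()
            new = int(rng.choice(20, p=cond))
        out.append(AA_ORDER[new])
    return "".join(out)


def _evolve_down_tree(
    tree: PhyloTree,
    ancestral: str,
    rng: np.random.Generator,
    branch_time: Optional[float],
    preserve_positions: Sequence[int],
) -> dict[str, str]:
    """Evolve the ancestral domain along the tree; returns leaf sequences."""
    leaves: dict[str, str] = {}

    def walk(node: TreeNode, seq: str) -> None:
        if node.is_leaf:
            leaves[node.label] = seq
            return
        for child, bl in node.children:
            t = branch_time if branch_time is not None else bl
            walk(child, evolve_sequence(seq, t, rng, preserve_positions))

    walk(tree.root, ancestral)
    return leaves


def simulate_family(config: SimulationConfig) -> SyntheticFamily:
    """Simulate one protein family; fully deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    sig = config.signature
    letters = list(config.spacer_alphabet)
    no_p_letters = [l for l in letters if l != "P"]

    def spacer(k: int, allow_p: bool = True) -> str:
        pool = letters if allow_p else no_p_letters
        return "".join(rng.choice(pool) for _ in range(k))

    labels = config.slot_labels()
    newick = config.duplication_tree or default_duplication_tree(labels)
    tree = parse_newick(newick)
    if tree.leaf_labels != frozenset(labels):
        raise ValueError(
            f"duplication tree leaves {sorted(tree.leaf_labels)} do not match "
            f"domain slots {labels}"
        )

    ancestral, cys_positions = sample_domain(sig, rng, config.spacer_alphabet)
    domain_seqs = _evolve_down_tree(
        tree,
        ancestral,
        rng,
        config.branch_time,
        cys_positions if config.preserve_skeleton_cys else (),
    )
    dom_len = len(ancestral)

    if not 2 <= config.disrupted_prefix_cys < sig.n_cys:
        raise ValueError("disrupted_prefix_cys out of range")

    records: list[SequenceRecord] = []
    truths: dict[str, DomainArchitecture] = {}
    ctm_flags = config.ctm_flags()
    if len(ctm_flags) != config.n_proteins:
        raise ValueError("ctm flag list does not match protein count")
    if len(config.disrupted_domain_index) != config.n_proteins:
        raise ValueError("disrupted_domain_index does not match protein count")

    for p_idx, (pid, nd) in enumerate(zip(config.protein_ids(), config.domains_per_protein)):
        parts: list[str] = [spacer(config.signal_peptide_length)]
        offset = config.signal_peptide_length
        domains: list[DomainMatch] = []
        disrupted = config.disrupted_domain_index[p_idx]
        for k in range(nd):
            label = f"{pid}.D{k + 1}"
            seq = domain_seqs[label]
            if k == disrupted:
                keep = cys_positions[config.disrupted_prefix_cys - 1] + 1
                seq = seq[:keep] + spacer(dom_len - keep)
                prefix_cys = cys_positions[: config.disrupted_prefix_cys]
                domains.append(
                    DomainMatch(
                        seq_id=pid,
                        start=offset,
                        end=offset + keep,
                        cys_positions=tuple(offset + c for c in prefix_cys),
                        complete=False,
                        prefix_len=config.disrupted_prefix_cys,
                    )
                )
            else:
                domains.append(
                    DomainMatch(
                        seq_id=pid,
                        start=offset,
                        end=offset + cys_positions[-1] + 1 + sig.trailing_gap[0],
                        cys_positions=tuple(offset + c for c in cys_positions),
                        complete=True,
                        prefix_len=sig.n_cys,
                    )
                )
            parts.append(seq)
            offset += dom_len
            if k < nd - 1:
                linker = int(rng.integers(config.linker_length[0], config.linker_length[1] + 1))
                parts.append(spacer(linker))
                offset += linker

        ctm = CtmAnnotation(present=False)
        if ctm_flags[p_idx]:
            pre = int(rng.integers(config.linker_length[0], config.linker_length[1] + 1))
            gap_p = int(rng.integers(config.ctm_proline_gap[0], config.ctm_proline_gap[1] + 1))
            tail = int(rng.integers(config.ctm_tail_length[0], config.ctm_tail_length[1] + 1))
            parts.append(spacer(pre, allow_p=True))
            offset += pre
            cxxc_start = offset
            parts.append("C" + spacer(2) + "C")
            offset += 4
            parts.append(spacer(gap_p, allow_p=False))
            offset += gap_p
            parts.append("P")
            proline_pos = offset
            offset += 1
            parts.append(spacer(tail))
            offset += tail
            ctm = CtmAnnotation(present=True, cxxc_start=cxxc_start, proline_pos=proline_pos)

        residues = "".join(parts)
        records.append(
            SequenceRecord(id=pid, residues=residues, description="synthetic family member")
        )
        truths[pid] = DomainArchitecture(seq_id=pid, domains=tuple(domains), ctm=ctm)

    return SyntheticFamily(
        records=tuple(records),
        truth_architectures=truths,
        true_tree=tree,
        provenance=config,
    )


def write_truth(family: SyntheticFamily, path: str | Path) -> None:
    """Write ground truth as JSON (0-based half-open intervals)."""
    payload = {
        "records": [
            {
                "id": rec.id,
                "length": len(rec),
                "domains": [
                    {
                        "start": d.start,
                        "end": d.end,
                        "complete": d.complete,
                        "prefix_len": d.prefix_len,
                        "cys_positions": list(d.cys_positions),
                    }
                    for d in family.truth_architectures[rec.id].domains
                ],
                "ctm": {
                    "present": family.truth_architectures[rec.id].ctm.present,
                    "cxxc_start": family.truth_architectures[rec.id].ctm.cxxc_start,
                    "proline_pos": family.truth_architectures[rec.id].ctm.proline_pos,
                },
            }
            for rec in family.records
        ],
        "true_tree": to_newick(family.true_tree),
        "config": family.provenance.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def truth_matches_architecture(
    truth: DomainArchitecture, observed: DomainArchitecture
) -> bool:
    """Exact agreement of domain intervals, completeness flags, and CTM."""
    t = [(d.start, d.end, d.complete, d.cys_positions) for d in truth.domains]
    o = [(d.start, d.end, d.complete, d.cys_positions) for d in observed.domains]
    if sorted(t) != sorted(o):
        return False
    if truth.ctm.present != observed.ctm.present:
        return False
    if truth.ctm.present and (
        truth.ctm.cxxc_start != observed.ctm.cxxc_start
        or truth.ctm.proline_pos != observed.ctm.proline_pos
    ):
        return False
    return True
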