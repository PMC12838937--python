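"""Sequence records, FASTA I/O, translation, and protein physicochemical parameters.

The data model is deliberately small: a :class:`SequenceRecord` is an
identified amino-acid (or nucleotide) string, and
:func:`compute_protein_params` derives the quantities routinely reported for
a purified protein — length, cysteine content, average molecular mass, and
the 280 nm extinction coefficient under the two published Trp/Tyr/cystine
coefficient sets (Gill & von Hippel 1989; Pace et al. 1995).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: Trp / Tyr / cystine molar absorption coefficients at 280 nm (M^-1 cm^-1).
EXTINCTION_CONVENTIONS = {
    "pace": (5500.0, 1490.0, 125.0),
    "gill-von-hippel": (5690.0, 1280.0, 120.0),
}

WATER_MASS_DA = 18.02


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence.

    Residues are uppercase; proteins use the 20 one-letter codes plus ``X``,
    nucleotide records use ``ACGTN``.
    """

    id: str
    residues: str
    description: str = ""
    is_nucleotide: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise SequenceError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = NUCLEOTIDE_ALPHABET if self.is_nucleotide else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                kind = "nucleotide" if self.is_nucleotide else "protein"
                raise SequenceError(
                    f"record {self.id!r}: illegal {kind} residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinParams:
    """Physicochemical parameters of one protein sequence."""

    length: int
    cys_count: int
    cys_fraction: float
    mol_weight_da: float
    eps_molar: float
    eps_mass: float
    convention: str
    cystine_mode: str

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "cys_count": self.cys_count,
            "cys_fraction": self.cys_fraction,
            "mol_weight_da": self.mol_weight_da,
            "eps_molar": self.eps_molar,
            "eps_mass": self.eps_mass,
            "convention": self.convention,
            "cystine_mode": self.cystine_mode,
        }


def read_fasta(path: str | Path, is_nucleotide: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Line wrapping is removed and residues are uppercased. Raises
    :class:`SequenceError` on an empty file, duplicate ids, or illegal
    residue characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise SequenceError(f"duplicate record id {bio_rec.id!r} in {path}")
        seen.add(bio_rec.id)
        desc = bio_rec.description
        if desc.startswith(bio_rec.id):
            desc = desc[len(bio_rec.id):].strip()
        records.append(
            SequenceRecord(
                id=bio_rec.id,
                residues=str(bio_rec.seq),
                description=desc,
                is_nucleotide=is_nucleotide,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with ``wrap``-column sequence lines."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


_STANDARD_TABLE = 1  # NCBI standard genetic code


def translate_cds(nuc: SequenceRecord, frame: int = 0) -> "SequenceRecord | TranslatedRecord":
    """Translate a nucleotide record in the given frame (0, 1, or 2).

    Stop codons render as ``*``; a trailing partial codon is dropped.
    """
    if not nuc.is_nucleotide:
        raise SequenceError(f"record {nuc.id!r} is not flagged as nucleotide")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, or 2")
    coding = nuc.residues[frame:]
    if len(coding) < 3:
        raise SequenceError(f"record {nuc.id!r}: fewer than one codon in frame {frame}")
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(table=_STANDARD_TABLE))
    if "*" in aa:
        return TranslatedRecord(id=nuc.id, residues=aa, description=nuc.description)
    return SequenceRecord(id=nuc.id, residues=aa, description=nuc.description)


@dataclass(frozen=True)
class TranslatedRecord:
    """A raw translation that may contain stop codons (``*``).

    Stops fall outside the protein alphabet enforced by
    :class:`SequenceRecord`, so translations that include them are carried in
    this thin duck-typed wrapper instead.
    """

    id: str
    residues: str
    description: str = ""
    is_nucleotide: bool = False

    def __len__(self) -> int:
        return len(self.residues)


def compute_protein_params(
    rec: SequenceRecord,
    convention: str = "gill-von-hippel",
    cystine_mode: str = "all-paired",
    allow_x: bool = False,
) -> ProteinParams:
    """Compute length, cysteine content, average mass, and 280 nm extinction.

    ``eps_molar = nW*cW + nY*cY + n_cystine*cC`` where the coefficient triple
    is chosen by ``convention`` and ``n_cystine = floor(nC/2)`` when
    ``cystine_mode == "all-paired"`` (all cysteines disulfide-bonded) or 0 for
    ``"all-reduced"``. ``eps_mass = eps_molar / mol_weight_da`` is in (mg/mL)^-1 cm^-1.

    ``X`` residues are rejected unless ``allow_x``, in which case they
    contribute zero mass and zero absorbance.
    """
    if rec.is_nucleotide:
        raise SequenceError(f"record {rec.id!r} is a nucleotide sequence")
    seq = rec.residues
    if not seq:
        raise SequenceError("empty sequence")
    if convention not in EXTINCTION_CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; choose from {sorted(EXTINCTION_CONVENTIONS)}"
        )
    if cystine_mode not in ("all-paired", "all-reduced"):
        raise ValueError(f"unknown cystine_mode {cystine_mode!r}")
    if "X" in seq:
        if not allow_x:
            raise SequenceError(
                f"record {rec.id!r} contains 'X'; pass allow_x=True to treat it as massless"
            )
        massless = seq.replace("X", "")
        if not massless:
            raise SequenceError(f"record {rec.id!r} is all-'X'")
        weight = _bio_molecular_weight(massless, seq_type="protein")
    else:
        weight = _bio_molecular_weight(seq, seq_type="protein")

    length = len(seq)
    n_cys = seq.count("C")
    c_trp, c_tyr, c_cystine = EXTINCTION_CONVENTIONS[convention]
    n_cystine = n_cys // 2 if cystine_mode == "all-paired" else 0
    eps_molar = seq.count("W") * c_trp + seq.count("Y") * c_tyr + n_cystine * c_cystine
    eps_mass = eps_molar / weight
    return ProteinParams(
        length=length,
        cys_count=n_cys,
        cys_fraction=n_cys / length,
        mol_weight_da=weight,
        eps_molar=eps_molar,
        eps_mass=eps_mass,
        convention=convention,
        cystine_mode=cystine_mode,
    )


def params_table(named_params: Sequence[tuple[str, ProteinParams]]) -> str:
    """Render parameters as a tab-separated table (one row per protein)."""
    cols = [
        "id", "length", "cys_count", "cys_fraction", "mol_weight_da",
        "eps_molar", "eps_mass", "convention", "cystine_mode",
    ]
    lines = ["\t".join(cols)]
    for name, p in named_params:
        lines.append(
            "\t".join(
                [
                    name,
                    str(p.length),
                    str(p.cys_count),
                    f"{p.cys_fraction:.4f}",
                    f"{p.mol_weight_da:.2f}",
                    f"{p.eps_molar:.0f}",
                    f"{p.eps_mass:.4f}",
                    p.convention,
                    p.cystine_mode,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def params_json(named_params: Sequence[tuple[str, ProteinParams]]) -> str:
    return json.dumps({name: p.to_dict() for name, p in named_params}, indent=2)
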