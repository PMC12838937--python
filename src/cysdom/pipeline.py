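"""End-to-end analysis: annotate → extract domains → align → distances → NJ tree.

`run_pipeline` executes the stages in order, writes all artifacts (TSV/JSON
parameter report, GFF3 annotation, per-domain FASTA, aligned FASTA and
Clustal-style text, PHYLIP square distance matrix, Newick tree, JSON
report), and runs a self-consistency validation pass over what it wrote.
Phylogeny is skipped with a logged notice when fewer than three complete
domains exist in total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import seq_core
from .align import Msa, progressive_msa, write_aligned_fasta
from .phylo import (
    DistanceMatrix,
    PhyloTree,
    ascii_tree,
    distance_matrix,
    has_bipartition,
    neighbor_joining,
    to_newick,
)
from .seq_core import ProteinParams, SequenceRecord, compute_protein_params
from .signature import (
    DEFAULT_SIGNATURE,
    CysteineSignature,
    DomainArchitecture,
    ScanConfig,
    annotate,
    parse_signature,
    read_gff3,
    write_gff3,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Options of one pipeline run."""

    signature: CysteineSignature = DEFAULT_SIGNATURE
    scan: ScanConfig = ScanConfig()
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    distance_method: str = "ml"
    include_partials: bool = False
    convention: str = "gill-von-hippel"
    cystine_mode: str = "all-paired"
    bipartition_groups: tuple[frozenset[str], ...] = ()
    outdir: Optional[Path] = None

    @staticmethod
    def from_mapping(data: dict) -> "PipelineConfig":
        """Build a config from a flat key-value mapping (e.g. parsed YAML)."""
        sig = data.get("signature")
        scan = ScanConfig(
            allow_cys_in_spacer=bool(data.get("allow_cys_in_spacer", False)),
            min_prefix=int(data.get("min_prefix", 4)),
            ctm_window=int(data.get("ctm_window", 20)),
        )
        groups = tuple(
            frozenset(g.split(",")) if isinstance(g, str) else frozenset(g)
            for g in data.get("bipartition_groups", [])
        )
        return PipelineConfig(
            signature=parse_signature(sig) if sig else DEFAULT_SIGNATURE,
            scan=scan,
            matrix_name=data.get("matrix_name", "BLOSUM62"),
            gap_open=float(data.get("gap_open", 11.0)),
            gap_extend=float(data.get("gap_extend", 1.0)),
            distance_method=data.get("distance_method", "ml"),
            include_partials=bool(data.get("include_partials", False)),
            convention=data.get("convention", "gill-von-hippel"),
            cystine_mode=data.get("cystine_mode", "all-paired"),
            bipartition_groups=groups,
            outdir=Path(data["outdir"]) if data.get("outdir") else None,
        )


@dataclass
class AnalysisReport:
    """In-memory result of a pipeline run."""

    params: dict[str, ProteinParams]
    architectures: dict[str, DomainArchitecture]
    domain_records: list[SequenceRecord]
    msa: Optional[Msa]
    distances: Optional[DistanceMatrix]
    tree: Optional[PhyloTree]
    bipartition_results: dict[str, bool]
    config: PipelineConfig

    @property
    def newick(self) -> Optional[str]:
        return to_newick(self.tree) if self.tree is not None else None

    def summary_dict(self) -> dict:
        return {
            "sequences": {
                seq_id: {
                    "params": self.params[seq_id].to_dict(),
                    "n_complete_domains": len(arch.complete_domains),
                    "n_partial_domains": len(arch.partial_domains),
                    "ctm_present": arch.ctm.present,
                    "domains": [
                        {
                            "start": d.start,
                            "end": d.end,
                            "complete": d.complete,
                            "prefix_len": d.prefix_len,
                        }
                        for d in arch.domains
                    ],
                    "ctm": {
                        "present": arch.ctm.present,
                        "cxxc_start": arch.ctm.cxxc_start,
                        "proline_pos": arch.ctm.proline_pos,
                    },
                }
                for seq_id, arch in self.architectures.items()
            },
            "domain_ids": [r.id for r in self.domain_records],
            "tree_newick": self.newick,
            "bipartition_results": self.bipartition_results,
        }


def domain_label(seq_id: str, index: int) -> str:
    return f"{seq_id}.D{index}"


def extract_domains(
    rec: SequenceRecord,
    arch: DomainArchitecture,
    include_partials: bool = False,
) -> list[SequenceRecord]:
    """Cut domain subsequences, labelled ``SEQID.D<k>`` by start order.

    Numbering runs over ALL domains (complete and partial) sorted by start,
    so a disrupted second domain keeps the DII name; partial domains are
    only *returned* when ``include_partials``.
    """
    out = []
    for k, d in enumerate(sorted(arch.domains, key=lambda d: (d.start, d.end)), start=1):
        if not d.complete and not include_partials:
            continue
        out.append(
            SequenceRecord(
                id=domain_label(rec.id, k),
                residues=rec.residues[d.start : d.end],
                description=("complete" if d.complete else f"partial prefix_len={d.prefix_len}"),
            )
        )
    return out


def run_pipeline(
    records: Sequence[SequenceRecord],
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the full analysis over protein records; write artifacts if configured."""
    if not records:
        raise PipelineError("input: no sequences provided")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise PipelineError("input: duplicate sequence ids")

    try:
        params = {
            r.id: compute_protein_params(r, config.convention, config.cystine_mode)
            for r in records
        }
    except Exception as exc:
        raise PipelineError(f"protein-parameters stage: {exc}") from exc

    try:
        architectures = {r.id: annotate(r, config.signature, config.scan) for r in records}
    except Exception as exc:
        raise PipelineError(f"signature-scan stage: {exc}") from exc

    domain_records: list[SequenceRecord] = []
    for r in records:
        domain_records.extend(
            extract_domains(r, architectures[r.id], config.include_partials)
        )

    msa = distances = tree = None
    n_for_tree = len(domain_records)
    if n_for_tree >= 3:
        try:
            msa = progressive_msa(
                domain_records, config.matrix_name, config.gap_open, config.gap_extend
            )
            distances = distance_matrix(msa, config.distance_method)
            tree = neighbor_joining(distances)
        except Exception as exc:
            raise PipelineError(f"phylogeny stage: {exc}") from exc
    else:
        logger.info(
            "phylogeny skipped: only %d extracted domain(s), need >= 3", n_for_tree
        )

    bipartition_results: dict[str, bool] = {}
    for group in config.bipartition_groups:
        key = ",".join(sorted(group))
        if tree is None:
            bipartition_results[key] = False
            continue
        try:
            bipartition_results[key] = has_bipartition(tree, group)
        except ValueError as exc:
            raise PipelineError(f"bipartition-test stage: {exc}") from exc

    report = AnalysisReport(
        params=params,
        architectures=architectures,
        domain_records=domain_records,
        msa=msa,
        distances=distances,
        tree=tree,
        bipartition_results=bipartition_results,
        config=config,
    )
    if config.outdir is not None:
        write_artifacts(report, records, config.outdir)
        validate_artifacts(report, config.outdir)
    return report


def write_artifacts(
    report: AnalysisReport, records: Sequence[SequenceRecord], outdir: Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named = [(r.id, report.params[r.id]) for r in records]
    (outdir / "params.tsv").write_text(seq_core.params_table(named))
    (outdir / "params.json").write_text(seq_core.params_json(named) + "\n")
    write_gff3(report.architectures.values(), outdir / "domains.gff3")
    if report.domain_records:
        seq_core.write_fasta(report.domain_records, outdir / "domains.fasta")
    if report.msa is not None:
        write_aligned_fasta(report.msa, outdir / "domains.aln.fasta")
        (outdir / "domains.aln.clustal.txt").write_text(report.msa.to_clustal())
    if report.distances is not None:
        (outdir / "distances.phylip").write_text(report.distances.to_phylip())
    if report.tree is not None:
        (outdir / "tree.nwk").write_text(report.newick + "\n")
        (outdir / "tree.txt").write_text(ascii_tree(report.tree))
    (outdir / "report.json").write_text(
        json.dumps(report.summary_dict(), indent=2) + "\n"
    )


def validate_artifacts(report: AnalysisReport, outdir: Path) -> None:
    """Fail the run when counts disagree across the written artifacts."""
    outdir = Path(outdir)
    gff = read_gff3(outdir / "domains.gff3")
    for seq_id, arch in report.architectures.items():
        n_mem = len(arch.domains)
        n_gff = len(gff[seq_id].domains) if seq_id in gff else 0
        if arch.domains and n_mem != n_gff:
            raise PipelineError(
                f"validation: {seq_id} has {n_mem} domains in memory, {n_gff} in GFF3"
            )
    summary = json.loads((outdir / "report.json").read_text())
    for seq_id, arch in report.architectures.items():
        s = summary["sequences"][seq_id]
        if s["n_complete_domains"] != len(arch.complete_domains):
            raise PipelineError(f"validation: domain-count mismatch for {seq_id}")
    if report.tree is not None:
        if report.tree.leaf_labels != {r.id for r in report.domain_records}:
            raise PipelineError("validation: tree leaves do not match extracted domains")
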