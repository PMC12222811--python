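"""Reference-genome and read I/O.

A *replicon* is any independently replicating element of a genome — a
chromosome or a plasmid.  A genome is modelled as an ordered list of
replicons sorted by descending length; the longest chromosome is the
reference against which all copy numbers are expressed (copy number 1 by
definition).

Replicon roles come from an optional two-column metadata table
(``replicon_id<TAB>role``); without one, a case-insensitive ``"plasmid"``
substring in the FASTA description marks a plasmid, mirroring how RefSeq
annotates plasmid records in their definition lines.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROMOSOME = "chromosome"
PLASMID = "plasmid"

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid of a reference genome."""

    id: str
    sequence: str
    role: str  # "chromosome" | "plasmid"
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        if self.role not in (CHROMOSOME, PLASMID):
            raise ValueError(f"unknown role {self.role!r} for replicon {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRef:
    """A multi-replicon reference genome.

    ``replicons`` are sorted by (length descending, id ascending) so the
    ordering is a pure function of content, never of file order.
    ``reference_index`` points at the longest chromosome; it is 0 except in
    the pathological (and later filtered) case of a plasmid longer than
    every chromosome.
    """

    replicons: tuple[Replicon, ...]
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate replicon ids in genome")
        if not any(r.role == CHROMOSOME for r in self.replicons):
            raise ValueError("no reference chromosome in genome")
        ordered = sorted(self.replicons, key=lambda r: (-r.length, r.id))
        object.__setattr__(self, "replicons", tuple(ordered))

    @property
    def reference_index(self) -> int:
        # sorted by length desc then id asc, so the first chromosome in
        # order is the longest chromosome
        return min(i for i, r in enumerate(self.replicons) if r.role == CHROMOSOME)

    @property
    def reference(self) -> Replicon:
        return self.replicons[self.reference_index]

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.replicons]

    @property
    def n_replicons(self) -> int:
        return len(self.replicons)

    def plasmids(self) -> list[Replicon]:
        return [r for r in self.replicons if r.role == PLASMID]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; ``mate`` is "single", "R1" or "R2"."""

    id: str
    sequence: str
    mate: str = "single"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r} has an empty sequence")


def _normalize_sequence(raw: str, label: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        # IUPAC ambiguity codes other than N are mapped to N rather than
        # rejected: they occur in real assemblies and are never indexed.
        table = str.maketrans({c: "N" for c in bad})
        seq = seq.translate(table)
    return seq


def _read_metadata_table(path: str | Path) -> dict[str, str]:
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'replicon_id<TAB>role', got {line!r}"
                )
            rid, role = parts
            role = role.strip().lower()
            if role not in (CHROMOSOME, PLASMID):
                raise ValueError(f"{path}:{lineno}: unknown role {role!r}")
            roles[rid.strip()] = role
    return roles


def load_genome(
    fasta_path: str | Path,
    metadata: str | Path | dict[str, str] | None = None,
) -> GenomeRef:
    """Load a multi-replicon reference genome from FASTA.

    Parameters
    ----------
    fasta_path
        FASTA file with one record per replicon.
    metadata
        Optional role table — either a path to a ``replicon_id<TAB>role``
        TSV or a pre-built mapping.  Without it, a record whose description
        contains "plasmid" (case-insensitive) is a plasmid; everything else
        is a chromosome.

    Raises
    ------
    ValueError
        On duplicate record ids, empty sequences, or a genome with no
        chromosome (no reference to normalise against).
    """
    fasta_path = Path(fasta_path)
    if isinstance(metadata, (str, Path)):
        roles_map = _read_metadata_table(metadata)
    else:
        roles_map = dict(metadata) if metadata else {}

    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate replicon id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"replicon {rec.id!r} has an empty sequence")
        if rec.id in roles_map:
            role = roles_map[rec.id]
        else:
            role = PLASMID if "plasmid" in rec.description.lower() else CHROMOSOME
        replicons.append(
            Replicon(id=rec.id, sequence=seq, role=role, description=rec.description)
        )
    if not replicons:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return GenomeRef(replicons=tuple(replicons), genome_id=fasta_path.stem)


def write_genome(genome: GenomeRef, fasta_path: str | Path) -> None:
    """Write a GenomeRef back to FASTA, preserving roles in descriptions."""
    records = []
    for rep in genome.replicons:
        desc = rep.description
        # make the role recoverable on reload by the keyword rule
        if rep.role == PLASMID and "plasmid" not in desc.lower():
            desc = (desc + " plasmid").strip()
        records.append(SeqRecord(Seq(rep.sequence), id=rep.id, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fastq(path: str | Path, mate: str) -> Iterator[ReadRecord]:
    with _open_maybe_gzip(path) as fh:
        idx = 0
        for rec in SeqIO.parse(fh, "fastq"):
            idx += 1
            yield ReadRecord(
                id=rec.id,
                sequence=_normalize_sequence(str(rec.seq), rec.id),
                mate=mate,
            )


def load_reads(paths: Sequence[str | Path]) -> Iterator[ReadRecord]:
    """Stream reads from one (single-end) or two (paired R1/R2) FASTQ files.

    Gzip-compressed inputs are detected by the ``.gz`` suffix.  For paired
    input, mates are interleaved R1, R2, R1, R2, ... and the two files must
    hold the same number of records.
    """
    paths = [Path(p) for p in paths]
    if len(paths) == 1:
        yield from _parse_fastq(paths[0], "single")
    elif len(paths) == 2:
        it1 = _parse_fastq(paths[0], "R1")
        it2 = _parse_fastq(paths[1], "R2")
        n1 = n2 = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                raise ValueError(
                    f"paired FASTQ files have different record counts "
                    f"({paths[0].name}: {n1 + (r1 is not None)}, "
                    f"{paths[1].name}: {n2 + (r2 is not None)} so far)"
                )
            n1 += 1
            n2 += 1
            yield r1
            yield r2
    else:
        raise ValueError("load_reads expects one or two FASTQ paths")


def apply_genome_filters(genome: GenomeRef) -> tuple[GenomeRef | None, list[dict]]:
    """Apply the analysis-stage genome filters.

    Two rules:

    * plasmids shorter than 1000 bp are dropped (strictly less-than — a
      1000 bp plasmid is kept); these are typically unplaced contigs
      misannotated as plasmids;
    * a genome containing a plasmid longer than its longest chromosome is
      rejected outright, as a likely misannotation.

    Returns ``(filtered genome or None, report)`` where the report lists one
    dict per removal with keys ``replicon_id`` and ``reason``.  Idempotent.
    """
    report: list[dict] = []
    ref_len = max(
        (r.length for r in genome.replicons if r.role == CHROMOSOME), default=0
    )
    for rep in genome.plasmids():
        if rep.length > ref_len:
            report.append(
                {
                    "replicon_id": rep.id,
                    "reason": "plasmid_longer_than_chromosome_genome_rejected",
                }
            )
    if report:
        # whole genome rejected
        for rep in genome.replicons:
            if not any(r["replicon_id"] == rep.id for r in report):
                report.append(
                    {"replicon_id": rep.id, "reason": "genome_rejected"}
                )
        return None, report

    kept: list[Replicon] = []
    for rep in genome.replicons:
        if rep.role == PLASMID and rep.length < 1000:
            report.append(
                {"replicon_id": rep.id, "reason": "plasmid_shorter_than_1000bp"}
            )
        else:
            kept.append(rep)
    return GenomeRef(replicons=tuple(kept), genome_id=genome.genome_id), report


def write_filter_report(report: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon_id\treason\n")
        for row in report:
            fh.write(f"{row['replicon_id']}\t{row['reason']}\n")
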