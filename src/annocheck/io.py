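"""Protein FASTA input/output and NCBI-style defline parsing.

Records are read with Bio.SeqIO and post-processed into
:class:`ProteinRecord` objects: sequences are uppercased, stop (``*``) and
gap (``-``) characters stripped, residues validated against the extended
amino-acid alphabet, and the defline split into accession / description /
organism following the NCBI convention ``>ACCESSION description [Organism]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .motifs import SEQUENCE_AA


class FastaFormatError(ValueError):
    """Malformed FASTA content (bad residues, duplicate or empty accessions)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its parsed annotation metadata."""

    accession: str
    description: str
    organism: str
    sequence: str
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaFormatError("record accession must be non-empty")
        if not self.sequence:
            raise FastaFormatError(f"{self.accession}: empty sequence after cleaning")
        bad = set(self.sequence) - SEQUENCE_AA
        if bad:
            raise FastaFormatError(
                f"{self.accession}: illegal residue letter(s) {sorted(bad)}"
            )


@dataclass
class ProteomeSet:
    """All records of one species, with its phylum (or ``UNKNOWN``)."""

    species_name: str
    phylum: str = "UNKNOWN"
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(accs) != len(set(accs)):
            seen: set[str] = set()
            dup = next(a for a in accs if a in seen or seen.add(a))  # type: ignore[func-returns-value]
            raise FastaFormatError(
                f"{self.species_name}: duplicate accession {dup!r}"
            )

    def __len__(self) -> int:
        return len(self.records)


def parse_defline(text: str, dialect: str = "ncbi") -> tuple[str, str, str]:
    """Split a header line (without ``>``) into (accession, description, organism).

    The accession is the first whitespace-delimited token. In the ``ncbi``
    dialect the organism is the content of the last balanced ``[...]`` group
    when the header ends with one; the description is whatever sits between.
    With ``dialect="plain"`` the whole remainder is the description. Never
    raises: degenerate headers yield empty description/organism.
    """
    stripped = text.strip()
    if not stripped:
        return "", "", ""
    parts = stripped.split(None, 1)
    accession = parts[0]
    rest = parts[1].strip() if len(parts) > 1 else ""
    if dialect == "plain" or not rest:
        return accession, rest, ""
    organism = ""
    description = rest
    if rest.endswith("]"):
        depth = 0
        for i in range(len(rest) - 1, -1, -1):
            if rest[i] == "]":
                depth += 1
            elif rest[i] == "[":
                depth -= 1
                if depth == 0:
                    organism = rest[i + 1 : -1]
                    description = rest[:i].strip()
                    break
    return accession, description, organism


def clean_sequence(raw: str, accession: str = "?") -> str:
    """Uppercase, strip ``*``/``-``, and validate the residue alphabet."""
    seq = raw.upper().replace("*", "").replace("-", "")
    bad = set(seq) - SEQUENCE_AA
    if bad:
        raise FastaFormatError(
            f"{accession}: illegal residue letter(s) {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, dialect: str = "ncbi") -> list[ProteinRecord]:
    """Read a protein FASTA file into cleaned, validated records in file order.

    An empty file yields an empty list. Duplicate accessions and headers with
    an empty accession raise :class:`FastaFormatError` (the latter with the
    offending line number).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, description, organism = parse_defline(rec.description, dialect)
        if not accession:
            raise FastaFormatError(
                f"{path}: empty accession in header at line "
                f"{_find_header_line(path, rec.description)}"
            )
        if accession in seen:
            raise FastaFormatError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                description=description,
                organism=organism,
                sequence=clean_sequence(str(rec.seq), accession),
                source_file=str(path),
            )
        )
    return records


def _find_header_line(path: Path, header: str) -> int:
    """Locate a header's line number; used only when reporting format errors."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].rstrip("\n") == header:
                return lineno
    return 0


def read_proteome(
    path: str | Path,
    species_name: str | None = None,
    phylum: str = "UNKNOWN",
    dialect: str = "ncbi",
) -> ProteomeSet:
    """Read one species' FASTA file; species defaults to the file stem."""
    path = Path(path)
    return ProteomeSet(
        species_name=species_name or path.stem,
        phylum=phylum,
        records=read_fasta(path, dialect),
    )


def format_defline(record: ProteinRecord) -> str:
    parts = [record.accession]
    if record.description:
        parts.append(record.description)
    if record.organism:
        parts.append(f"[{record.organism}]")
    return " ".join(parts)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{format_defline(rec)}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")
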