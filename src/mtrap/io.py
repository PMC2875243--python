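"""FASTA / CLUSTAL readers and writers.

'-' is the gap character on disk.  '*' (sometimes used for stop codons
or, in older alignment tools, for gaps) is rejected with a message
rather than guessed at.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import GAP, RESIDUES


class FormatError(ValueError):
    """Malformed sequence file."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    id: str
    letters: str
    description: str = ""


_NUCLEOTIDE = set("ACGTUN")


def looks_like_nucleotide(letters: str) -> bool:
    """Composition heuristic: ≥95% of residues drawn from ACGTUN."""
    residues = [c for c in letters.upper() if c != GAP]
    if not residues:
        return False
    return sum(c in _NUCLEOTIDE for c in residues) / len(residues) >= 0.95


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    allow_nucleotide: bool = True,
) -> list[SequenceRecord]:
    """Read a multi-FASTA file into uppercase records.

    With ``aligned=True`` all records must share one length.  Duplicate
    ids, empty files/records and '*' characters are hard errors.
    """
    path = Path(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse FASTA file {path}: {exc}") from exc
    if not raw:
        raise FormatError(f"no FASTA records in {path}")
    records, seen = [], set()
    for rec in raw:
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        letters = str(rec.seq).upper()
        if not letters:
            raise FormatError(f"record {rec.id!r} in {path} is empty")
        if "*" in letters:
            raise FormatError(
                f"record {rec.id!r} contains '*'; use '-' for gaps "
                "(the '*' character is ambiguous with stop codons)"
            )
        bad = set(letters) - set(RESIDUES) - {GAP}
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains symbols outside the protein "
                f"alphabet: {''.join(sorted(bad))}"
            )
        records.append(SequenceRecord(rec.id, letters, rec.description))
    if aligned:
        lengths = {len(r.letters) for r in records}
        if len(lengths) > 1:
            raise FormatError(f"aligned records in {path} have ragged lengths {sorted(lengths)}")
    if not allow_nucleotide and all(looks_like_nucleotide(r.letters) for r in records):
        raise FormatError(
            f"{path} looks like nucleotide sequence; only protein input is "
            "supported (pass the override flag to force)"
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header += f" {desc}"
            fh.write(header + "\n")
            for start in range(0, len(rec.letters), width):
                fh.write(rec.letters[start : start + width] + "\n")


def write_clustal(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Minimal CLUSTAL-format writer for aligned records (write-only format)."""
    records = list(records)
    lengths = {len(r.letters) for r in records}
    if len(lengths) > 1:
        raise FormatError("CLUSTAL output requires equal-length (aligned) records")
    name_w = max(len(r.id) for r in records)
    with open(path, "w") as fh:
        fh.write("CLUSTAL format alignment\n\n")
        length = lengths.pop()
        for start in range(0, length, width):
            for rec in records:
                fh.write(f"{rec.id:<{name_w}}  {rec.letters[start : start + width]}\n")
            fh.write("\n")
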