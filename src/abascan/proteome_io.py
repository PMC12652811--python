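"""Reading and writing the pipeline's file formats.

FASTA proteomes (UniProt-style or plain headers) are parsed with Biopython
and validated/canonicalized here; match tables are plain UTF-8 TSV with a
header row, tab separators, ``\\n`` line endings and a deterministic sort
order so outputs are diffable.
"""

from __future__ import annotations

import csv
import io
import re
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .motifs import ACCEPTED_AA, MotifMatch

_UNIPROT_HEADER = re.compile(r"^(\w+)\|([\w.-]+)\|(\S+)(?:\s+(.*))?$")

MATCH_COLUMNS = ("seq_id", "motif", "start", "end", "matched_text", "anchors")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein: accession, free-text description, canonical residues."""

    seq_id: str
    description: str
    residues: str


class FastaError(ValueError):
    """Raised on malformed or invalid FASTA input."""


class TableError(ValueError):
    """Raised on malformed TSV table input."""


@contextmanager
def _open_read(source: str | Path | IO[str]) -> Iterator[IO[str]]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield fh
    else:
        yield source


@contextmanager
def _open_write(dest: str | Path | IO[str]) -> Iterator[IO[str]]:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            yield fh
    else:
        yield dest


def parse_uniprot_header(header: str) -> tuple[str, str]:
    """Split a FASTA header (without the leading ``>``) into (seq_id,
    description).

    UniProt-style ``db|ACCESSION|NAME description`` headers yield the
    accession as seq_id; anything else yields the first whitespace-delimited
    token.
    """
    header = header.strip()
    if not header:
        raise FastaError("empty FASTA header")
    m = _UNIPROT_HEADER.match(header)
    if m:
        _, accession, name, desc = m.groups()
        description = name if not desc else f"{name} {desc}"
        return accession, description
    parts = header.split(None, 1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_fasta(source: str | Path | IO[str]) -> list[SequenceRecord]:
    """Read a FASTA proteome into validated :class:`SequenceRecord` objects.

    Sequences are uppercased, internal whitespace is removed and a single
    trailing ``*`` (stop) is stripped.  Duplicate accessions, empty
    sequences, characters outside the accepted alphabet and empty files are
    errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_read(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq_id, description = parse_uniprot_header(rec.description)
            residues = "".join(str(rec.seq).split()).upper()
            if residues.endswith("*"):
                residues = residues[:-1]
            if not residues:
                raise FastaError(f"record {seq_id!r} has an empty sequence")
            bad = set(residues) - ACCEPTED_AA
            if bad:
                raise FastaError(
                    f"record {seq_id!r} contains invalid residue(s) {sorted(bad)}"
                )
            if seq_id in seen:
                raise FastaError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            records.append(SequenceRecord(seq_id, description, residues))
    if not records:
        raise FastaError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: str | Path | IO[str],
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with _open_write(dest) as fh:
        for rec in records:
            header = f">{rec.seq_id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_match_table(matches: Iterable[MotifMatch],
                      dest: str | Path | IO[str]) -> None:
    """Write matches as TSV, sorted by (seq_id, motif, start, end)."""
    rows = sorted(matches, key=lambda m: (m.seq_id, m.motif_name, m.start, m.end))
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MATCH_COLUMNS)
        for m in rows:
            writer.writerow(
                [m.seq_id, m.motif_name, m.start, m.end, m.matched_text,
                 ",".join(str(p) for p in m.anchor_positions)]
            )


def read_match_table(source: str | Path | IO[str]) -> list[MotifMatch]:
    """Read a match TSV back into :class:`MotifMatch` objects (lossless
    round trip with :func:`write_match_table`)."""
    with _open_read(source) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableError("empty match table") from None
        if tuple(header) != MATCH_COLUMNS:
            missing = set(MATCH_COLUMNS) - set(header)
            raise TableError(
                f"bad match-table header {header!r}"
                + (f" (missing {sorted(missing)})" if missing else "")
            )
        matches: list[MotifMatch] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(MATCH_COLUMNS):
                raise TableError(f"line {lineno}: expected {len(MATCH_COLUMNS)} columns")
            seq_id, motif, start_s, end_s, text, anchors_s = row
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TableError(f"line {lineno}: non-integer coordinates") from None
            if start > end:
                raise TableError(f"line {lineno}: start {start} > end {end}")
            anchors = tuple(int(a) for a in anchors_s.split(",")) if anchors_s else ()
            matches.append(MotifMatch(seq_id, motif, start, end, text, anchors))
    return matches
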