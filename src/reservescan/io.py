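"""FASTA and tabular input/output.

Thin, validating wrappers used across the pipeline.  Parsing is delegated to
Biopython's FASTA reader; validation enforces the protein alphabet (20
standard residues plus the ambiguity codes X/B/Z/U/O/J), unique record ids and
non-empty files.  CRLF and LF files parse identically.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import validate_sequence


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


def _as_handle(source) -> tuple[Iterable[str], str]:
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"FASTA file not found: {path}")
        return path.read_text().splitlines(), str(path)
    return source, "<stream>"


def read_fasta(source, validate: bool = True) -> list[tuple[str, str]]:
    """Read protein records from a FASTA path, handle or line iterable.

    Returns ``[(id, sequence), ...]`` in file order.  The record id is the
    first whitespace-delimited token of the header line.

    Raises
    ------
    FastaError
        On an empty file, a duplicate id, or (when ``validate``) a sequence
        character outside the amino-acid alphabet and ambiguity codes.
    """
    lines, name = _as_handle(source)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for header, seq in SimpleFastaParser(_iter_lines(lines)):
        rec_id = header.split()[0] if header.split() else ""
        if not rec_id:
            raise FastaError(f"{name}: record with empty id")
        if rec_id in seen:
            raise FastaError(f"{name}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        seq = seq.upper()
        if validate:
            try:
                validate_sequence(seq, name=rec_id)
            except ValueError as exc:
                raise FastaError(f"{name}: {exc}") from exc
        records.append((rec_id, seq))
    if not records:
        raise FastaError(f"{name}: no FASTA records found")
    return records


def _iter_lines(lines: Iterable[str]) -> Iterator[str]:
    for line in lines:
        yield line.rstrip("\r\n") + "\n"


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write ``(id, sequence)`` records as wrapped FASTA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        write_fasta_handle(records, fh, width=width)


def write_fasta_handle(records: Iterable[tuple[str, str]], fh: IO[str], width: int = 60) -> None:
    for rec_id, seq in records:
        fh.write(f">{rec_id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_tsv(df, path) -> None:
    """Write a DataFrame as TSV (no index), creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
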