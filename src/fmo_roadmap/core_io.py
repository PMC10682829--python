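"""Sequence and alignment containers plus FASTA I/O.

The package works on protein sequences over the 20 standard amino acids
plus ``X`` (unknown).  Ambiguity codes (``B``, ``Z``, ``J``) and the rare
translated residues (``U``, ``O``) are rejected by default because the
fingerprint-matching semantics downstream must be unambiguous; a
``permissive`` switch maps them to ``X`` instead.  An ``X`` in a sequence
matches only wildcard positions of a motif, never a literal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino acid codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Working alphabet: standard residues plus 'X' for unknown.
ALPHABET = frozenset(AA20) | {"X"}
#: Codes accepted only under ``permissive`` and folded to 'X'.
AMBIGUOUS = frozenset("BZJUO")

GAP = "-"


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, ...)."""


class RaggedAlignmentError(ValueError):
    """Rows of an aligned FASTA file differ in length."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified, validated protein sequence.

    Parameters
    ----------
    id:
        Unique identifier (first whitespace-delimited token of the FASTA
        header).
    residues:
        Uppercase residue string over the 21-letter alphabet.
    description:
        Remainder of the FASTA header; free text.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An aligned set of sequences (rows of equal length, gaps as '-')."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise RaggedAlignmentError("alignment has no rows")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceError(f"duplicate id in alignment: {dup!r}")
        ref_id, ref_row = self.rows[0]
        for rid, row in self.rows:
            if len(row) != len(ref_row):
                raise RaggedAlignmentError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"row {ref_id!r} has length {len(ref_row)}"
                )
            ungapped = row.replace(GAP, "")
            # validates the residue alphabet as a side effect
            ProteinSequence(id=rid, residues=ungapped)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(f"no row with id {rid!r}")

    def ungapped(self, rid: str) -> ProteinSequence:
        return ProteinSequence(id=rid, residues=self.row(rid).replace(GAP, ""))


def _clean_residues(raw: str, seq_id: str, permissive: bool) -> str:
    s = raw.upper().rstrip("*")
    if permissive:
        s = "".join("X" if c in AMBIGUOUS else c for c in s)
    for pos, ch in enumerate(s, start=1):
        if ch not in ALPHABET and ch != GAP:
            raise SequenceError(
                f"sequence {seq_id!r}: illegal character {ch!r} at position {pos}"
            )
    return s


def _parse_fasta(path: str | Path, permissive: bool) -> list[tuple[str, str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append((rec.id, desc, _clean_residues(str(rec.seq), rec.id, permissive)))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return records


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSequence]:
    """Read unaligned protein FASTA; order preserved, '*' stops stripped."""
    out = []
    for rid, desc, residues in _parse_fasta(path, permissive):
        if GAP in residues:
            raise SequenceError(
                f"sequence {rid!r} contains gap characters; use read_alignment"
            )
        out.append(ProteinSequence(id=rid, residues=residues, description=desc))
    return out


def read_alignment(path: str | Path, permissive: bool = False) -> MultipleAlignment:
    """Read aligned FASTA into a :class:`MultipleAlignment`."""
    rows = tuple((rid, residues) for rid, _, residues in _parse_fasta(path, permissive))
    return MultipleAlignment(rows=rows)


def _wrap(s: str, width: int = 60) -> Iterable[str]:
    for i in range(0, len(s), width):
        yield s[i:i + width]


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA, 60-column wrapped."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            header = f">{seq.id}" + (f" {seq.description}" if seq.description else "")
            fh.write(header + "\n")
            for line in _wrap(seq.residues):
                fh.write(line + "\n")


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA, 60-column wrapped."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for line in _wrap(row):
                fh.write(line + "\n")
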