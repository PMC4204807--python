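"""Sequence and alignment data model plus FASTA/TSV input-output.

The pipeline operates on two containers: :class:`SequenceRecord` (a named
DNA or protein sequence, possibly gapped) and :class:`MsAlignment` (an
ordered multiple alignment of equal-length gapped records).  All column
coordinates in the package are 0-based, half-open; human-facing tables use
1-based closed coordinates and say so in their column names.

Gap characters are normalised to ``-`` ('.' is accepted on input) and
sequences are upper-cased on input.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

GAP = "-"

# IUPAC alphabets (gap allowed only inside alignments, checked separately)
DNA_CHARS = frozenset("ACGTURYSWKMBDHVN")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
# note: 'J' is a legal IUPAC amino-acid ambiguity (Leu/Ile) but not a DNA code


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed; message names the line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``seq`` may contain ``-`` gap characters when the record is a row of an
    alignment; ``ungapped()`` strips them.
    """

    id: str
    seq: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def validate(self, allow_gaps: bool = True) -> None:
        alphabet = DNA_CHARS if self.moltype == "dna" else PROTEIN_CHARS
        for i, c in enumerate(self.seq):
            if c == GAP:
                if not allow_gaps:
                    raise ValueError(
                        f"record {self.id!r}: gap character at position {i} "
                        "outside an alignment"
                    )
                continue
            if c not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.moltype} character "
                    f"{c!r} at position {i}"
                )


@dataclass
class MsAlignment:
    """Multiple sequence alignment: ordered gapped records of equal length."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if self.records:
            n = len(self.records[0].seq)
            for r in self.records:
                if len(r.seq) != n:
                    raise ValueError(
                        f"record {r.id!r} has gapped length {len(r.seq)}, "
                        f"expected {n}"
                    )
            ids = [r.id for r in self.records]
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate record ids: {dupes}")

    @property
    def ncols(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    @property
    def nrows(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def take_columns(self, cols: Sequence[int]) -> "MsAlignment":
        """Sub-alignment restricted to the given columns (in given order)."""
        recs = [
            replace(r, seq="".join(r.seq[j] for j in cols))
            for r in self.records
        ]
        return MsAlignment(recs)

    def slice_columns(self, start: int, end: int) -> "MsAlignment":
        recs = [replace(r, seq=r.seq[start:end]) for r in self.records]
        return MsAlignment(recs)

    def drop_all_gap_columns(self) -> tuple["MsAlignment", list[int]]:
        """Remove columns that are gap in every sequence.

        Returns the cleaned alignment and the retained column indices of
        the original coordinate system.
        """
        keep = [
            j
            for j in range(self.ncols)
            if any(r.seq[j] != GAP for r in self.records)
        ]
        if len(keep) == self.ncols:
            return self, list(range(self.ncols))
        return self.take_columns(keep), keep


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_fasta(path: str | os.PathLike, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a (possibly gapped) FASTA file into SequenceRecords.

    Order is preserved and gap characters retained.  A record containing a
    character outside the IUPAC alphabet for ``moltype`` raises
    :class:`FastaParseError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    alphabet = DNA_CHARS if moltype == "dna" else PROTEIN_CHARS
    with open(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, l in enumerate(text.splitlines()) if l.strip()
        )
        raise FastaParseError(
            f"{path}: line {first_bad}: expected FASTA header '>'"
        )
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _normalise(str(rec.seq))
        for c in set(seq):
            if c != GAP and c not in alphabet:
                lineno = _find_char_line(text, rec.id, c)
                raise FastaParseError(
                    f"{path}: line {lineno}: illegal {moltype} character "
                    f"{c!r} in record {rec.id!r}"
                )
        records.append(SequenceRecord(id=rec.id, seq=seq, moltype=moltype))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FastaParseError(f"{path}: duplicate record ids in FASTA")
    return records


def _find_char_line(text: str, rec_id: str, char: str) -> int:
    """Locate the first line of a record's body containing ``char``."""
    in_rec = False
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
            continue
        if in_rec and (char in line.upper() or char.lower() in line):
            return i
    return 0


def read_alignment(path: str | os.PathLike, moltype: str = "dna") -> MsAlignment:
    """Read an aligned FASTA file; all records must have equal length."""
    return MsAlignment(read_fasta(path, moltype=moltype))


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
#
# Every typed pipeline output has a writer and a matching reader so that
# write -> read is the identity.  Schemas are stable; human-facing start/end
# columns are 1-based closed and named *_1based.
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
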