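"""Multiple sequence alignments: container and FASTA / A3M readers.

An :class:`Msa` keeps the raw aligned rows plus the subset of columns treated
as match states.  For A3M input the match states are given by the format's
case convention (lowercase = insertion relative to the master); for aligned
FASTA a column is a match column when fewer than half of its rows are gaps.
Column indices are 1-based throughout, like every coordinate in the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

GAP_CHARS = "-."


class MsaParseError(ValueError):
    pass


@dataclass
class Msa:
    id: str
    rows: list[tuple[str, str]]
    match_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaParseError(f"MSA {self.id!r} has no rows")
        width = len(self.rows[0][1])
        for name, seq in self.rows:
            if len(seq) != width:
                raise MsaParseError(
                    f"MSA {self.id!r}: row {name!r} has length {len(seq)}, "
                    f"expected {width}"
                )
        if width < 1:
            raise MsaParseError(f"MSA {self.id!r} has zero columns")
        for c in self.match_columns:
            if not 1 <= c <= width:
                raise MsaParseError(
                    f"MSA {self.id!r}: match column {c} outside 1..{width}"
                )
        if list(self.match_columns) != sorted(set(self.match_columns)):
            raise MsaParseError(
                f"MSA {self.id!r}: match columns must be strictly increasing"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def match_row(self, i: int) -> str:
        """Row i restricted to the match columns."""
        seq = self.rows[i][1]
        return "".join(seq[c - 1] for c in self.match_columns)

    def gap_fraction(self, col: int) -> float:
        """Fraction of rows that are gapped in 1-based column `col`."""
        return sum(
            1 for _, s in self.rows if s[col - 1] in GAP_CHARS
        ) / self.n_rows

    def slice_match_columns(self, lo: int, hi: int) -> "Msa":
        """Sub-MSA over match-column *indices* lo..hi (1-based inclusive,
        indices into `match_columns`, not raw columns)."""
        cols = self.match_columns[lo - 1 : hi]
        rows = [
            (name, "".join(seq[c - 1] for c in cols)) for name, seq in self.rows
        ]
        return Msa(
            id=f"{self.id}/{lo}-{hi}",
            rows=rows,
            match_columns=list(range(1, len(cols) + 1)),
        )


def _fasta_match_columns(rows: list[tuple[str, str]]) -> list[int]:
    width = len(rows[0][1])
    n = len(rows)
    out = []
    for c in range(width):
        gaps = sum(1 for _, s in rows if s[c] in GAP_CHARS)
        if gaps / n < 0.5:
            out.append(c + 1)
    return out


def read_msa(path: str | Path, format: str = "fasta") -> Msa:
    """Read an MSA from aligned FASTA or A3M.

    FASTA: all rows must be equal length; match columns are those with gap
    fraction < 0.5.  A3M: lowercase letters are insert states and are removed
    row by row; the remaining (match/delete) rows must then agree in length.
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise MsaParseError(f"{path}: no sequences")
        rows = [(r.id, str(r.seq)) for r in records]
        widths = {len(s) for _, s in rows}
        if len(widths) != 1:
            bad = next(n for n, s in rows if len(s) != len(rows[0][1]))
            raise MsaParseError(f"{path}: unequal row lengths (row {bad!r})")
        return Msa(id=path.stem, rows=rows, match_columns=_fasta_match_columns(rows))
    if format == "a3m":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise MsaParseError(f"{path}: no sequences")
        rows = []
        for r in records:
            seq = "".join(c for c in str(r.seq) if not (c.islower() or c == "."))
            rows.append((r.id, seq))
        width = len(rows[0][1])
        for name, seq in rows:
            if len(seq) != width:
                raise MsaParseError(
                    f"{path}: row {name!r} has {len(seq)} match states, "
                    f"expected {width} (after removing a3m inserts)"
                )
        return Msa(id=path.stem, rows=rows, match_columns=list(range(1, width + 1)))
    raise ValueError(f"unknown MSA format {format!r}")


def write_msa_fasta(msa: Msa, path: str | Path, match_only: bool = False) -> None:
    """Write the MSA (optionally restricted to match columns) as aligned FASTA."""
    with open(path, "w") as fh:
        for i, (name, seq) in enumerate(msa.rows):
            fh.write(f">{name}\n")
            fh.write((msa.match_row(i) if match_only else seq) + "\n")


def msa_from_string(text: str, format: str = "fasta", id: str = "msa") -> Msa:
    """Parse an MSA from an in-memory FASTA/A3M string (test convenience)."""
    handle = io.StringIO(text)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise MsaParseError("no sequences in string")
    if format == "a3m":
        rows = []
        for r in records:
            seq = "".join(c for c in str(r.seq) if not (c.islower() or c == "."))
            rows.append((r.id, seq))
        width = len(rows[0][1])
        for name, seq in rows:
            if len(seq) != width:
                raise MsaParseError(
                    f"row {name!r} has {len(seq)} match states, expected {width}"
                )
        return Msa(id=id, rows=rows, match_columns=list(range(1, width + 1)))
    rows = [(r.id, str(r.seq)) for r in records]
    widths = {len(s) for _, s in rows}
    if len(widths) != 1:
        bad = next(n for n, s in rows if len(s) != len(rows[0][1]))
        raise MsaParseError(f"unequal row lengths (row {bad!r})")
    return Msa(id=id, rows=rows, match_columns=_fasta_match_columns(rows))
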