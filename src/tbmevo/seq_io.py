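"""Readers and writers for the formats the pipeline consumes.

Plain FASTA (unaligned), aligned FASTA and Clustal go through Biopython's
parsers; everything is normalized into two small domain types,
:class:`SequenceRecord` (ungapped protein sequence) and :class:`Alignment`
(the coordinate hub mapping columns to reference residues).  A minimal
PDB B-factor rewriter supports projecting per-residue scores onto
structure models.

Conventions: residue numbers and alignment columns are 1-based inclusive;
the internal gap symbol is ``-`` ('.' is accepted on read only); 'X' is a
legal residue standing for ambiguity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"

_SPECIES_KEY = re.compile(r"species=(\S+)")


class SeqIOError(ValueError):
    """Raised on malformed sequence input."""


def _parse_species(record_id: str, description: str) -> str | None:
    """Species tag: a ``species=`` key in the description wins, else the
    id prefix before the first ``|``, else None."""
    m = _SPECIES_KEY.search(description or "")
    if m:
        return m.group(1)
    if "|" in record_id:
        return record_id.split("|", 1)[0]
    return None


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with identifier and species tag."""

    id: str
    residues: str
    description: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch in (GAP, "."):
                raise SeqIOError(
                    f"sequence {self.id!r} contains gap character {ch!r} "
                    f"at position {pos} (unaligned input must be gap-free)"
                )
            if ch not in ALPHABET:
                raise SeqIOError(
                    f"sequence {self.id!r} has illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment; residues may contain the gap symbol."""

    id: str
    residues: str
    description: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("alignment row requires a non-empty id")
        for pos, ch in enumerate(self.residues, start=1):
            if ch != GAP and ch not in ALPHABET:
                raise SeqIOError(
                    f"row {self.id!r} has illegal character {ch!r} at column {pos}"
                )

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            description=self.description,
            species=self.species,
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Set of equal-length gapped rows; the coordinate hub of the pipeline.

    Invariants: >= 2 rows, all the same length, unique ids, and every
    column holds at least one non-gap symbol.
    """

    rows: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) < 2:
            raise SeqIOError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            offenders = sorted({r.id for r in rows})
            raise SeqIOError(f"ragged alignment rows: {', '.join(offenders)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate row id(s): {', '.join(dup)}")
        ncols = lengths.pop()
        if ncols == 0:
            raise SeqIOError("alignment has zero columns")
        for j in range(ncols):
            if all(r.residues[j] == GAP for r in rows):
                raise SeqIOError(f"column {j + 1} is all-gap")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, row_id: str) -> AlignedSequence:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(f"row {row_id!r} not in alignment")

    def column(self, col: int) -> str:
        """Column ``col`` (1-based) as a string, one symbol per row."""
        if not 1 <= col <= self.ncols:
            raise IndexError(f"column {col} out of range 1..{self.ncols}")
        return "".join(r.residues[col - 1] for r in self.rows)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA.  Lowercase is raised, trailing/embedded ``*``
    stripped, gaps rejected, duplicate ids rejected."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("*", "")
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                description=rec.description,
                species=_parse_species(rec.id, rec.description),
            )
        )
    if not records:
        raise SeqIOError(f"no sequences found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord | AlignedSequence],
    path: str | Path,
    width: int = 60,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments

_DIALECTS = {"afa": "fasta", "clustal": "clustal"}


def read_alignment(path: str | Path, dialect: str = "afa") -> Alignment:
    """Read an MSA in aligned-FASTA (``afa``) or ``clustal`` dialect.

    ``.`` is normalized to ``-``; both dialects yield identical
    :class:`Alignment` values for the same content.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise SeqIOError(f"unknown alignment dialect {dialect!r} (use afa or clustal)")
    rows: list[AlignedSequence] = []
    if dialect == "afa":
        # parse as plain FASTA so ragged rows can be reported by id
        raw = list(SeqIO.parse(str(path), "fasta"))
        if not raw:
            raise SeqIOError(f"no rows found in {path}")
        lengths = {len(r.seq) for r in raw}
        if len(lengths) > 1:
            offenders = sorted({r.id for r in raw if len(r.seq) != max(lengths)})
            raise SeqIOError(f"ragged alignment rows in {path}: {', '.join(offenders)}")
        parsed = raw
    else:
        parsed = list(AlignIO.read(str(path), "clustal"))
    for rec in parsed:
        residues = str(rec.seq).upper().replace(".", GAP)
        rows.append(
            AlignedSequence(
                id=rec.id,
                residues=residues,
                description=getattr(rec, "description", "") or "",
                species=_parse_species(rec.id, getattr(rec, "description", "") or ""),
            )
        )
    return Alignment(rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    write_fasta(aln.rows, path, width=width)


# ---------------------------------------------------------------------------
# PDB B-factor projection

_PDB_RECORD = ("ATOM  ", "HETATM")


def write_bfactor_pdb(
    pdb_in: str | Path,
    chain: str,
    residue_scores: Mapping[int, float],
    pdb_out: str | Path,
) -> int:
    """Rewrite the B-factor column of ATOM/HETATM records in one chain.

    ``residue_scores`` is keyed by author residue numbers (no insertion
    codes; residues carrying an insertion code are skipped with a
    warning).  Only columns 61-66 of matched lines change; everything
    else is copied byte-for-byte.  Returns the number of distinct
    residues annotated.
    """
    pdb_in, pdb_out = Path(pdb_in), Path(pdb_out)
    lines = pdb_in.read_text().splitlines(keepends=True)
    chains_seen: set[str] = set()
    touched: set[int] = set()
    skipped_icode: set[tuple[int, str]] = set()
    out_lines: list[str] = []
    for line in lines:
        rec = line[:6]
        if rec in _PDB_RECORD and len(line.rstrip("\n")) >= 26:
            line_chain = line[21]
            chains_seen.add(line_chain)
            if line_chain == chain:
                try:
                    resseq = int(line[22:26])
                except ValueError:
                    out_lines.append(line)
                    continue
                icode = line[26] if len(line) > 26 else " "
                if resseq in residue_scores:
                    if icode != " ":
                        skipped_icode.add((resseq, icode))
                        out_lines.append(line)
                        continue
                    body = line.rstrip("\n")
                    if len(body) < 66:
                        body = body.ljust(66)
                    newline = "\n" if line.endswith("\n") else ""
                    score = f"{residue_scores[resseq]:6.2f}"
                    out_lines.append(body[:60] + score + body[66:] + newline)
                    touched.add(resseq)
                    continue
        out_lines.append(line)
    if residue_scores and chain not in chains_seen:
        raise SeqIOError(f"chain {chain!r} absent from {pdb_in}")
    for resseq, icode in sorted(skipped_icode):
        warnings.warn(
            f"residue {resseq}{icode} has an insertion code; score keyed "
            f"without icode was not applied",
            stacklevel=2,
        )
    if residue_scores and not touched:
        warnings.warn(
            f"no residue in chain {chain!r} matched the score map", stacklevel=2
        )
    pdb_out.write_text("".join(out_lines))
    return len(touched)
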