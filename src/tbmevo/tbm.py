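"""Tankyrase-binding-motif (TBM) scanning and cross-species presence calls.

Three motif configurations are recognised, written in SLiM grammar with
1-based positions:

* ``canonical`` — ``Rxx[ACGP]xGxx`` (length 8: R at 1, one of A/C/G/P at
  4, G at 6),
* ``rx4`` — ``Rx(4)Gxx`` (length 8: R at 1, G at 6),
* ``rx5`` — ``Rx(5)Gxx`` (length 9: R at 1, G at 7).

Every canonical window is also an rx4 window; a window is labelled with
the most specific configuration it satisfies (canonical > rx4 > rx5).
Because rx4 and rx5 windows have different lengths, the same arginine
can anchor both an 8-mer and a 9-mer hit.  The ambiguity code 'X' never
satisfies a constrained position but matches the wildcards.

Correspondence with the human motif is decided on alignment columns: a
hit counts as *aligned* only when its arginine occupies exactly the
column of the human reference arginine; hits whose arginine falls
within a configurable column window are flagged *nearby* (a proxy for
"in a likely disordered region in proximity"), everything else is
absent.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conservation import reference_map
from .seq_io import Alignment, SequenceRecord


@dataclass(frozen=True)
class MotifPattern:
    """A TBM configuration: fixed length plus per-position constraints."""

    name: str
    length: int
    constraints: tuple[tuple[int, str], ...]  # (1-based position, allowed residues)

    def matches(self, window: str) -> bool:
        if len(window) != self.length:
            return False
        return all(window[pos - 1] in allowed for pos, allowed in self.constraints)


CANONICAL = MotifPattern("canonical", 8, ((1, "R"), (4, "ACGP"), (6, "G")))
RX4 = MotifPattern("rx4", 8, ((1, "R"), (6, "G")))
RX5 = MotifPattern("rx5", 9, ((1, "R"), (7, "G")))

#: most specific first
DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (CANONICAL, RX4, RX5)

VERDICTS = (
    "canonical_aligned",
    "relaxed_aligned",
    "nearby_unaligned",
    "absent",
    "no_ortholog",
)
_VERDICT_RANK = {v: i for i, v in enumerate(VERDICTS)}


def best_verdict(verdicts: Iterable[str]) -> str:
    return min(verdicts, key=lambda v: _VERDICT_RANK[v])


@dataclass(frozen=True)
class MotifHit:
    """One TBM match in one sequence (start = residue number of the R)."""

    seq_id: str
    start: int
    length: int
    configuration: str
    matched_text: str

    def __post_init__(self) -> None:
        if self.matched_text[0] != "R":
            raise ValueError("a TBM hit must start with R")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class ReferenceTBM:
    """A human reference motif from the curated binder table."""

    partner: str
    arg_residue: int
    expected_seq: str
    role: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.arg_residue < 1:
            raise ValueError(f"{self.partner}: arginine residue number must be >= 1")
        if not 7 <= len(self.expected_seq) <= 9:
            raise ValueError(
                f"{self.partner}: TBM sequence must be 7-9 residues, "
                f"got {len(self.expected_seq)}"
            )
        if not self.expected_seq.startswith("R"):
            raise ValueError(f"{self.partner}: TBM sequence must start with R")


@dataclass(frozen=True)
class CuratedBinderTable:
    """The curated table of confirmed tankyrase partners and their TBMs."""

    entries: tuple[ReferenceTBM, ...]

    @property
    def partners(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.partner not in seen:
                seen.append(e.partner)
        return seen

    def for_partner(self, partner: str) -> list[ReferenceTBM]:
        return [e for e in self.entries if e.partner == partner]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CuratedBinderTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = tuple(
            ReferenceTBM(
                partner=r.partner,
                arg_residue=int(r.arg_residue),
                expected_seq=r.tbm_seq,
                role=r.role,
                truncated=bool(int(r.truncated)),
            )
            for r in df.itertuples()
        )
        return cls(entries=entries)

    @classmethod
    def load_packaged(cls) -> "CuratedBinderTable":
        ref = importlib.resources.files("tbmevo.data") / "tnks_binders.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class PresenceCall:
    """Per (partner motif, species) verdict for the presence matrix."""

    partner: str
    species: str
    arg_residue: int
    verdict: str
    hits: tuple[MotifHit, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


# ---------------------------------------------------------------------------
# Scanning


def scan(
    seq: SequenceRecord, patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS
) -> list[MotifHit]:
    """All TBM windows in a sequence, each labelled with the most
    specific matching configuration; overlapping windows all count."""
    residues = seq.residues
    n = len(residues)
    lengths = sorted({p.length for p in patterns})
    hits: list[MotifHit] = []
    for start in range(1, n + 1):
        for length in lengths:
            if start + length - 1 > n:
                continue
            window = residues[start - 1 : start + length - 1]
            for pat in patterns:  # most specific first
                if pat.length == length and pat.matches(window):
                    hits.append(
                        MotifHit(
                            seq_id=seq.id,
                            start=start,
                            length=length,
                            configuration=pat.name,
                            matched_text=window,
                        )
                    )
                    break
    hits.sort(key=lambda h: (h.start, h.length))
    return hits


def scan_all(
    seq: SequenceRecord, patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS
) -> list[MotifHit]:
    """Whole-protein scan with no positional filtering (the mode used
    for proteins whose many motifs are reported exhaustively)."""
    return scan(seq, patterns)


# ---------------------------------------------------------------------------
# Correspondence classification


def _residue_to_column(aln: Alignment, row_id: str) -> dict[int, int]:
    return {res: col for col, res in reference_map(aln, row_id).items()}


def classify(
    ortholog_id: str,
    aln: Alignment,
    ref_id: str,
    ref_tbm: ReferenceTBM,
    nearby_window: int = 30,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
) -> PresenceCall:
    """Verdict for one ortholog against one human reference motif.

    A hit whose arginine maps to exactly the column of the reference
    arginine gives ``canonical_aligned`` (canonical configuration) or
    ``relaxed_aligned`` (rx4/rx5); a hit within +/- ``nearby_window``
    columns gives ``nearby_unaligned``; otherwise ``absent``.  The best
    verdict among all hits wins.
    """
    ref_res_to_col = _residue_to_column(aln, ref_id)
    try:
        ref_col = ref_res_to_col[ref_tbm.arg_residue]
    except KeyError:
        raise ValueError(
            f"reference residue {ref_tbm.arg_residue} is beyond the "
            f"{ref_id!r} row ({len(ref_res_to_col)} residues)"
        ) from None
    orth_row = aln.row(ortholog_id)  # KeyError if absent
    orth_res_to_col = _residue_to_column(aln, ortholog_id)
    hits = scan(orth_row.ungapped(), patterns)
    verdict = "absent"
    supporting: list[MotifHit] = []
    for hit in hits:
        col = orth_res_to_col[hit.start]
        if col == ref_col:
            v = (
                "canonical_aligned"
                if hit.configuration == "canonical"
                else "relaxed_aligned"
            )
        elif abs(col - ref_col) <= nearby_window:
            v = "nearby_unaligned"
        else:
            continue
        if _VERDICT_RANK[v] < _VERDICT_RANK[verdict]:
            verdict = v
            supporting = [hit]
        elif v == verdict:
            supporting.append(hit)
    species = orth_row.species or orth_row.id
    return PresenceCall(
        partner=ref_tbm.partner,
        species=species,
        arg_residue=ref_tbm.arg_residue,
        verdict=verdict,
        hits=tuple(supporting),
    )


def _find_row_by_species(aln: Alignment, species: str) -> str | None:
    for r in aln.rows:
        if r.species == species or r.id == species:
            return r.id
    return None


def presence_matrix(
    binder_table: CuratedBinderTable,
    ortholog_alignments: Mapping[str, Alignment],
    species_list: Sequence[str],
    ref_species: str = "human",
    nearby_window: int = 30,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
) -> pd.DataFrame:
    """Presence/absence matrix over (partner motif) x species.

    Rows are indexed by ``(partner, arg_residue)`` — partners with
    several reference motifs get one sub-row per motif.  Species without
    a row in a partner's alignment, and partners without an alignment at
    all, are called ``no_ortholog``.
    """
    rows: dict[tuple[str, int], dict[str, str]] = {}
    for entry in binder_table.entries:
        key = (entry.partner, entry.arg_residue)
        aln = ortholog_alignments.get(entry.partner)
        if aln is None:
            warnings.warn(
                f"no ortholog alignment supplied for partner {entry.partner!r}",
                stacklevel=2,
            )
            rows[key] = {sp: "no_ortholog" for sp in species_list}
            continue
        ref_row_id = _find_row_by_species(aln, ref_species)
        if ref_row_id is None:
            raise ValueError(
                f"alignment for {entry.partner!r} lacks the reference "
                f"species row {ref_species!r}"
            )
        verdicts: dict[str, str] = {}
        for sp in species_list:
            row_id = _find_row_by_species(aln, sp)
            if row_id is None:
                verdicts[sp] = "no_ortholog"
                continue
            call = classify(
                row_id,
                aln,
                ref_row_id,
                entry,
                nearby_window=nearby_window,
                patterns=patterns,
            )
            verdicts[sp] = call.verdict
        rows[key] = verdicts
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["partner", "arg_residue"])
    return pd.DataFrame(list(rows.values()), index=index, columns=list(species_list))
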