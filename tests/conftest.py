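"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re
from functools import lru_cache

import pytest

from tbmevo.seq_io import AlignedSequence, Alignment, SequenceRecord

# ---------------------------------------------------------------------------
# Independent regex oracle for TBM scanning (overlapping-window search).

_RE_CANONICAL = re.compile(r"(?=(R..[ACGP].G..))")
_RE_RX4 = re.compile(r"(?=(R....G..))")
_RE_RX5 = re.compile(r"(?=(R.....G..))")


def regex_scan_oracle(seq: str) -> list[tuple[int, int, str]]:
    """All (start, length, configuration) TBM hits, 1-based starts.

    Length-8 windows are labelled canonical when the canonical grammar
    matches, rx4 otherwise; length-9 windows are rx5.  Mirrors the
    production scanner's contract from an independent implementation.
    """
    hits = []
    canon_starts = {m.start() for m in _RE_CANONICAL.finditer(seq)}
    for m in _RE_RX4.finditer(seq):
        name = "canonical" if m.start() in canon_starts else "rx4"
        hits.append((m.start() + 1, 8, name))
    for m in _RE_RX5.finditer(seq):
        hits.append((m.start() + 1, 9, "rx5"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# Independent exhaustive alignment enumerators (affine gap costs).


def oracle_global_score(a: str, b: str, scheme) -> float:
    """Best global affine-gap score by plain recursion over all
    alignments, memoized on (i, j, state of the previous move)."""
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, scheme.score(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = ge if last == "x" else go + ge
            best = max(best, -cost + rec(i + 1, j, "x"))
        if j < len(b):
            cost = ge if last == "y" else go + ge
            best = max(best, -cost + rec(i, j + 1, "y"))
        return best

    return rec(0, 0, "m")


def oracle_local_score(a: str, b: str, scheme) -> float:
    """Best local score: maximum of the global oracle over every pair of
    substrings, floored at the empty alignment (0)."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, oracle_global_score(a[i0:i1], b[j0:j1], scheme))
    return best


# ---------------------------------------------------------------------------
# Small reusable inputs.


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        rows=(
            AlignedSequence(id="a", residues="AC-DE"),
            AlignedSequence(id="b", residues="ACADE"),
            AlignedSequence(id="c", residues="ACAD-"),
        )
    )


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


def make_record(seq: str, rec_id: str = "s") -> SequenceRecord:
    return SequenceRecord(id=rec_id, residues=seq)
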