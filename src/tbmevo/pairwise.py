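"""Global and local affine-gap protein alignment.

The two aligners fill the classic three-state (Gotoh) recurrences and
trace back deterministically.  A gap of length L costs
``gap_open + L * gap_extend`` (the first gapped residue pays
open + extend); end gaps are penalized in global mode.  Defaults follow
the EMBOSS command-line tools the field uses for this job: BLOSUM62 with
open 10 / extend 0.5 for global (Needle) and open 14 / extend 4 for
local (Matcher) alignments.

Percent identity is reported over the full alignment length including
gapped columns (the EMBOSS "Identity" convention) unless the
shorter-sequence denominator is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .seq_io import SequenceRecord

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric substitution scores over the 20 amino acids plus 'X'
    (which scores 0 against everything) and affine gap penalties."""

    matrix: tuple[tuple[str, str, float], ...]
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        lut: dict[tuple[str, str], float] = {}
        for a, b, s in self.matrix:
            lut[(a, b)] = s
            lut[(b, a)] = s
        object.__setattr__(self, "_lut", lut)

    def score(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        try:
            return self._lut[(a, b)]
        except KeyError:
            raise KeyError(f"no substitution score for pair ({a!r}, {b!r})") from None

    @classmethod
    def from_mapping(
        cls, scores: dict[tuple[str, str], float], gap_open: float, gap_extend: float
    ) -> "ScoringScheme":
        for (a, b), s in scores.items():
            if scores.get((b, a), s) != s:
                raise ValueError(f"asymmetric scores for pair ({a}, {b})")
        return cls(
            matrix=tuple((a, b, float(s)) for (a, b), s in sorted(scores.items())),
            gap_open=gap_open,
            gap_extend=gap_extend,
        )

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 0.5) -> "ScoringScheme":
        return _blosum62(gap_open, gap_extend)

    @classmethod
    def needle_default(cls) -> "ScoringScheme":
        """BLOSUM62, open 10, extend 0.5 — global-alignment default."""
        return cls.blosum62(10.0, 0.5)

    @classmethod
    def matcher_default(cls) -> "ScoringScheme":
        """BLOSUM62, open 14, extend 4 — local-alignment default."""
        return cls.blosum62(14.0, 4.0)


@lru_cache(maxsize=None)
def _blosum62(gap_open: float, gap_extend: float) -> ScoringScheme:
    mat = substitution_matrices.load("BLOSUM62")
    entries = []
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for i, a in enumerate(aas):
        for b in aas[i:]:
            entries.append((a, b, float(mat[a, b])))
    return ScoringScheme(
        matrix=tuple(entries), gap_open=gap_open, gap_extend=gap_extend
    )


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of a pairwise alignment; gapped strings of equal length."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("gap aligned to gap")

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)

    @property
    def identity_count(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )


def percent_identity(p: PairwiseAlignment, denominator: str = "alignment") -> float:
    """Percent identity of a pairwise alignment.

    ``denominator="alignment"`` (default) counts all columns including
    gaps; ``"shorter"`` divides by the shorter ungapped sequence length.
    """
    if p.alignment_length == 0:
        raise ValueError("percent identity is undefined for an empty alignment")
    if denominator == "alignment":
        denom = p.alignment_length
    elif denominator == "shorter":
        denom = min(
            len(p.aligned_a.replace("-", "")), len(p.aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * p.identity_count / denom


# ---------------------------------------------------------------------------
# DP internals.  States: M = residues aligned, X = gap in b (consumes a,
# "up"), Y = gap in a (consumes b, "left").  Tie-breaks are fixed —
# state preference M > X > Y everywhere — so tracebacks are reproducible.

_M, _X, _Y = 0, 1, 2


def _fill_global(a: str, b: str, s: ScoringScheme):
    n, m = len(a), len(b)
    go, ge = s.gap_open, s.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = s.score(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(
                M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge
            )
            Y[i, j] = max(
                M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge
            )
    return M, X, Y


def _best_state(m: float, x: float, y: float) -> int:
    # preference M > X > Y on ties
    if m >= x and m >= y:
        return _M
    if x >= y:
        return _X
    return _Y


def global_align(
    a: SequenceRecord, b: SequenceRecord, s: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap global (Needleman-Wunsch) alignment."""
    if s is None:
        s = ScoringScheme.needle_default()
    sa, sb = a.residues, b.residues
    M, X, Y = _fill_global(sa, sb, s)
    n, m = len(sa), len(sb)
    go, ge = s.gap_open, s.gap_extend
    state = _best_state(M[n, m], X[n, m], Y[n, m])
    score = (M[n, m], X[n, m], Y[n, m])[state]
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            target = M[i, j] - s.score(sa[i - 1], sb[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, val in ((_M, M[i, j]), (_X, X[i, j]), (_Y, Y[i, j])):
                if abs(val - target) < eps:
                    state = cand
                    break
        elif state == _X:
            out_a.append(sa[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if abs(M[i, j] - go - ge - here) < eps:
                state = _M
            elif abs(X[i, j] - ge - here) < eps:
                state = _X
            else:
                state = _Y
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] - go - ge - here) < eps:
                state = _M
            elif abs(X[i, j] - go - ge - here) < eps:
                state = _X
            else:
                state = _Y
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        mode="global",
    )


def local_align(
    a: SequenceRecord, b: SequenceRecord, s: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap local (Smith-Waterman) alignment.

    When every pairwise residue score is negative the empty alignment
    (score 0) is returned.
    """
    if s is None:
        s = ScoringScheme.matcher_default()
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    go, ge = s.gap_open, s.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, :] = NEG_INF
    M[:, 0] = NEG_INF
    best = (0.0, 0, 0)  # (score, i, j); lowest (i, j) wins ties
    for i in range(1, n + 1):
        ai = sa[i - 1]
        for j in range(1, m + 1):
            sub = s.score(ai, sb[j - 1])
            prev = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = prev + sub
            X[i, j] = max(
                M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge
            )
            Y[i, j] = max(
                M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge
            )
            if M[i, j] > best[0] + 1e-12:
                best = (float(M[i, j]), i, j)
    score, bi, bj = best
    if score <= 0.0:
        return PairwiseAlignment(
            id_a=a.id, id_b=b.id, aligned_a="", aligned_b="", score=0.0, mode="local"
        )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = bi, bj, _M
    eps = 1e-9
    while True:
        if state == _M:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            target = M[i, j] - s.score(sa[i - 1], sb[j - 1])
            i, j = i - 1, j - 1
            if abs(target) < eps and not (
                i > 0 and j > 0 and (
                    abs(M[i, j] - target) < eps
                    or abs(X[i, j] - target) < eps
                    or abs(Y[i, j] - target) < eps
                )
            ):
                break
            found = False
            for cand, val in (
                (_M, M[i, j] if i > 0 and j > 0 else NEG_INF),
                (_X, X[i, j] if i > 0 else NEG_INF),
                (_Y, Y[i, j] if j > 0 else NEG_INF),
            ):
                if val != NEG_INF and abs(val - target) < eps:
                    state = cand
                    found = True
                    break
            if not found:
                break  # alignment starts here (prev contribution was the 0 state)
        elif state == _X:
            out_a.append(sa[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if abs(M[i, j] - go - ge - here) < eps:
                state = _M
            elif abs(X[i, j] - ge - here) < eps:
                state = _X
            else:
                state = _Y
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] - go - ge - here) < eps:
                state = _M
            elif abs(X[i, j] - go - ge - here) < eps:
                state = _X
            else:
                state = _Y
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=score,
        mode="local",
    )
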