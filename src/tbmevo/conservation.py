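"""Position-specific conservation profiling of an MSA.

Profiles are anchored to a reference row: only columns where the
reference is ungapped are reported, each keyed by the reference residue
number.  Conservation per column is summarized as

* ``distinct_residues`` — the number of different amino-acid identities
  among the non-gap symbols ('X' counts as its own symbol),
* ``gap_fraction`` — gaps / rows,
* ``grade`` — a 1-9 conservation grade (9 = most conserved) obtained by
  banding the diversity count into nine equal-width bins between 1 and
  the largest diversity observed in the alignment.  This is a
  transparent diversity-based surrogate for phylogeny-aware Bayesian
  rate grades; it uses no evolutionary model.
* ``strictly_conserved`` — a single non-'X' identity with no gaps.

Pairwise identity between rows of the same MSA divides identical
matched columns by the columns where at least one of the two rows is
non-gap, so columns gapped in both rows carry no weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .seq_io import GAP, Alignment


def column_diversity(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column ``(distinct_residues, gap_fraction)`` arrays."""
    ncols, nrows = aln.ncols, aln.nrows
    distinct = np.zeros(ncols, dtype=int)
    gap_fraction = np.zeros(ncols, dtype=float)
    for j in range(ncols):
        col = aln.column(j + 1)
        gaps = col.count(GAP)
        distinct[j] = len(set(col) - {GAP})
        gap_fraction[j] = gaps / nrows
    return distinct, gap_fraction


def reference_map(aln: Alignment, ref_id: str) -> dict[int, int]:
    """Map alignment column -> reference residue number (both 1-based),
    defined on the columns where the reference row is ungapped."""
    row = aln.row(ref_id)  # KeyError if absent
    mapping: dict[int, int] = {}
    res = 0
    for j, ch in enumerate(row.residues, start=1):
        if ch != GAP:
            res += 1
            mapping[j] = res
    return mapping


def _grades(distinct: np.ndarray) -> np.ndarray:
    """Band diversity counts into grades 9 (least diverse) .. 1 (most).

    Bins are equal-width over [1, max(distinct)]; with no diversity at
    all every column is grade 9.  The grade is monotonically
    non-increasing in the diversity count.
    """
    dmax = int(distinct.max(initial=1))
    if dmax <= 1:
        return np.full(distinct.shape, 9, dtype=int)
    width = (dmax - 1) / 9.0
    bins = np.minimum(((distinct - 1) / width).astype(int), 8)
    return 9 - bins


def profile(aln: Alignment, ref_id: str) -> pd.DataFrame:
    """Conservation profile projected onto the reference row.

    Returns a DataFrame with one row per reference residue and columns
    ``residue, column, ref_aa, distinct_residues, gap_fraction, grade,
    strictly_conserved``.
    """
    distinct, gap_fraction = column_diversity(aln)
    grades = _grades(distinct)
    refmap = reference_map(aln, ref_id)
    ref_row = aln.row(ref_id)
    rows = []
    for col, res in sorted(refmap.items()):
        j = col - 1
        col_syms = set(aln.column(col))
        strict = (
            distinct[j] == 1 and gap_fraction[j] == 0.0 and "X" not in col_syms
        )
        rows.append(
            {
                "residue": res,
                "column": col,
                "ref_aa": ref_row.residues[j],
                "distinct_residues": int(distinct[j]),
                "gap_fraction": float(gap_fraction[j]),
                "grade": int(grades[j]),
                "strictly_conserved": bool(strict),
            }
        )
    return pd.DataFrame(rows)


def strictly_conserved_residues(aln: Alignment, ref_id: str) -> list[int]:
    """Reference residue numbers of the strictly conserved columns."""
    prof = profile(aln, ref_id)
    return prof.loc[prof["strictly_conserved"], "residue"].tolist()


def msa_identity_matrix(aln: Alignment) -> pd.DataFrame:
    """Symmetric percent-identity matrix between all rows of an MSA.

    Identity of a pair = identical non-gap matched columns over columns
    where at least one of the two rows is non-gap, x 100.  Diagonal is
    100 by definition.
    """
    ids = aln.ids
    arr = np.array([list(r.residues) for r in aln.rows])
    n = len(ids)
    out = np.full((n, n), 100.0)
    nongap = arr != GAP
    for i in range(n):
        for k in range(i + 1, n):
            either = nongap[i] | nongap[k]
            denom = int(either.sum())
            if denom == 0:
                ident = 100.0
            else:
                same = (arr[i] == arr[k]) & nongap[i] & nongap[k]
                ident = 100.0 * int(same.sum()) / denom
            out[i, k] = out[k, i] = ident
    return pd.DataFrame(out, index=ids, columns=ids)
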