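"""Distance-based phylogeny reconstruction with column-resampling bootstrap.

Distances come from an MSA as p-distances (fraction of differing sites
over columns where both rows are ungapped) or Poisson-corrected
distances ``-ln(1 - p)``; saturated pairs (p >= 0.95) are capped at a
configured maximum.  Trees are built with classical neighbor joining
(Saitou-Nei Q-criterion) with a lowest-index tie-break and negative
branch lengths clamped to zero, and serialized as Newick through
Bio.Phylo.  Bootstrap support for each internal edge of the full-data
tree is the percentage of column-resampled replicate trees containing
the same bipartition.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .seq_io import GAP, Alignment

PhyloTree = Tree


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon list."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "values", values)
        n = len(taxa)
        if values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.taxa)


def distance_from_alignment(
    aln: Alignment, model: str = "poisson", max_distance: float = 10.0
) -> DistanceMatrix:
    """Pairwise distances from an MSA under the ``p`` or ``poisson`` model."""
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    arr = np.array([list(r.residues) for r in aln.rows])
    nongap = arr != GAP
    ids = aln.ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            both = nongap[i] & nongap[k]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[k]!r}"
                )
            p = float(((arr[i] != arr[k]) & both).sum()) / m
            if model == "p":
                d = p
            elif p >= 0.95:
                d = max_distance
            else:
                d = -math.log1p(-p)
            out[i, k] = out[k, i] = d
    return DistanceMatrix(taxa=tuple(ids), values=out)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ tree; ties in the Q-criterion break toward the
    lowest (i, j) pair, negative branch lengths clamp to zero.  The
    returned tree is unrooted (trifurcating root clade)."""
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=t) for t in dm.taxa]
    active = list(range(dm.n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = Clade(clades=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]
    # resolve the final three nodes with the three-point formulas
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].branch_length = max(length, 0.0)
    root = Clade(clades=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Newick serialization and bipartitions


def to_newick(tree: PhyloTree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip() + "\n"


def from_newick(text: str) -> PhyloTree:
    return Phylo.read(io.StringIO(text), "newick")


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    side not containing the lexicographically smallest taxon."""
    leaves = sorted(t.name for t in tree.get_terminals())
    anchor = leaves[0]
    full = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds (symmetric bipartition-difference) distance."""
    return len(bipartitions(a) ^ bipartitions(b))


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    taxa = sorted(t.name for t in tree.get_terminals())
    n = len(taxa)
    out = np.zeros((n, n))
    # accumulate depths from the root once, then use LCA-free pairwise sums
    for i in range(n):
        for k in range(i + 1, n):
            dist = tree.distance(taxa[i], taxa[k])
            out[i, k] = out[k, i] = dist
    return DistanceMatrix(taxa=tuple(taxa), values=out)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_alignment(aln: Alignment, cols: np.ndarray) -> Alignment:
    from .seq_io import AlignedSequence

    rows = []
    for r in aln.rows:
        residues = "".join(r.residues[c] for c in cols)
        rows.append(
            AlignedSequence(
                id=r.id, residues=residues, description=r.description, species=r.species
            )
        )
    return Alignment(rows=tuple(rows))


def bootstrap(
    aln: Alignment,
    n_replicates: int,
    seed: int,
    model: str = "poisson",
    max_distance: float = 10.0,
) -> PhyloTree:
    """NJ tree from the full alignment with per-edge bootstrap support.

    Columns are resampled with replacement ``n_replicates`` times from a
    single seeded generator; the support of each internal edge of the
    full-data tree is the percentage of replicate trees containing the
    same bipartition.  Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(distance_from_alignment(aln, model, max_distance))
    target = {bp: 0 for bp in bipartitions(full)}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.ncols, size=aln.ncols)
        rep_aln = _resample_alignment(aln, cols)
        rep_tree = neighbor_joining(
            distance_from_alignment(rep_aln, model, max_distance)
        )
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    leaves = sorted(t.name for t in full.get_terminals())
    anchor = leaves[0]
    fullset = frozenset(leaves)
    for clade in full.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = fullset - side
        if side in target:
            clade.confidence = round(100.0 * target[side] / n_replicates, 1)
    return full
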