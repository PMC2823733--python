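"""Supermatrix phylogenomics: concatenation, block filtering, Kimura
protein distances, neighbour-joining and column-bootstrap support.

The tree-building branch implemented here is the distance one:
concatenate per-gene alignments, drop poorly aligned columns with a
Gblocks-style filter (gap positions allowed up to "half"), compute Kimura
protein distances ``d = -ln(1 - p - 0.2 p^2)`` under pairwise deletion,
agglomerate with standard neighbour-joining, and attach bootstrap
percentages to the bipartitions of the original tree.  Rooting is by
outgroup (re-exported from :mod:`cladesig.tree`).
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass

import numpy as np

from .msa import GAP, MSA
from .tree import PhyloTree, TreeNode, root_with_outgroup  # noqa: F401

_GAP_CODE = ord(GAP)

KIMURA_P_MAX = (-1.0 + math.sqrt(1.8)) / 0.4  # ~0.8541; domain boundary


class PhyloError(ValueError):
    pass


# -- concatenation -------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    msa: MSA
    intervals: list[tuple[str, int, int]]  # (gene_id, start, end) half-open


def concatenate(msas: list[tuple[str, MSA]],
                taxon_policy: str = "strict") -> ConcatenatedAlignment:
    """Append per-gene alignments column-wise in list order.

    ``msas`` is a list of ``(gene_id, MSA)``; sequence ids are taxon ids.
    ``strict`` errors when taxon sets differ; ``pad`` fills absent taxa
    with gap runs for that gene.
    """
    if taxon_policy not in ("strict", "pad"):
        raise PhyloError(f"unknown taxon policy {taxon_policy!r}")
    gene_ids = [g for g, _ in msas]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise PhyloError(f"duplicate gene ids: {dupes}")
    if not msas:
        raise PhyloError("no alignments to concatenate")

    taxa_sets = [set(m.ids) for _, m in msas]
    if taxon_policy == "strict":
        universe = taxa_sets[0]
        for (gid, _), ts in zip(msas, taxa_sets):
            if ts != universe:
                diff = sorted(universe ^ ts)
                raise PhyloError(
                    f"gene {gid!r}: taxon set differs (strict mode): {diff}")
    else:
        universe = set().union(*taxa_sets)
    taxa = sorted(universe)

    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    intervals: list[tuple[str, int, int]] = []
    offset = 0
    for gid, m in msas:
        row_of = dict(zip(m.ids, m.rows))
        for t in taxa:
            chunks[t].append(row_of.get(t, GAP * m.ncol))
        intervals.append((gid, offset, offset + m.ncol))
        offset += m.ncol
    cat = MSA(taxa, ["".join(chunks[t]) for t in taxa])
    return ConcatenatedAlignment(cat, intervals)


# -- block filtering -----------------------------------------------------

@dataclass(frozen=True)
class BlockFilterParams:
    b1: int | None = None      # min seqs for a conserved position (default n//2+1)
    b2: int | None = None      # min seqs for highly conserved (default ceil(0.85 n))
    b3: int = 8                # max contiguous nonconserved stretch
    b4: int = 10               # min block length
    gap_mode: str = "half"     # none | half | all

    def __post_init__(self) -> None:
        if self.gap_mode not in ("none", "half", "all"):
            raise PhyloError(f"unknown gap_mode {self.gap_mode!r}")
        if self.b3 < 1 or self.b4 < 2:
            raise PhyloError("require b3 >= 1 and b4 >= 2")

    def resolved(self, n: int) -> tuple[int, int]:
        b1 = self.b1 if self.b1 is not None else n // 2 + 1
        b2 = self.b2 if self.b2 is not None else math.ceil(0.85 * n)
        if not (b1 <= b2 <= n):
            raise PhyloError(f"require b1 <= b2 <= n (got {b1}, {b2}, {n})")
        return b1, b2


def filter_blocks(aln: MSA, params: BlockFilterParams | None = None
                  ) -> tuple[MSA, list[int]]:
    """Remove poorly aligned columns, Gblocks style.

    Steps: (1) drop columns failing the gap rule; (2) classify columns by
    the count of their most frequent residue (nonconserved < b1, highly
    conserved >= b2); (3) delete contiguous nonconserved stretches longer
    than b3; (4) trim block ends back to highly conserved columns; (5)
    drop blocks shorter than b4.  Returns the filtered alignment and the
    kept original column indices (in order); an empty result only warns.
    """
    params = params or BlockFilterParams()
    n = aln.nseq
    if n < 4:
        raise PhyloError("block filtering requires >= 4 sequences")
    b1, b2 = params.resolved(n)

    def gap_ok(j: int) -> bool:
        frac = sum(1 for r in aln.rows if r[j] == GAP) / n
        if params.gap_mode == "none":
            return frac == 0.0
        if params.gap_mode == "half":
            return frac <= 0.5
        return True

    kept = [j for j in range(aln.ncol) if gap_ok(j)]

    def conservation(j: int) -> str:
        counts: dict[str, int] = {}
        for r in aln.rows:
            ch = r[j]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values()) if counts else 0
        if top < b1:
            return "non"
        return "high" if top >= b2 else "cons"

    klass = {j: conservation(j) for j in kept}

    # (3) remove long nonconserved stretches (over the surviving sequence)
    survivors: list[int] = []
    blocks: list[list[int]] = []
    i = 0
    current: list[int] = []
    while i < len(kept):
        if klass[kept[i]] == "non":
            k = i
            while k < len(kept) and klass[kept[k]] == "non":
                k += 1
            if k - i > params.b3:
                if current:
                    blocks.append(current)
                    current = []
            else:
                current.extend(kept[i:k])
            i = k
        else:
            current.append(kept[i])
            i += 1
    if current:
        blocks.append(current)

    # (4) trim ends to highly conserved columns; (5) length filter
    for block in blocks:
        lo, hi = 0, len(block)
        while lo < hi and klass[block[lo]] != "high":
            lo += 1
        while hi > lo and klass[block[hi - 1]] != "high":
            hi -= 1
        trimmed = block[lo:hi]
        if len(trimmed) >= params.b4:
            survivors.extend(trimmed)

    if not survivors:
        warnings.warn("block filter removed every column")
        return MSA(list(aln.ids), ["" for _ in aln.ids]), []
    return aln.select_columns(survivors), survivors


# -- distances -----------------------------------------------------------

def kimura_distance(p: float) -> float:
    """Kimura protein distance ``-ln(1 - p - 0.2 p^2)``; domain p < ~0.854."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        raise PhyloError(f"Kimura distance undefined at p={p:.6g} (>= {KIMURA_P_MAX:.6g})")
    return -math.log(arg)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("distance matrix shape mismatch")
        if np.isnan(m).any():
            raise PhyloError("distance matrix contains NaN")
        if (m < 0).any():
            raise PhyloError("negative distances")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")

    def to_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "  " +
                         " ".join(f"{x:.8f}" for x in self.matrix[i]) + "\n")


def pairwise_kimura(aln: MSA, site_policy: str = "pairwise_deletion"
                    ) -> DistanceMatrix:
    """Kimura distances from observed difference proportions.

    ``pairwise_deletion`` excludes, per pair, sites gapped in either
    sequence; ``complete_deletion`` keeps only columns ungapped everywhere.
    Errors (naming the pair) on zero comparable sites or a difference
    proportion at/over the domain boundary — no silent capping.
    """
    if site_policy not in ("pairwise_deletion", "complete_deletion"):
        raise PhyloError(f"unknown site policy {site_policy!r}")
    if aln.nseq < 2:
        raise PhyloError("need >= 2 sequences")
    arr = aln.to_array()
    nongap = arr != _GAP_CODE
    if site_policy == "complete_deletion":
        cols = nongap.all(axis=0)
        arr = arr[:, cols]
        nongap = nongap[:, cols]
    n = aln.nseq
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = nongap[i] & nongap[j]
            ncomp = int(comp.sum())
            if ncomp == 0:
                raise PhyloError(
                    f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
            p = float(((arr[i] != arr[j]) & comp).sum()) / ncomp
            try:
                d = kimura_distance(p)
            except PhyloError:
                raise PhyloError(
                    f"Kimura domain violation (p={p:.4f}) for pair "
                    f"({aln.ids[i]}, {aln.ids[j]})") from None
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D)


# -- neighbour joining ---------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbour-joining; returns an unrooted tree.

    Tie-breaking on the Q criterion is by smallest index pair, negative
    branch lengths are clamped to 0 with a warning — both for determinism.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbour joining requires >= 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf
        # argmin of the flattened upper triangle: first occurrence wins,
        # i.e. ties break to the smallest (i, j) index pair
        ii, jj = divmod(int(np.argmin(Q)), m)
        a, b = active[ii], active[jj]
        la = 0.5 * D[a, b] + (r[ii] - r[jj]) / (2 * (m - 2))
        lb = D[a, b] - la
        parent = TreeNode()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        na.length = clamp(la)
        parent.add_child(nb)
        nb.length = clamp(lb)
        # reuse slot a for the new node
        for c in active:
            if c not in (a, b):
                D[a, c] = D[c, a] = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        nodes[a] = parent
        active.remove(b)

    a, b, c = active
    top = TreeNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes[idx]
        top.add_child(node)
        node.length = clamp(ln)
    return PhyloTree(top, rooted=False)


# -- bootstrap -----------------------------------------------------------

def bootstrap_support(aln: MSA, n_reps: int = 1000, seed: int = 0,
                      site_policy: str = "pairwise_deletion"
                      ) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Column bootstrap of the Kimura+NJ tree.

    Resamples alignment columns with replacement (each replicate has the
    original number of columns), rebuilds the tree, and reports, for every
    non-trivial bipartition of the tree built from the full alignment, the
    percentage of replicates containing it.  Fully deterministic for a
    fixed seed.
    """
    if aln.ncol == 0:
        raise PhyloError("empty alignment")
    base_dm = pairwise_kimura(aln, site_policy)
    base_tree = nj_tree(base_dm)
    targets = base_tree.bipartitions()
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.ncol, size=aln.ncol)
        rep = aln.select_columns(cols.tolist())
        rep_tree = nj_tree(pairwise_kimura(rep, site_policy))
        rep_bps = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return base_tree, support


def annotate_supports(tree: PhyloTree,
                      support: dict[frozenset[str], float]) -> PhyloTree:
    """Write support percentages into internal node names of a copy."""
    out = tree.copy()
    all_leaves = frozenset(out.leaf_names())
    ref = min(all_leaves)
    for node in out.root.traverse_preorder():
        if node.is_leaf or node is out.root:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if side in support:
            node.name = f"{support[side]:.0f}"
    return out


def deep_split_support(tree: PhyloTree,
                       support: dict[frozenset[str], float],
                       group: set[str]) -> float | None:
    """Support of the bipartition separating ``group``, if present."""
    all_leaves = frozenset(tree.leaf_names())
    side = frozenset(group)
    if min(all_leaves) in side:
        side = all_leaves - side
    return support.get(side)


def nj_from_msa(aln: MSA, site_policy: str = "pairwise_deletion") -> PhyloTree:
    return nj_tree(pairwise_kimura(aln, site_policy))
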