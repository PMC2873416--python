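"""Distance matrices, neighbor-joining trees and tree comparison.

Trees are unrooted and carried as :class:`skbio.TreeNode` objects (newick
round-trippable).  The NJ implementation fixes the numeric policies needed
for bit-reproducibility: Q-criterion joins with ties broken by the
lexicographically smallest taxon-label pair, and negative branch lengths
clamped to zero with the deficit moved to the sister branch.

Gene-tree vs genome-tree incongruence — the signature of locus-specific
introgression between subspecies — is quantified by the Robinson–Foulds
bipartition distance and by explicit monophyly checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .seqio import GenotypeMatrix, LocusAlignment, MISSING

SATURATED = float("inf")


@dataclass
class DistanceMatrix:
    """Symmetric distances with zero diagonal over labelled taxa."""

    taxa: list[str]
    matrix: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def _pairwise_p(seq_a: str, seq_b: str) -> float:
    """p-distance with pairwise deletion of missing positions."""
    compared = mismatched = 0
    for x, y in zip(seq_a, seq_b):
        if x in MISSING or y in MISSING:
            continue
        compared += 1
        if x != y:
            mismatched += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return mismatched / compared


def _translate(seq: str) -> str:
    """Translate a nucleotide sequence; untranslatable codons become X."""
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_dna_by_id[1]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3].upper()
        if any(b not in "ACGT" for b in codon):
            out.append("X")
        elif codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[codon])
    return "".join(out)


def distance_matrix(source: LocusAlignment | GenotypeMatrix,
                    model: str = "p") -> DistanceMatrix:
    """Pairwise distances under one of four models.

    ``p``             mismatch proportion (pairwise deletion)
    ``jc``            Jukes–Cantor correction of p; p >= 3/4 gives inf
    ``protein_p``     p-distance on translated sequences (X treated missing)
    ``allele_sharing`` 1 − shared-allele fraction on a GenotypeMatrix
    """
    if model == "allele_sharing":
        if not isinstance(source, GenotypeMatrix):
            raise TypeError("allele_sharing requires a GenotypeMatrix")
        g = source.genotypes
        n = len(source.samples)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = (g[i] != -1) & (g[j] != -1)
                if not ok.any():
                    raise ValueError("no comparable sites between samples")
                m[i, j] = m[j, i] = 1.0 - (g[i][ok] == g[j][ok]).mean()
        return DistanceMatrix(list(source.samples), m, model)

    if not isinstance(source, LocusAlignment):
        raise TypeError(f"model {model!r} requires a LocusAlignment")
    seqs = source.sequences
    if model == "protein_p":
        seqs = [_translate(s).replace("X", "N").replace("*", "N")
                for s in seqs]
    n = source.n
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(seqs[i], seqs[j])
            if model == "jc":
                p = SATURATED if p >= 0.75 else \
                    -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            m[i, j] = m[j, i] = p
    return DistanceMatrix(list(source.samples), m, model)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Returns an unrooted tree (trifurcating root node).  Joins follow the
    Q criterion; among tied minima the pair whose sorted label pair is
    lexicographically smallest is joined.  A negative branch length is
    clamped to zero and the deficit moved to its sister branch.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("saturated (infinite) distances cannot be joined")
    d = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    # label used only for deterministic tie-breaking
    labels = list(dm.taxa)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [(tuple(sorted((labels[i], labels[j]))), i, j)
                      for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
                      if i < j]
        _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # resolve the final three lineages on a trifurcating root
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lens = [0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    for node, ln in zip(nodes, lens):
        node.length = float(max(ln, 0.0))
    return TreeNode(children=nodes)


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the lexicographically smallest leaf."""
    leaves = {leaf.name for leaf in tree.tips()}
    anchor = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {leaf.name for leaf in node.tips()}
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        if anchor in side:
            side = leaves - side
        parts.add(frozenset(side))
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    l1 = {leaf.name for leaf in t1.tips()}
    l2 = {leaf.name for leaf in t2.tips()}
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def monophyly_check(tree: TreeNode, taxa_subset: set[str] | list[str]
                    ) -> bool:
    """True iff some edge of the unrooted tree separates exactly
    ``taxa_subset`` from the remaining taxa."""
    subset = frozenset(taxa_subset)
    leaves = {leaf.name for leaf in tree.tips()}
    if not subset or not subset < leaves:
        raise ValueError("subset must be non-empty and proper")
    if len(subset) == 1 or len(leaves - subset) == 1:
        return True  # trivial edge at a leaf
    complement = frozenset(leaves - subset)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if side == subset or side == complement:
            return True
    return False


def bootstrap_support(aln: LocusAlignment, model: str = "jc",
                      reps: int = 100, seed: int = 0
                      ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Site-resampled NJ bootstrap.

    Builds the NJ tree on the full alignment, then ``reps`` trees on
    alignments resampled column-wise with replacement; support for each
    internal edge is the fraction of replicate trees containing its
    bipartition.  Supports are written as internal node names and also
    returned keyed by canonical bipartition.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(distance_matrix(aln, model))
    counts: dict[frozenset[str], int] = {p: 0 for p in _bipartitions(tree)}
    L = aln.length
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        res = LocusAlignment(
            locus_id=aln.locus_id,
            samples=list(aln.samples),
            populations=dict(aln.populations),
            sequences=["".join(s[c] for c in cols) for s in aln.sequences],
            coordinate_offset=aln.coordinate_offset,
        )
        try:
            rep_parts = _bipartitions(neighbor_joining(
                distance_matrix(res, model)))
        except ValueError:  # saturated replicate
            continue
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    support = {p: c / reps for p, c in counts.items()}
    anchor = min(leaf.name for leaf in tree.tips())
    leaves = {leaf.name for leaf in tree.tips()}
    for node in tree.non_tips(include_self=False):
        side = {leaf.name for leaf in node.tips()}
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        key = frozenset(leaves - side if anchor in side else side)
        node.name = f"{support[key]:.3f}"
    return tree, support
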