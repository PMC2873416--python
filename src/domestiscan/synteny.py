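"""Homolog pairing and colinearity chaining between two genomic regions.

Detects segmental duplication the way flanking-gene synteny is usually
established: CDS sequences from the two regions are compared all-vs-all
with a scored local aligner, reciprocal best hits passing identity and
coverage thresholds become homolog pairs, and the longest chain of pairs
monotone in both regions' gene orders (run in both orientations) is the
synteny block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO


@dataclass
class Gene:
    gene_id: str
    start: int    # 1-based inclusive
    end: int
    strand: str
    cds: str


@dataclass
class RegionGeneSet:
    """Ordered genes of one genomic region."""

    region_id: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.start)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @classmethod
    def read(cls, annotation_tsv: str | Path, cds_fasta: str | Path,
             region_id: str | None = None) -> "RegionGeneSet":
        """GFF-like TSV (gene_id, start, end, strand) plus a CDS FASTA."""
        cds = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(cds_fasta), "fasta")}
        genes = []
        with open(annotation_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "gene_id":
                    continue
                gid = row[0]
                if gid not in cds:
                    raise ValueError(f"gene {gid!r} missing from CDS FASTA")
                genes.append(Gene(gid, int(row[1]), int(row[2]), row[3],
                                  cds[gid]))
        return cls(region_id or Path(annotation_tsv).stem, genes)


@dataclass
class HomologPair:
    gene_a: str
    gene_b: str
    score: float
    identity: float
    coverage: float


@dataclass
class SyntenyBlock:
    pairs: list[HomologPair]
    orientation: str  # 'same' or 'inverted'


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def _align_stats(a: str, b: str, aligner: Align.PairwiseAligner
                 ) -> tuple[float, float, float]:
    """(score, identity over aligned columns, coverage of shorter CDS)."""
    if not a or not b:
        return 0.0, 0.0, 0.0
    alignment = aligner.align(a, b)[0]
    matches = aligned_len = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        aligned_len += len(seg_a)
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    if aligned_len == 0:
        return 0.0, 0.0, 0.0
    identity = matches / aligned_len
    coverage = aligned_len / min(len(a), len(b))
    return float(alignment.score), identity, coverage


def homolog_pairs(set_a: RegionGeneSet, set_b: RegionGeneSet,
                  min_identity: float = 0.6,
                  min_coverage: float = 0.5) -> list[HomologPair]:
    """Reciprocal-best-hit homolog pairs between two regions.

    Each gene's best partner (by local alignment score) must be mutual,
    with identity >= ``min_identity`` over aligned columns and aligned
    coverage >= ``min_coverage`` of the shorter CDS.  Pairs are returned
    in region-A gene order.
    """
    aligner = _aligner()
    stats: dict[tuple[str, str], tuple[float, float, float]] = {}
    for ga in set_a.genes:
        for gb in set_b.genes:
            stats[(ga.gene_id, gb.gene_id)] = _align_stats(
                ga.cds, gb.cds, aligner)

    def best(gene: str, partners: list[str], key) -> str | None:
        scored = [(stats[key(gene, p)][0], p) for p in partners]
        top = max(scored) if scored else (0.0, None)
        return top[1] if top[0] > 0 else None

    best_a = {ga: best(ga, set_b.gene_ids, lambda g, p: (g, p))
              for ga in set_a.gene_ids}
    best_b = {gb: best(gb, set_a.gene_ids, lambda g, p: (p, g))
              for gb in set_b.gene_ids}
    pairs = []
    for ga in set_a.gene_ids:
        gb = best_a[ga]
        if gb is None or best_b[gb] != ga:
            continue
        score, identity, coverage = stats[(ga, gb)]
        if identity >= min_identity and coverage >= min_coverage:
            pairs.append(HomologPair(ga, gb, score, identity, coverage))
    return pairs


def collinear_chain(pairs: list[HomologPair],
                    set_a: RegionGeneSet, set_b: RegionGeneSet
                    ) -> SyntenyBlock:
    """Longest chain of homolog pairs monotone in both gene orders.

    Solved as a longest-increasing-subsequence over region-B ranks after
    sorting by region-A rank, run for both orientations (B ranks as-is and
    reversed); the better chain is kept, ties preferring 'same'
    orientation and then the chain whose first pair has the lower A-rank.
    """
    if not pairs:
        raise ValueError("need at least one homolog pair")
    rank_a = {g: i for i, g in enumerate(set_a.gene_ids)}
    rank_b = {g: i for i, g in enumerate(set_b.gene_ids)}
    ordered = sorted(pairs, key=lambda p: rank_a[p.gene_a])

    def lis(seq: list[int]) -> list[int]:
        """Indices of one longest strictly increasing subsequence,
        preferring the earliest-starting chain among ties."""
        n = len(seq)
        best_len = [1] * n          # longest chain ending at i
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if seq[j] < seq[i] and best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
        # earliest end index achieving the maximum gives the
        # lowest-starting chain under left-to-right DP
        end = min(range(n), key=lambda i: (-best_len[i], i))
        chain = []
        while end != -1:
            chain.append(end)
            end = prev[end]
        return chain[::-1]

    b_ranks = [rank_b[p.gene_b] for p in ordered]
    same = lis(b_ranks)
    inverted = lis([-r for r in b_ranks])
    if len(same) >= len(inverted):
        idx, orientation = same, "same"
    else:
        idx, orientation = inverted, "inverted"
    return SyntenyBlock(pairs=[ordered[i] for i in idx],
                        orientation=orientation)


def write_block_tsv(block: SyntenyBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tidentity\tcoverage\torientation\n")
        for p in block.pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:.1f}\t"
                     f"{p.identity:.4f}\t{p.coverage:.4f}\t"
                     f"{block.orientation}\n")
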