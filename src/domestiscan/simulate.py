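"""Synthetic resequencing panels with domestication structure.

Emulates the sampling design of a cultivated/wild germplasm study: two
cultivated subpopulations (japonica, indica) each derived from a wild
population through an independent domestication bottleneck, an optional
selective sweep or introgression event at a focal locus, and a single
distant outgroup sequence.  Genealogies follow the Kingman coalescent with
piecewise-constant rates (time in units of 2N generations of the wild
population); mutations follow the infinite-sites model: Poisson(θ·ℓ/2)
mutations dropped on branches, each at a distinct alignment column.

The sweep is a star-coalescence approximation: at the sweep time every
cultivated lineage at the focal locus coalesces at once, which reproduces
the qualitative sweep signatures (diversity deficit, excess of rare
variants, negative Tajima's D) without modelling selection coefficients.
Introgression additionally merges the two cultivated subpopulations into
one star, so the focal-locus gene tree clusters all cultivars while the
genome-wide SNP tree keeps them separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .seqio import GenotypeMatrix, LocusAlignment

BASES = np.array(list("ACGT"))


@dataclass
class SimScenario:
    """Full parameterization of the synthetic demography.

    Sample sizes default to the 25-cultivar / 25-wild germplasm design.
    ``theta`` is the per-locus scaled mutation rate 4Nμℓ; the default
    gives a per-site wild diversity of 0.01 at the default 4.6-kb length,
    matching observed wild-rice nucleotide diversity.
    The bottleneck is (time, severity): going back in time each cultivated
    subpopulation's coalescence intensity is multiplied by 1/severity for
    ``bottleneck_duration`` starting at that time, after which it merges
    into the wild population.  ``outgroup_divergence`` is the expected
    substitutions per site separating the outgroup sequence.
    """

    seed: int
    n_wild: int = 25
    n_japonica: int = 13
    n_indica: int = 12
    L: int = 4600
    theta: float = 46.0
    bottleneck_time: float = 0.1
    bottleneck_severity: float = 0.15
    bottleneck_duration: float = 0.1
    sweep: bool = False
    sweep_time: float = 0.1  # fixation at the domestication-bottleneck onset
    introgression: bool = False
    outgroup_divergence: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_wild, self.n_japonica, self.n_indica) < 2:
            raise ValueError("each population needs >= 2 samples")
        if not 0.0 < self.bottleneck_severity <= 1.0:
            raise ValueError("severity must be in (0, 1]")
        if self.theta < 0 or self.L < 1 or self.outgroup_divergence < 0:
            raise ValueError("theta, L and outgroup_divergence must be >= 0")
        if (self.sweep or self.introgression) and \
                not 0.0 < self.sweep_time <= self.bottleneck_time:
            raise ValueError("sweep_time must be in (0, bottleneck_time]")


@dataclass
class _Node:
    idx: int
    time: float
    children: list[int] = field(default_factory=list)
    name: str | None = None


@dataclass
class SimTruth:
    """Ground truth backing one simulated alignment."""

    node_times: list[float]
    node_children: list[list[int]]
    sample_nodes: dict[str, int]          # sample name -> leaf node index
    mutations: list[tuple[int, int]]      # (column, branch child-node idx)
    sweep_linked: set[int]                # columns on post-sweep cultivated branches
    populations: dict[str, str]


def _coalesce(active: list[int], nodes: list[_Node], t0: float, t1: float,
              rate_mult: float, rng: np.random.Generator,
              down_to: int = 1) -> float:
    """Coalesce ``active`` lineages between t0 and t1 at scaled rate."""
    t = t0
    while len(active) > down_to:
        k = len(active)
        rate = rate_mult * k * (k - 1) / 2.0
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > t1:
            return t1
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        parent = _Node(idx=len(nodes), time=t,
                       children=[active[i], active[j]])
        nodes.append(parent)
        active[:] = [a for m, a in enumerate(active) if m not in (i, j)]
        active.append(parent.idx)
    return t


def _star_coalesce(active: list[int], nodes: list[_Node], t: float) -> None:
    """Merge all lineages into one ancestor at time t (sweep fixation)."""
    if len(active) < 2:
        return
    parent = _Node(idx=len(nodes), time=t, children=list(active))
    nodes.append(parent)
    active[:] = [parent.idx]


def simulate_locus(scn: SimScenario, locus_id: str = "locus",
                   rng: np.random.Generator | None = None,
                   include_outgroup: bool = True
                   ) -> tuple[LocusAlignment, SimTruth]:
    """Simulate one locus alignment (plus outgroup) with ground truth."""
    rng = rng if rng is not None else np.random.default_rng(scn.seed)

    nodes: list[_Node] = []
    pops: dict[str, list[int]] = {}
    populations: dict[str, str] = {}
    sample_nodes: dict[str, int] = {}
    for pop, count in (("japonica", scn.n_japonica),
                       ("indica", scn.n_indica), ("wild", scn.n_wild)):
        pops[pop] = []
        for i in range(count):
            name = f"{pop}_{i + 1:02d}"
            node = _Node(idx=len(nodes), time=0.0, name=name)
            nodes.append(node)
            pops[pop].append(node.idx)
            populations[name] = pop
            sample_nodes[name] = node.idx

    t_b = scn.bottleneck_time
    t_end_b = t_b + scn.bottleneck_duration
    sweep_parents: list[int] = []

    if scn.sweep or scn.introgression:
        # neutral drift within each pop until the sweep fixation time
        for pop in ("japonica", "indica", "wild"):
            _coalesce(pops[pop], nodes, 0.0, scn.sweep_time, 1.0, rng)
        if scn.introgression:
            merged = pops["japonica"] + pops["indica"]
            _star_coalesce(merged, nodes, scn.sweep_time)
            pops["japonica"], pops["indica"] = merged, []
        else:
            _star_coalesce(pops["japonica"], nodes, scn.sweep_time)
            _star_coalesce(pops["indica"], nodes, scn.sweep_time)
        sweep_parents = [pops[p][0] for p in ("japonica", "indica")
                         if pops[p]]
        t_resume = scn.sweep_time
    else:
        t_resume = 0.0

    for pop in ("japonica", "indica"):
        _coalesce(pops[pop], nodes, t_resume, t_b, 1.0, rng)
        _coalesce(pops[pop], nodes, t_b, t_end_b,
                  1.0 / scn.bottleneck_severity, rng)
    _coalesce(pops["wild"], nodes, t_resume, t_end_b, 1.0, rng)
    ancestral = pops["japonica"] + pops["indica"] + pops["wild"]
    _coalesce(ancestral, nodes, t_end_b, np.inf, 1.0, rng, down_to=1)
    root = ancestral[0]

    # branch lengths indexed by child node
    parent_of: dict[int, int] = {}
    for node in nodes:
        for ch in node.children:
            parent_of[ch] = node.idx
    branch_nodes = [i for i in range(len(nodes)) if i != root]
    branch_lens = np.array([nodes[parent_of[i]].time - nodes[i].time
                            for i in branch_nodes])
    total_len = float(branch_lens.sum())

    n_mut = rng.poisson(scn.theta * total_len / 2.0) if scn.theta > 0 else 0
    n_out = rng.poisson(scn.L * scn.outgroup_divergence) \
        if include_outgroup else 0
    if n_mut + n_out > scn.L:
        raise ValueError(
            f"infinite-sites model needs L >= mutation count "
            f"({n_mut + n_out} > {scn.L}); increase L or lower theta")
    columns = rng.choice(scn.L, size=n_mut + n_out, replace=False)
    mut_cols, out_cols = columns[:n_mut], columns[n_mut:]
    if n_mut:
        probs = branch_lens / total_len
        mut_branches = rng.choice(len(branch_nodes), size=n_mut, p=probs)
    else:
        mut_branches = np.array([], dtype=int)

    anc_seq = rng.integers(0, 4, size=scn.L)
    # derived base differs from ancestral at each mutated column
    shifts = rng.integers(1, 4, size=n_mut + n_out)

    # leaves under each branch (child node)
    leaves_below: dict[int, set[int]] = {}

    def _collect(i: int) -> set[int]:
        if i in leaves_below:
            return leaves_below[i]
        node = nodes[i]
        got = {i} if not node.children else \
            set().union(*(_collect(c) for c in node.children))
        leaves_below[i] = got
        return got

    _collect(root)

    seqs = {name: anc_seq.copy() for name in sample_nodes}
    leaf_name = {v: k for k, v in sample_nodes.items()}
    mutations = []
    sweep_linked: set[int] = set()
    sweep_desc: set[int] = set()
    for sp in sweep_parents:
        sweep_desc |= {i for i in leaves_below if
                       leaves_below[i] <= leaves_below[sp] and i != sp}
    for m in range(n_mut):
        col = int(mut_cols[m])
        child = branch_nodes[int(mut_branches[m])]
        mutations.append((col, child))
        if child in sweep_desc or child in sweep_parents:
            sweep_linked.add(col)
        derived = (anc_seq[col] + shifts[m]) % 4
        for leaf in leaves_below[child]:
            seqs[leaf_name[leaf]][col] = derived

    samples = list(sample_nodes)
    sequences = ["".join(BASES[s]) for s in (seqs[n] for n in samples)]
    if include_outgroup:
        og = anc_seq.copy()
        for m, col in enumerate(out_cols):
            og[col] = (anc_seq[col] + shifts[n_mut + m]) % 4
        samples.append("outgroup_1")
        sequences.append("".join(BASES[og]))
        populations = dict(populations)
        populations["outgroup_1"] = "outgroup"

    aln = LocusAlignment(locus_id=locus_id, samples=samples,
                         populations=populations, sequences=sequences)
    truth = SimTruth(
        node_times=[n.time for n in nodes],
        node_children=[list(n.children) for n in nodes],
        sample_nodes=sample_nodes,
        mutations=mutations,
        sweep_linked=sweep_linked,
        populations=dict(populations),
    )
    return aln, truth


def simulate_germplasm_panel(scn: SimScenario, n_loci: int = 5,
                             focal_locus_index: int = 0
                             ) -> tuple[list[LocusAlignment],
                                        list[SimTruth], GenotypeMatrix]:
    """A multi-locus panel: the focal locus carries the scenario's sweep /
    introgression flags, every other locus evolves neutrally under the
    same demography.  The genotype matrix pools biallelic derived-allele
    codes across non-focal loci (the genome-wide SNP stand-in)."""
    if n_loci < 2:
        raise ValueError("panel needs >= 2 loci")
    if not 0 <= focal_locus_index < n_loci:
        raise ValueError("focal_locus_index out of range")
    rng = np.random.default_rng(scn.seed)
    neutral = replace(scn, sweep=False, introgression=False)
    alignments, truths = [], []
    geno_cols, site_ids = [], []
    ingroup: list[str] | None = None
    for li in range(n_loci):
        locus_scn = scn if li == focal_locus_index else neutral
        aln, truth = simulate_locus(locus_scn, locus_id=f"locus_{li + 1}",
                                    rng=rng)
        alignments.append(aln)
        truths.append(truth)
        if li == focal_locus_index:
            continue
        sub = aln.subset(["japonica", "indica", "wild"])
        if ingroup is None:
            ingroup = sub.samples
        arr = sub.to_array()
        for col, _child in truth.mutations:
            column = arr[:, col]
            if len(set(column)) == 2:  # biallelic among the ingroup
                alleles, counts = np.unique(column, return_counts=True)
                minor = alleles[np.argmin(counts)]
                geno_cols.append((column == minor).astype(np.int8))
                site_ids.append(f"{aln.locus_id}_{col + 1}")
    genotypes = np.array(geno_cols, dtype=np.int8).T if geno_cols else \
        np.zeros((len(ingroup or []), 0), dtype=np.int8)
    gm = GenotypeMatrix(samples=list(ingroup or []), site_ids=site_ids,
                        genotypes=genotypes)
    return alignments, truths, gm


STOPS = {"TAA", "TAG", "TGA"}


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(BASES[rng.integers(0, 4, size=3)])
        if codon not in STOPS:
            codons.append(codon)
    return codons


def evolve_codon_pair(n_codons: int, omega: float, target_pS: float,
                      seed: int) -> tuple[str, str]:
    """Evolve two coding sequences from a common ancestor under a fixed
    nonsynonymous/synonymous acceptance ratio ω.

    Candidate point mutations are proposed uniformly; synonymous changes
    are always accepted, nonsynonymous accepted with probability ω, and
    changes creating stop codons rejected.  Substitution proceeds,
    alternating between the two copies, until the accepted synonymous
    substitutions reach ``target_pS`` per synonymous site (NG86 site count
    of the ancestor).  Used to calibrate the Ka/Ks estimator.
    """
    from .kaks import ng86_sites

    if omega <= 0:
        raise ValueError("omega must be > 0")
    if not 0.0 < target_pS < 0.7:
        raise ValueError("target_pS must be in (0, 0.7)")
    rng = np.random.default_rng(seed)
    ancestor = _random_coding_sequence(n_codons, rng)
    s_sites = sum(ng86_sites(c)[0] for c in ancestor)
    target_syn = int(round(target_pS * s_sites))
    seqs = [list(ancestor), list(ancestor)]
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_dna_by_id[1].forward_table

    syn_done = 0
    which = 0
    while syn_done < target_syn:
        seq = seqs[which]
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        old = seq[ci]
        new_base = BASES[int(rng.integers(0, 4))]
        if new_base == old[pos]:
            continue
        new = old[:pos] + new_base + old[pos + 1:]
        if new in STOPS:
            continue
        if table[new] == table[old]:
            seq[ci] = new
            syn_done += 1
            which = 1 - which
        elif rng.random() < omega:
            seq[ci] = new
            which = 1 - which
    return "".join(seqs[0]), "".join(seqs[1])
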