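# Methods

`domestiscan` analyzes resequencing panels of a crop and its wild
relative for the molecular signatures of duplication and
domestication-selection at a candidate locus: reduced nucleotide
diversity in cultivars, a skewed frequency spectrum, a distorted
polymorphism/divergence ratio, haplotype homogenization, near-fixed
functional differences, and locus-specific gene-tree/genome-tree
discordance.  This note records the models, the defaults and why they
were chosen, the numerical policies, and what the synthetic panels do
and do not demonstrate.

## Diversity statistics

For a population sample of n aligned sequences, the package computes
segregating sites S, per-site nucleotide diversity
θπ = (mean pairwise Hamming distance)/L_eff, Watterson's
θW = S/(a₁·L_eff) with a₁ = Σ_{i<n} 1/i, and Tajima's D

    D = (π̂ − S/a₁) / sqrt(e₁ S + e₂ S (S−1)),

with π̂ the *total* mean pairwise difference and e₁, e₂ the standard
constants derived from n.  D is undefined (reported `NA`) when S = 0,
and also at n = 3, where both variance constants vanish identically.

**Missing data.** Within the analyzed population, any column containing
`-` or `N` is dropped entirely (site-wise complete deletion), and L_eff
counts the retained columns.  This is the conventional behavior of
interactive polymorphism software and keeps every pair of sequences
compared over the same sites; the cost is that a single badly sequenced
sample can shrink L_eff for the whole population, so heavily gapped
samples should be removed before analysis.

**Significance of D** is assessed by parametric bootstrap under the
standard neutral coalescent conditional on the observed S (default
10,000 seeded replicates), not the beta approximation: the replicate
genealogy is a random-merge Kingman tree, mutations are placed on
branches proportionally to length, and D is recomputed.  This is
reproducible and makes the null explicit.

**Haplotype typing** uses exact sequence identity over retained columns;
no single-mismatch clustering.  Types are numbered by descending
frequency (ties by first occurrence), and haplotype diversity is
n(1 − Σp_i²)/(n − 1).

**Near-fixed differences** between populations A and B report sites
where A's major allele has frequency ≥ t in A and ≤ 1 − t in B, with
t = 0.95 by default — the "almost fixed" criterion appropriate for a
domestication target where a few heterogeneous accessions are expected.

## HKA test

Under neutrality the ratio of within-species polymorphism to divergence
from an outgroup is shared across loci.  Two implementations are
provided because printed p-values from legacy software are generally
not reconstructible without the original per-site data:

* `hka1987` — the classic two-locus moment-equation form.  Per-site
  θ̂_i and a common divergence parameter T̂ (with outgroup/ingroup size
  ratio f, default 1) are fitted so that expected S and D totals match
  the observations (the fit conserves ΣE[S] = ΣS and ΣE[D] = ΣD
  exactly, solved by bracketed root-finding on one scalar).  The
  goodness-of-fit sum over loci of (obs − exp)²/var for both S and D,
  with the model variances including the coalescent terms, is referred
  to χ² with 1 df.
* `contingency` — a 2×2 chi-square (Yates off) on
  [[S_cand, D_cand], [S_ref, D_ref]], switching to Fisher's exact test
  when an expected cell is below 5.  Transparent and usable directly on
  printed count tables, but it ignores the coalescent variance and is
  therefore anticonservative for small locus counts.

Divergence is counted against a single outgroup sequence (D = sites
monomorphic in the ingroup and different from the outgroup); polarity is
not inferred.  Polymorphism and divergence get separate effective
lengths because outgroup-missing columns only affect the latter.

## Ka/Ks (NG86) and duplication dating

Synonymous/nonsynonymous site counts per codon are the per-position
fractions of the three possible point mutations that preserve the amino
acid, excluding mutations to stop codons and renormalizing so every
codon contributes exactly three sites.  Differences between codons are
classified directly (one change) or averaged over all equally weighted
mutational pathways whose intermediates avoid stops (two or three
changes); if every pathway hits a stop, unrestricted pathways are used
with a warning.  pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
d = −(3/4)ln(1 − 4p/3), with p ≥ 3/4 flagged as saturated.  Codons
containing gaps or ambiguity in either sequence are dropped pairwise.

The neutrality test is Fisher's exact test on
{nonsynonymous, synonymous} × {differences, non-differences} with
fractional counts rounded half-up; on very short inputs a multi-hit
codon can push Nd above N_sites, in which case the complementary cell is
clamped at zero.  The genetic code defaults to the standard nuclear
code and is configurable.

Duplication age follows the strict molecular clock T = Ks/(2μ) with
μ = 6.5×10⁻⁹ synonymous substitutions per site per year by default (the
commonly assumed neutral rate for rice nuclear genes).  For a segmental
duplication the recommended input is the arithmetic mean Ks over the
block's homolog pairs (saturated pairs excluded with a warning).  The
clock assumption is strong: a swept or otherwise selected region can
bias Ks and hence the date, which is why the surrounding scan matters.

## Trees

Distances: p (pairwise deletion), Jukes–Cantor, protein p-distance on
translated sequences, and allele-sharing distance (1 − shared fraction)
on a genotype matrix for the genome tree.  Neighbor joining follows
Saitou–Nei with two policies fixed for bit-reproducibility: tied Q
minima are resolved toward the lexicographically smallest taxon-label
pair, and a negative branch length is clamped to zero with the deficit
moved to the sister branch.  Trees are unrooted (trifurcating root) and
newick round-trippable.  Incongruence is quantified by the
Robinson–Foulds bipartition distance and by explicit monophyly checks
(is there an edge separating exactly the cultivar set?).  Bootstrap
support resamples alignment columns with replacement, seeded.

## Synthetic panels

The generator emulates the sampling design the analysis assumes: two
cultivated subpopulations (defaults 13 japonica + 12 indica) each
derived *independently* from one wild population (default 25 samples)
through a domestication bottleneck, plus a single distant outgroup
sequence.  Genealogies are Kingman coalescents with piecewise-constant
rates (time in units of 2N generations of the wild population);
mutations are infinite-sites, Poisson(θ·branch/2), each at a distinct
column; the outgroup is the ancestral sequence with
Poisson(L·divergence) private substitutions.

Defaults and their provenance:

| parameter | default | rationale |
|---|---|---|
| L | 4600 bp | the gene-region length used for locus trees in rice domestication scans |
| θ (per locus) | 46 (0.01/site) | wild rice nucleotide diversity ≈ 0.0097/site |
| bottleneck onset | 0.1 | domestication recent relative to 2N generations |
| bottleneck severity | 0.15 (duration 0.1) | yields cultivated/wild genome diversity ratio ≈ 0.7, matching observed genome-average ratios (≈ 0.55–0.75) |
| sweep time | 0.1 (= bottleneck onset) | fixation during domestication; leaves time for rare post-sweep variants, hence negative Tajima's D rather than S = 0 |
| outgroup divergence | 0.1/site | observed divergence to the BB-genome outgroup (~0.098 at the candidate locus) |

The sweep is a **star-coalescence approximation**: at the sweep time all
cultivated lineages at the focal locus coalesce simultaneously, rather
than simulating a structured coalescent with a selection coefficient.
This reproduces the qualitative signatures (diversity deficit, excess
rare variants, negative D) but compresses the fixation trajectory to an
instant, so the magnitude of linked effects near the sweep edge is not
quantitative.  Introgression is the same star applied across *both*
cultivated subpopulations, emulating a focal haplotype shared between
subspecies; everything between "one subspecies donated its haplotype"
and "parallel selection on the same haplotype" is deliberately not
distinguished, exactly as it cannot be distinguished in the real data.

The panel generator gives the focal locus the sweep/introgression flags
and evolves all other loci neutrally under the same demography; the
genotype matrix pools biallelic sites from the non-focal loci as the
genome-wide SNP stand-in (a few hundred SNPs, far fewer than a real
genotyping panel — genome-tree topology is correspondingly noisier).

What the generator omits: recombination within loci (each locus is one
genealogy), recurrent mutation, gene flow after domestication except
via the explicit introgression flag, population growth, and any
realistic chromosome structure.  Passing tests on these panels show the
estimators and the scan logic are correct and calibrated under the
stated model; they do not show the model captures every property of
real resequencing data (alignment error, consensus-calling artifacts,
recombination-driven heterogeneity along the locus).

The codon evolver for Ka/Ks calibration proposes uniform point
mutations on a random stop-free coding sequence, accepts synonymous
changes always and nonsynonymous with probability ω, alternating
substitutions between the two copies until synonymous divergence
reaches the target.  It deliberately has no transition bias or codon
usage preference — matching the assumptions of plain NG86.

## Pipeline

`run_scan` executes diversity → windows → HKA → Ka/Ks → haplotypes →
fixed differences → trees, recording any stage failure and continuing;
outputs are `report.json`, `stats.tsv`, `windows.tsv` and
`trees/*.nwk`, with the config digest and seed embedded so a rerun is
byte-identical.  Window statistics are reported raw, without
multiple-testing correction across windows, matching how sliding-window
selection scans are conventionally read; the sweep boundary is left to
the user's judgment on the tracks.

## Problem sizes used in the shipped checks

The calibration and pattern suites run at desk scale, chosen to keep
the whole battery in minutes on one core: 2,000 neutral replicates
(n = 10, θ = 5) for the S and D calibration; 1,000 replicates for HKA
type-I error; 100 replicates of 500-codon pairs for ω recovery; and
100 five-locus panels each for the sweep and introgression pattern
rates.

## Known limitations

* Exact reproduction of published per-population θπ values or legacy
  HKA p-values requires the original alignments and masking decisions,
  which deposited accession numbers alone do not determine; the package
  therefore validates against oracles and calibrations, not against
  those printed values.
* The `hka1987` variance formulas assume no recombination within loci
  and free recombination between them.
* NG86 is a counting method: it ignores transition/transversion bias
  and codon-frequency effects, and saturates near p = 3/4.
* NJ negative-branch handling and tie-breaking are principled but not
  claimed to match any particular legacy implementation's internals.
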