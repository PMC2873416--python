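"""Nei–Gojobori (1986) Ka/Ks estimation and molecular-clock dating.

Synonymous and nonsynonymous sites are counted per codon as the fraction
of the three possible point mutations at each position that preserve the
encoded amino acid (mutations creating stop codons are excluded and the
remaining fractions renormalized so each codon contributes exactly three
sites).  Differences between codons are classified directly for single
changes and averaged over equally weighted mutational pathways avoiding
stop codons for multiple changes.  Proportions are Jukes–Cantor corrected:
d = -(3/4) ln(1 - (4/3) p).

A Ka/Ks well below 1 indicates purifying selection; the companion Fisher
exact test compares nonsynonymous vs synonymous differences against their
site totals.  Duplication ages follow the molecular clock T = Ks / (2 μ)
with μ in synonymous substitutions per site per year.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable
from scipy import stats

BASES = "ACGT"
SATURATED = float("inf")  # marker for p >= 3/4 (JC correction undefined)


class FrameError(ValueError):
    """Coding sequence length is not a multiple of 3 or codons invalid."""


def _codon_table(code: str | int = "standard") -> CodonTable.CodonTable:
    if code == "standard":
        return CodonTable.unambiguous_dna_by_id[1]
    if isinstance(code, int):
        return CodonTable.unambiguous_dna_by_id[code]
    return CodonTable.unambiguous_dna_by_name[code]


@lru_cache(maxsize=None)
def _aa(codon: str, code: str | int = "standard") -> str | None:
    """Amino acid, or None for a stop codon."""
    table = _codon_table(code)
    if codon in table.stop_codons:
        return None
    return table.forward_table[codon]


def _check_codon(codon: str, code: str | int = "standard") -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise FrameError(f"invalid codon {codon!r}")
    if _aa(codon, code) is None:
        raise FrameError(f"stop codon {codon!r} in coding sequence")


@lru_cache(maxsize=None)
def ng86_sites(codon: str, code: str | int = "standard"
               ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    At each position the fraction of non-stop point mutations that are
    synonymous is the synonymous site contribution; positions always
    contribute one site, so the two fractions sum to 3.
    """
    _check_codon(codon, code)
    aa0 = _aa(codon, code)
    syn = 0.0
    for pos in range(3):
        syn_count = non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            aa = _aa(mutant, code)
            if aa is None:
                continue
            non_stop += 1
            if aa == aa0:
                syn_count += 1
        if non_stop:
            syn += syn_count / non_stop
    return syn, 3.0 - syn


def _classify_step(c1: str, c2: str, code: str | int) -> tuple[float, float]:
    """(syn, nonsyn) for a single-base codon change."""
    return (1.0, 0.0) if _aa(c1, code) == _aa(c2, code) else (0.0, 1.0)


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str,
                     code: str | int = "standard") -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference fractions between two codons.

    Multi-base differences are averaged over all mutational pathways
    (orderings of the changed positions) whose intermediates avoid stop
    codons, with equal pathway weights.  If every pathway passes through a
    stop, unrestricted pathways are used with a warning.
    """
    _check_codon(codon_a, code)
    _check_codon(codon_b, code)
    changed = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not changed:
        return 0.0, 0.0
    if len(changed) == 1:
        return _classify_step(codon_a, codon_b, code)

    def pathway_counts(order: tuple[int, ...], allow_stops: bool
                       ) -> tuple[float, float] | None:
        syn = nsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _aa(nxt, code) is None:
                if not allow_stops:
                    return None
                # unrestricted fallback: count the step by comparing the
                # flanking non-stop codons is impossible; treat stop-passing
                # steps as nonsynonymous
                nsyn += 1.0
            else:
                s, n = _classify_step_lenient(current, nxt, code)
                syn += s
                nsyn += n
            current = nxt
        return syn, nsyn

    valid = [c for order in itertools.permutations(changed)
             if (c := pathway_counts(order, allow_stops=False)) is not None]
    if not valid:
        warnings.warn(
            f"all pathways {codon_a}->{codon_b} pass through stop codons; "
            "counting via unrestricted pathways", stacklevel=2)
        valid = [pathway_counts(order, allow_stops=True)
                 for order in itertools.permutations(changed)]
    syn = sum(v[0] for v in valid) / len(valid)
    return syn, len(changed) - syn


def _classify_step_lenient(c1: str, c2: str, code: str | int
                           ) -> tuple[float, float]:
    a1, a2 = _aa(c1, code), _aa(c2, code)
    if a1 is None or a2 is None:
        return 0.0, 1.0
    return (1.0, 0.0) if a1 == a2 else (0.0, 1.0)


@dataclass
class CodonPair:
    """NG86 summary for one pair of aligned coding sequences."""

    n_codons: int       # codons analyzed after pairwise gap/N removal
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float           # inf marks JC saturation (p >= 3/4)
    Ks: float
    ratio: float | None  # None when Ks == 0 (undefined)
    fisher_p: float


@dataclass
class ClockEstimate:
    """Molecular-clock age from synonymous divergence."""

    Ks: float
    rate: float   # substitutions per silent site per year
    years: float


def jukes_cantor(p: float) -> float:
    """JC69 distance; returns the saturation marker for p >= 3/4."""
    if p >= 0.75:
        return SATURATED
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def kaks_pair(seq_a: str, seq_b: str, code: str | int = "standard"
              ) -> CodonPair:
    """NG86 Ka, Ks and Fisher exact neutrality test for two codon-aligned
    coding sequences.

    Codons containing gaps or N in either sequence are dropped pairwise.
    Site counts are averaged over the two sequences; pN = Nd/N and
    pS = Sd/S are Jukes–Cantor corrected.  The exact test uses the 2x2
    table {nonsynonymous, synonymous} x {differences, non-differences}
    with fractional counts rounded half-up.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise FrameError("sequences must be equal length (codon-aligned)")
    if len(seq_a) % 3:
        raise FrameError("length is not a multiple of 3")
    N_sites = S_sites = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(b not in BASES for b in ca + cb):
            continue  # pairwise deletion of gapped/ambiguous codons
        sa, na = ng86_sites(ca, code)
        sb, nb = ng86_sites(cb, code)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        s, n = ng86_differences(ca, cb, code)
        Sd += s
        Nd += n
        n_codons += 1
    if n_codons == 0:
        raise FrameError("no analyzable codons after pairwise deletion")
    pN = Nd / N_sites if N_sites else 0.0
    pS = Sd / S_sites if S_sites else 0.0
    ka, ks = jukes_cantor(pN), jukes_cantor(pS)
    if ka == 0.0 and ks == 0.0:
        ratio = None
    elif ks == 0.0 or math.isinf(ka) or math.isinf(ks):
        ratio = None
    else:
        ratio = ka / ks
    # a multi-hit codon can push Nd above N_sites on very short inputs;
    # clamp so the exact-test table stays valid
    table = [[_round_half_up(Nd), max(_round_half_up(N_sites - Nd), 0)],
             [_round_half_up(Sd), max(_round_half_up(S_sites - Sd), 0)]]
    fisher_p = float(stats.fisher_exact(table)[1])
    return CodonPair(n_codons=n_codons, N_sites=N_sites, S_sites=S_sites,
                     Nd=Nd, Sd=Sd, pN=pN, pS=pS, Ka=ka, Ks=ks,
                     ratio=ratio, fisher_p=fisher_p)


def duplication_time(ks: float, rate: float = 6.5e-9) -> ClockEstimate:
    """Age of a duplication from its synonymous divergence: T = Ks/(2 μ).

    The default rate 6.5e-9 synonymous substitutions per site per year is
    the commonly assumed neutral rate for rice nuclear genes.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return ClockEstimate(Ks=ks, rate=rate, years=ks / (2.0 * rate))


def mean_ks_over_pairs(pairs: list[CodonPair]) -> float:
    """Arithmetic mean Ks across pairs; saturated pairs are excluded
    (with a warning), e.g. for dating a segmental duplication from the
    mean of its constituent homolog pairs."""
    if not pairs:
        raise ValueError("need at least one pair")
    usable = [p.Ks for p in pairs if not math.isinf(p.Ks)]
    if not usable:
        raise ArithmeticError("all pairs saturated; mean Ks undefined")
    if len(usable) < len(pairs):
        warnings.warn(f"excluded {len(pairs) - len(usable)} saturated "
                      "pair(s) from mean Ks", stacklevel=2)
    return sum(usable) / len(usable)
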