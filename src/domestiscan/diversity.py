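"""Nucleotide diversity, frequency-spectrum and haplotype statistics.

Per-locus and sliding-window summaries of a population sample: segregating
sites S, nucleotide diversity θπ, Watterson's θW, Tajima's D, haplotype
typing and diversity, and near-fixed differences between populations.

Missing-data rule (applies to every statistic here): within the analyzed
population, any column containing ``-`` or ``N`` is dropped entirely
(site-wise complete deletion); ``L_eff`` is the number of retained columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seqio import InsufficientSampleError, LocusAlignment, MISSING


@dataclass
class LocusStats:
    """Diversity summary for one population at one locus or window."""

    locus_id: str
    population: str
    n: int
    L_eff: int
    S: int
    pi: float          # per-site θπ
    theta_w: float     # per-site Watterson estimator
    tajima_d: float | None  # None when S == 0
    hap_count: int
    hap_div: float


@dataclass
class WindowTrack:
    """Sliding-window statistic values; bounds are 1-based inclusive."""

    locus_id: str
    population: str
    stat: str
    window: int
    step: int
    windows: list[tuple[int, int, LocusStats]]


def _retained_columns(aln: LocusAlignment) -> np.ndarray:
    """Boolean mask of columns free of '-' and 'N' across all rows."""
    arr = aln.to_array()
    return ~(np.isin(arr, ["-", "N"]).any(axis=0))


def _clean_array(aln: LocusAlignment, population: str | None,
                 min_n: int = 2) -> np.ndarray:
    sub = aln if population is None else aln.subset([population])
    if sub.n < min_n:
        raise InsufficientSampleError(
            f"{sub.n} sequence(s) in {population!r}; need >= {min_n}")
    arr = sub.to_array()
    return arr[:, _retained_columns(sub)]


def _site_counts(arr: np.ndarray) -> tuple[int, int]:
    """(S, L_eff) on a missing-free character array."""
    L_eff = arr.shape[1]
    if L_eff == 0:
        return 0, 0
    segregating = (arr != arr[0]).any(axis=0)
    return int(segregating.sum()), L_eff


def segregating_sites(aln: LocusAlignment, population: str | None = None
                      ) -> tuple[int, int]:
    """Number of segregating (polymorphic) sites and retained length.

    A site segregates if at least two distinct bases occur among the
    population's samples at a retained column.
    """
    return _site_counts(_clean_array(aln, population))


def _mean_pairwise_differences(arr: np.ndarray) -> float:
    """Mean Hamming distance over all unordered sequence pairs (π̂, total)."""
    n = arr.shape[0]
    total = 0
    for i in range(n):
        diff = (arr[i + 1:] != arr[i]).sum()
        total += int(diff)
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(aln: LocusAlignment, population: str | None = None
                         ) -> float:
    """Per-site nucleotide diversity θπ: mean pairwise differences / L_eff."""
    arr = _clean_array(aln, population)
    if arr.shape[1] == 0:
        return 0.0
    return _mean_pairwise_differences(arr) / arr.shape[1]


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i, the Watterson normalizer."""
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(aln: LocusAlignment, population: str | None = None
                    ) -> float:
    """Per-site Watterson estimator θW = S / (a1 · L_eff)."""
    arr = _clean_array(aln, population)
    S, L_eff = _site_counts(arr)
    if L_eff == 0 or S == 0:
        return 0.0
    return S / (harmonic_a1(arr.shape[0]) * L_eff)


def tajima_d_from_counts(n: int, S: int, pi_hat: float) -> float | None:
    """Tajima's D from sample size, segregating sites and total mean
    pairwise differences π̂ (not per-site).  None when S == 0.

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 derived
    from n alone.
    """
    if S == 0:
        return None
    a1 = harmonic_a1(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n=3 makes both variance constants exactly zero
        return None
    return (pi_hat - S / a1) / math.sqrt(var)


def tajimas_d(aln: LocusAlignment, population: str | None = None
              ) -> float | None:
    """Tajima's D; None (undefined) when the population has no variation."""
    arr = _clean_array(aln, population, min_n=3)
    S, L_eff = _site_counts(arr)
    if S == 0:
        return None
    return tajima_d_from_counts(arr.shape[0], S, _mean_pairwise_differences(arr))


def tajimas_d_pvalue(d: float, n: int, S: int, reps: int = 10_000,
                     seed: int = 0) -> float:
    """Two-sided parametric-bootstrap p for Tajima's D.

    Simulates the standard neutral coalescent for n samples conditional on
    the observed number of segregating sites (mutations dropped uniformly
    on the genealogy), recomputes D per replicate, and returns the
    fraction of replicates at least as extreme as |d|.
    """
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(reps):
        # coalescent intervals: t_k ~ Exp(mean 2/(k(k-1))), k = n..2
        ks = np.arange(n, 1, -1)
        times = rng.exponential(2.0 / (ks * (ks - 1)))
        # lineage count per interval = k; place S mutations on branches
        # proportionally to k * t_k, then track derived-allele counts
        weights = ks * times
        probs = weights / weights.sum()
        intervals = rng.choice(len(ks), size=S, p=probs)
        # during interval with k lineages a mutation subtends one of k
        # lineages; derived count distribution under the coalescent is
        # handled by simulating the tree shape implicitly: draw the size
        # of the subtended clade uniformly among the k lineages' leaf
        # sets.  Build leaf counts by a simple random-merge genealogy.
        sizes = _random_merge_clade_sizes(n, rng)
        pi_hat = 0.0
        for iv in intervals:
            k = int(ks[iv])
            clade = sizes[k][rng.integers(k)]
            pi_hat += 2.0 * clade * (n - clade) / (n * (n - 1))
        rep_d = tajima_d_from_counts(n, S, pi_hat)
        if rep_d is not None and abs(rep_d) >= abs(d):
            extreme += 1
    return extreme / reps


def _random_merge_clade_sizes(n: int, rng: np.random.Generator
                              ) -> dict[int, list[int]]:
    """Leaf counts of the k lineages present while k lineages remain,
    under a random-merge (Kingman) genealogy."""
    sizes = {n: [1] * n}
    current = [1] * n
    for k in range(n, 2, -1):
        i, j = rng.choice(k, size=2, replace=False)
        merged = current[i] + current[j]
        current = [c for idx, c in enumerate(current) if idx not in (i, j)]
        current.append(merged)
        sizes[k - 1] = list(current)
    return sizes


def locus_stats(aln: LocusAlignment, population: str | None = None,
                locus_id: str | None = None) -> LocusStats:
    """All LocusStats fields for one population in one call."""
    sub = aln if population is None else aln.subset([population])
    arr = _clean_array(sub, None)
    n = arr.shape[0]
    S, L_eff = _site_counts(arr)
    pi_hat = _mean_pairwise_differences(arr) if L_eff else 0.0
    types, hap_div = haplotype_classify(sub)
    return LocusStats(
        locus_id=locus_id or aln.locus_id,
        population=population or "all",
        n=n,
        L_eff=L_eff,
        S=S,
        pi=pi_hat / L_eff if L_eff else 0.0,
        theta_w=S / (harmonic_a1(n) * L_eff) if L_eff and S else 0.0,
        tajima_d=tajima_d_from_counts(n, S, pi_hat) if n >= 3 else None,
        hap_count=len(types),
        hap_div=hap_div,
    )


def sliding_windows(aln: LocusAlignment, population: str | None,
                    window: int, step: int, stat: str = "pi",
                    include_partial: bool = False) -> WindowTrack:
    """Evaluate a statistic in sliding windows along the alignment.

    Windows are column slices of the full alignment (the deletion rule is
    re-applied within each window); there are floor((L-window)/step)+1 full
    windows, plus one trailing partial window when ``include_partial``.
    Reported bounds are 1-based inclusive alignment coordinates.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    L = aln.length
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    starts = list(range(0, L - window + 1, step))
    bounds = [(s, s + window) for s in starts]
    if include_partial and bounds and bounds[-1][1] < L:
        bounds.append((starts[-1] + step, L))
    out = []
    for lo, hi in bounds:
        piece = aln.slice_columns(lo, hi)
        st = locus_stats(piece, population)
        out.append((aln.coordinate_offset + lo,
                    aln.coordinate_offset + hi - 1, st))
    return WindowTrack(aln.locus_id, population or "all", stat,
                       window, step, out)


def haplotype_classify(aln: LocusAlignment,
                       populations: Iterable[str] | None = None
                       ) -> tuple[dict[int, list[str]], float]:
    """Group sequences into exact-identity haplotype types.

    Sequences identical at all retained columns share a type.  Type ids are
    1..k by descending member count, ties broken by first occurrence in
    input order.  Returns (type_id → member sample ids, haplotype
    diversity), where hap_div = n(1 − Σ p_i²)/(n − 1) for n ≥ 2, else 0.
    """
    sub = aln if populations is None else aln.subset(populations)
    arr = sub.to_array()
    keep = _retained_columns(sub)
    keys = ["".join(row[keep]) for row in arr]
    groups: dict[str, list[str]] = {}
    for sample, key in zip(sub.samples, keys):
        groups.setdefault(key, []).append(sample)
    ordered = sorted(groups.values(),
                     key=lambda members: (-len(members),
                                          sub.samples.index(members[0])))
    types = {i + 1: members for i, members in enumerate(ordered)}
    n = sub.n
    if n < 2:
        return types, 0.0
    sum_p2 = sum((len(m) / n) ** 2 for m in ordered)
    return types, n * (1.0 - sum_p2) / (n - 1)


def fixed_differences(aln: LocusAlignment, pop_a: str, pop_b: str,
                      freq_threshold: float = 0.95
                      ) -> list[tuple[int, str, str, float, float]]:
    """Sites where population A's major allele is (near-)fixed and
    (near-)absent from population B.

    Reports (1-based position, major allele in A, major allele in B,
    A-frequency of A's major allele, B-frequency of A's major allele) at
    sites where that allele has frequency ≥ threshold in A and
    ≤ 1 − threshold in B.  The default 0.95 captures "almost fixed"
    substitutions such as a domestication-selected coding change.
    """
    if not 0.5 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must be in (0.5, 1]")
    sub_a = aln.subset([pop_a])
    sub_b = aln.subset([pop_b])
    if sub_a.n < 2 or sub_b.n < 2:
        raise InsufficientSampleError("both populations need >= 2 sequences")
    arr_a, arr_b = sub_a.to_array(), sub_b.to_array()
    out = []
    for col in range(aln.length):
        col_a = [c for c in arr_a[:, col] if c not in MISSING]
        col_b = [c for c in arr_b[:, col] if c not in MISSING]
        if not col_a or not col_b:
            continue
        alleles_a, counts_a = np.unique(col_a, return_counts=True)
        major_a = alleles_a[np.argmax(counts_a)]
        freq_a = counts_a.max() / len(col_a)
        freq_b = col_b.count(major_a) / len(col_b)
        if freq_a >= freq_threshold and freq_b <= 1.0 - freq_threshold:
            alleles_b, counts_b = np.unique(col_b, return_counts=True)
            major_b = alleles_b[np.argmax(counts_b)]
            out.append((aln.coordinate_offset + col, str(major_a),
                        str(major_b), float(freq_a), float(freq_b)))
    return out
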