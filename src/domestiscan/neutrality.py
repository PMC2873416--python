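"""HKA test of polymorphism/divergence ratio homogeneity between two loci.

Under neutrality the ratio of within-species polymorphism to divergence
from an outgroup is the same at every locus; a locus swept during
domestication shows a deficit of polymorphism relative to its divergence.
Two flavours are provided:

``hka1987``
    The classic two-locus moment-equation test: per-length θ̂_i for each
    locus and a shared divergence time T̂ are fitted so that expected
    polymorphism and divergence counts match the observed totals, and a
    goodness-of-fit X² (sum over loci of squared deviations scaled by the
    model variances) is referred to χ² with 1 df.

``contingency``
    A 2x2 chi-square / Fisher-exact approximation on the table
    [[S_cand, D_cand], [S_ref, D_ref]] — transparent and robust for
    printed-count inputs, but it ignores the coalescent variance terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .diversity import harmonic_a1
from .seqio import LocusAlignment, MISSING


@dataclass
class HkaLocus:
    """Observed counts for one locus."""

    name: str
    S: int            # intraspecific polymorphic sites
    n: int            # sample size used for polymorphism
    L_poly: float     # sites surveyed for polymorphism
    D: int            # fixed differences to the outgroup
    L_div: float      # sites surveyed for divergence

    def __post_init__(self) -> None:
        if min(self.S, self.D) < 0 or min(self.L_poly, self.L_div) <= 0:
            raise ValueError("counts must be >= 0 and lengths > 0")
        if self.S > self.L_poly or self.D > self.L_div:
            raise ValueError("counts exceed surveyed lengths")


@dataclass
class HkaResult:
    method: str
    statistic: float
    df: int
    p_value: float
    theta_hat: dict[str, float] | None = None  # per-site θ̂ by locus name
    T_hat: float | None = None
    expected: dict[str, tuple[float, float]] | None = None  # (E[S], E[D])


class DegenerateInputError(ValueError):
    """A contingency table row or column is all zero."""


def hka_test(candidate: HkaLocus, reference: HkaLocus, f: float = 1.0,
             method: str = "hka1987") -> HkaResult:
    """Two-locus HKA test.

    ``f`` is the outgroup/ingroup population-size ratio (1 by default).
    ``method`` selects the 1987 moment-equation X² or the 2x2 contingency
    approximation (chi-square without Yates correction, switching to
    Fisher's exact test when any expected cell count is below 5).
    """
    if method == "hka1987":
        return _hka_1987(candidate, reference, f)
    if method == "contingency":
        return _hka_contingency(candidate, reference)
    raise ValueError(f"unknown method {method!r}")


def _hka_contingency(cand: HkaLocus, ref: HkaLocus) -> HkaResult:
    table = np.array([[cand.S, cand.D], [ref.S, ref.D]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero row or column in 2x2 table")
    expected = stats.contingency.expected_freq(table)
    chi2 = stats.chi2_contingency(table, correction=False)
    stat = float(chi2.statistic)
    if expected.min() < 5:  # small counts: exact test is the honest p
        p = float(stats.fisher_exact(np.round(table).astype(int))[1])
    else:
        p = float(chi2.pvalue)
    return HkaResult(method="contingency", statistic=stat, df=1,
                     p_value=float(p))


def _hka_1987(cand: HkaLocus, ref: HkaLocus, f: float) -> HkaResult:
    """Solve the moment equations for (θ1, θ2, T) and form the X² sum."""
    loci = [cand, ref]
    a = [harmonic_a1(loc.n) for loc in loci]
    a2 = [sum(1.0 / (i * i) for i in range(1, loc.n)) for loc in loci]
    S_tot = sum(loc.S for loc in loci)
    D_tot = sum(loc.D for loc in loci)
    half = (1.0 + f) / 2.0

    # Unknowns: per-site θ_i and u = T + (1+f)/2, constrained by
    #   Σ S_i = Σ θ_i L_i^poly a_i
    #   Σ D_i = u Σ θ_i L_i^div
    #   S_1 + D_1 = θ_1 (L_1^poly a_1 + L_1^div u)
    # Reduce to one equation in u and solve by bracketing.
    def thetas(u: float) -> tuple[float, float]:
        th1 = (cand.S + cand.D) / (cand.L_poly * a[0] + cand.L_div * u)
        th2 = (S_tot - th1 * cand.L_poly * a[0]) / (ref.L_poly * a[1])
        return th1, th2

    def residual(u: float) -> float:
        th1, th2 = thetas(u)
        return u * (th1 * cand.L_div + th2 * ref.L_div) - D_tot

    lo, hi = 1e-9, 1.0
    while residual(hi) < 0 and hi < 1e9:
        hi *= 2.0
    try:
        u_hat = optimize.brentq(residual, lo, hi, xtol=1e-12, rtol=1e-12)
    except ValueError as exc:
        raise ArithmeticError(
            f"HKA moment equations did not converge (S={S_tot}, D={D_tot}, "
            f"bracket residuals {residual(lo):.3g}/{residual(hi):.3g})"
        ) from exc
    th = thetas(u_hat)
    if min(th) <= 0:
        raise ArithmeticError(
            f"HKA moment solve produced non-positive theta: {th}")
    T_hat = u_hat - half

    x2 = 0.0
    expected = {}
    for i, loc in enumerate(loci):
        theta_poly = th[i] * loc.L_poly      # per-locus θ over L_poly
        theta_div = th[i] * loc.L_div
        e_s = theta_poly * a[i]
        v_s = e_s + theta_poly ** 2 * a2[i]
        e_d = theta_div * u_hat
        v_d = e_d + (theta_div * half) ** 2
        x2 += (loc.S - e_s) ** 2 / v_s + (loc.D - e_d) ** 2 / v_d
        expected[loc.name] = (e_s, e_d)
    p = float(stats.chi2.sf(x2, df=1))
    return HkaResult(method="hka1987", statistic=float(x2), df=1, p_value=p,
                     theta_hat={loci[i].name: th[i] for i in range(2)},
                     T_hat=float(T_hat), expected=expected)


def polymorphism_divergence_counts(aln: LocusAlignment,
                                   outgroup_population: str = "outgroup",
                                   name: str | None = None) -> HkaLocus:
    """Classify alignment columns into polymorphism vs divergence counts.

    Requires exactly one outgroup sample.  S counts ingroup segregating
    sites; D counts sites monomorphic in the ingroup whose (single) allele
    differs from the outgroup.  Columns with missing data in the relevant
    comparison are excluded, giving separate effective lengths for the
    polymorphism and divergence surveys.
    """
    outgroup = [s for s in aln.samples
                if aln.populations[s] == outgroup_population]
    if len(outgroup) != 1:
        raise ValueError(
            f"need exactly one outgroup sample, found {len(outgroup)}")
    ingroup = [s for s in aln.samples
               if aln.populations[s] != outgroup_population]
    if len(ingroup) < 2:
        raise ValueError("need >= 2 ingroup samples")
    arr = aln.to_array()
    idx = {s: i for i, s in enumerate(aln.samples)}
    in_rows = arr[[idx[s] for s in ingroup]]
    out_row = arr[idx[outgroup[0]]]

    S = D = 0
    L_poly = L_div = 0
    for col in range(aln.length):
        col_in = in_rows[:, col]
        if np.isin(col_in, list(MISSING)).any():
            continue
        L_poly += 1
        poly = len(set(col_in)) > 1
        if poly:
            S += 1
        if out_row[col] in MISSING:
            continue
        L_div += 1
        if not poly and col_in[0] != out_row[col]:
            D += 1
    return HkaLocus(name=name or aln.locus_id, S=S, n=len(ingroup),
                    L_poly=L_poly, D=D, L_div=L_div)


def simulate_hka_counts(theta1: float, theta2: float, T: float,
                        n1: int, n2: int, f: float = 1.0,
                        rng: np.random.Generator | None = None
                        ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Draw (S, D) for two loci under the neutral HKA model.

    θ here is per-locus (θ_i = 4Nμ_i L_i); T is the species divergence in
    2N-generation units.  S is Poisson on a simulated coalescent tree
    length; D is Poisson on 2T plus an exponential ancestral coalescent
    time with mean (1+f).  Used for type-I-error calibration.
    """
    rng = rng or np.random.default_rng()
    out = []
    for theta, n in ((theta1, n1), (theta2, n2)):
        ks = np.arange(n, 1, -1)
        ttot = float((ks * rng.exponential(2.0 / (ks * (ks - 1)))).sum())
        S = rng.poisson(theta * ttot / 2.0)
        t_anc = rng.exponential(1.0 + f)
        D = rng.poisson(theta / 2.0 * (2.0 * T + t_anc))
        out.append((int(S), int(D)))
    return out[0], out[1]
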