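"""HKA test: is a candidate locus's polymorphism/divergence ratio
compatible with a neutral reference locus?

Uses the published counts for a rice cell-wall invertase candidate locus
against the ADH1 reference (polymorphic sites within cultivars; fixed
differences to a wild-relative outgroup), then repeats the test on a
simulated neutral locus pair where no deviation should be found.
"""

import numpy as np

from domestiscan import HkaLocus, hka_test, \
    polymorphism_divergence_counts
from domestiscan.simulate import SimScenario, simulate_locus

candidate = HkaLocus("candidate", S=44, n=50, L_poly=4772,
                     D=454, L_div=4636)
reference = HkaLocus("ADH1", S=45, n=50, L_poly=2573, D=170, L_div=2573)

for method in ("contingency", "hka1987"):
    res = hka_test(candidate, reference, method=method)
    print(f"{method:>12}: X2 = {res.statistic:.3f}, df = {res.df}, "
          f"p = {res.p_value:.3g}")
# Both methods flag the candidate: it carries far too much divergence for
# its polymorphism (or too little polymorphism for its divergence) —
# the footprint of a selective sweep within the cultivated gene pool.

rng = np.random.default_rng(11)
scn = SimScenario(seed=11, L=3000, theta=20.0)
cand_aln, _ = simulate_locus(scn, locus_id="neutral_A", rng=rng)
ref_aln, _ = simulate_locus(scn, locus_id="neutral_B", rng=rng)
row_a = polymorphism_divergence_counts(cand_aln)
row_b = polymorphism_divergence_counts(ref_aln)
res = hka_test(row_a, row_b, method="hka1987")
print(f"\nneutral simulation: S/D = {row_a.S}/{row_a.D} vs "
      f"{row_b.S}/{row_b.D}, p = {res.p_value:.3f} (no deviation)")
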