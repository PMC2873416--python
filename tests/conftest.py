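import numpy as np
import pytest

from domestiscan.seqio import LocusAlignment, PopulationMap
from domestiscan.simulate import SimScenario, simulate_locus


@pytest.fixture
def tiny_alignment():
    """Three wild sequences with two segregating sites."""
    return LocusAlignment(
        locus_id="tiny",
        samples=["s1", "s2", "s3"],
        populations={s: "wild" for s in ("s1", "s2", "s3")},
        sequences=["AAAA", "AAAT", "AATT"],
    )


@pytest.fixture
def popmap():
    return PopulationMap({
        "s1": "wild", "s2": "wild", "s3": "wild",
        "c1": "japonica", "c2": "indica", "og": "outgroup",
    })


@pytest.fixture(scope="session")
def small_panel_alignment():
    """One simulated locus (cultivars + wild + outgroup), session-cached."""
    scn = SimScenario(seed=42, n_wild=10, n_japonica=6, n_indica=6,
                      L=1500, theta=12.0)
    aln, truth = simulate_locus(scn)
    return aln, truth


def random_alignment(rng, n=20, L=200, pops=("wild",), missing_frac=0.0):
    """Random (non-biological) alignment for brute-force oracle tests."""
    chars = np.array(list("ACGT"))
    arr = chars[rng.integers(0, 4, size=(n, L))]
    if missing_frac:
        mask = rng.random((n, L)) < missing_frac
        arr[mask] = rng.choice(["N", "-"], size=int(mask.sum()))
    samples = [f"t{i:02d}" for i in range(n)]
    populations = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    return LocusAlignment("rand", samples, populations,
                          ["".join(row) for row in arr])
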