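import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from conftest import random_alignment
from domestiscan.diversity import (fixed_differences, haplotype_classify,
                                   locus_stats, nucleotide_diversity,
                                   segregating_sites, sliding_windows,
                                   tajima_d_from_counts, tajimas_d,
                                   tajimas_d_pvalue, watterson_theta)
from domestiscan.seqio import InsufficientSampleError, LocusAlignment
from domestiscan.simulate import SimScenario, simulate_locus


def _aln(seqs, pop="wild"):
    samples = [f"s{i}" for i in range(len(seqs))]
    return LocusAlignment("t", samples, {s: pop for s in samples}, seqs)


def _brute_force_S(aln):
    """Per-column oracle: distinct non-missing bases at retained columns."""
    cols = list(zip(*aln.sequences))
    retained = [c for c in cols if not (set(c) & {"-", "N"})]
    return sum(len(set(c)) > 1 for c in retained), len(retained)


def _brute_force_pi(aln):
    """Mean hamming/L_eff over all unordered pairs (pairs share columns
    because of complete deletion)."""
    cols = [c for c in zip(*aln.sequences) if not (set(c) & {"-", "N"})]
    seqs = ["".join(t) for t in zip(*cols)]
    n = len(seqs)
    diffs = [sum(a != b for a, b in zip(seqs[i], seqs[j]))
             for i, j in itertools.combinations(range(n), 2)]
    return np.mean(diffs) / len(cols)


class TestSegregatingSites:
    def test_monomorphic(self):
        assert segregating_sites(_aln(["ACGT"] * 3)) == (0, 4)

    def test_by_inspection(self, tiny_alignment):
        assert segregating_sites(tiny_alignment) == (2, 4)

    def test_deletion_rule_drops_columns(self):
        # column 0 has a gap, column 1 an N: both dropped for everyone
        aln = _aln(["-AAT", "ANAT", "AAAA"])
        assert segregating_sites(aln) == (1, 2)

    @pytest.mark.parametrize("missing", [0.0, 0.05])
    def test_matches_columnwise_oracle(self, missing):
        rng = np.random.default_rng(11)
        for _ in range(5):
            aln = random_alignment(rng, n=20, L=200, missing_frac=missing)
            assert segregating_sites(aln) == _brute_force_S(aln)

    def test_single_sequence_rejected(self):
        with pytest.raises(InsufficientSampleError):
            segregating_sites(_aln(["ACGT"]))


class TestNucleotideDiversity:
    def test_identical_pair_is_zero(self):
        assert nucleotide_diversity(_aln(["ACGT", "ACGT"])) == 0.0

    def test_three_sequence_hand_value(self, tiny_alignment):
        # pairwise diffs 1, 2, 1 -> mean 4/3 over L=4
        assert nucleotide_diversity(tiny_alignment) == pytest.approx(
            4 / 3 / 4, abs=1e-9)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            aln = random_alignment(rng, n=12, L=150, missing_frac=0.03)
            assert nucleotide_diversity(aln) == pytest.approx(
                _brute_force_pi(aln), abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, n=10, L=100)
        perm = list(rng.permutation(aln.samples))
        shuffled = aln.subset(samples=perm)
        # subset preserves original order; rebuild in permuted order
        idx = {s: i for i, s in enumerate(aln.samples)}
        shuffled = LocusAlignment("t", perm, dict(aln.populations),
                                  [aln.sequences[idx[s]] for s in perm])
        assert nucleotide_diversity(aln) == nucleotide_diversity(shuffled)

    def test_duplication_scales_by_known_factor(self):
        # mean-pairwise pi under full sample duplication changes by
        # exactly 2(n-1)/(2n-1); invariance holds asymptotically
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n=8, L=120)
        doubled = LocusAlignment(
            "t", aln.samples + [s + "_dup" for s in aln.samples],
            {**aln.populations,
             **{s + "_dup": "wild" for s in aln.samples}},
            aln.sequences * 2)
        n = aln.n
        factor = 2 * (n - 1) / (2 * n - 1)
        assert nucleotide_diversity(doubled) == pytest.approx(
            nucleotide_diversity(aln) * factor, rel=1e-12)


class TestWattersonTheta:
    def test_zero_when_monomorphic(self):
        assert watterson_theta(_aln(["ACGT"] * 4)) == 0.0

    def test_hand_value(self):
        # n=4, L=100, S=3: a1 = 1 + 1/2 + 1/3
        seqs = ["A" * 100 for _ in range(4)]
        seqs[1] = "T" + seqs[1][1:]
        seqs[2] = "AT" + seqs[2][2:]
        seqs[3] = "AAT" + seqs[3][3:]
        assert watterson_theta(_aln(seqs)) == pytest.approx(
            3 / ((1 + 0.5 + 1 / 3) * 100), abs=1e-6)

    def test_equals_pi_for_two_sequences(self):
        rng = np.random.default_rng(2)
        aln = random_alignment(rng, n=2, L=300)
        assert watterson_theta(aln) == pytest.approx(
            nucleotide_diversity(aln), abs=1e-12)


class TestTajimasD:
    def test_undefined_without_variation(self):
        assert tajimas_d(_aln(["ACGT"] * 5)) is None

    def test_three_singletons_frozen_value(self):
        # n=4, L=100, three singleton sites: pi_hat=1.5, S=3;
        # independent evaluation of the published constants gives -0.7545
        seqs = ["A" * 100 for _ in range(4)]
        seqs[1] = "T" + seqs[1][1:]
        seqs[2] = "AT" + seqs[2][2:]
        seqs[3] = "AAT" + seqs[3][3:]
        assert tajimas_d(_aln(seqs)) == pytest.approx(-0.754451, abs=1e-4)
        assert tajima_d_from_counts(4, 3, 1.5) == pytest.approx(
            -0.7544510776, abs=1e-8)

    def test_requires_three_sequences(self):
        with pytest.raises(InsufficientSampleError):
            tajimas_d(_aln(["AT", "TA"]))

    def test_neutral_simulations_center_near_zero(self):
        """Mean D over neutral coalescent replicates is close to 0."""
        rng = np.random.default_rng(31)
        scn = SimScenario(seed=31, n_wild=10, n_japonica=2, n_indica=2,
                          L=1000, theta=5.0)
        ds = []
        for _ in range(400):
            aln, _ = simulate_locus(scn, rng=rng, include_outgroup=False)
            d = tajimas_d(aln, "wild")
            if d is not None:
                ds.append(d)
        assert abs(np.mean(ds)) < 0.1

    def test_bootstrap_p_extreme_for_large_D(self):
        p = tajimas_d_pvalue(-2.5, n=10, S=12, reps=400, seed=1)
        assert p < 0.1
        p_null = tajimas_d_pvalue(0.0, n=10, S=12, reps=400, seed=1)
        assert p_null > 0.5

    def test_sweep_cultivars_stochastically_below_neutral_wild(self):
        """Mirrors the negative-D-in-cultivars selection signature."""
        rng = np.random.default_rng(77)
        scn = SimScenario(seed=77, n_wild=10, n_japonica=6, n_indica=6,
                          L=1500, theta=15.0, sweep=True)
        cult, wild = [], []
        for _ in range(120):
            aln, _ = simulate_locus(scn, rng=rng, include_outgroup=False)
            dc = tajimas_d(aln, "japonica")
            dw = tajimas_d(aln, "wild")
            if dc is not None:
                cult.append(dc)
            if dw is not None:
                wild.append(dw)
        p = mannwhitneyu(cult, wild, alternative="less").pvalue
        assert p < 0.01


class TestSlidingWindows:
    def test_single_full_window(self):
        aln = _aln(["A" * 100, "T" + "A" * 99])
        track = sliding_windows(aln, None, window=100, step=10)
        assert len(track.windows) == 1
        assert track.windows[0][:2] == (1, 100)

    def test_non_overlapping_count(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, n=4, L=1000)
        track = sliding_windows(aln, None, window=100, step=100)
        assert len(track.windows) == 10
        assert track.windows[-1][:2] == (901, 1000)

    def test_window_equals_recomputed_slice(self):
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, n=8, L=400, missing_frac=0.02)
        track = sliding_windows(aln, None, window=150, step=50)
        for start, end, st in track.windows:
            piece = aln.slice_columns(start - 1, end)
            assert st.pi == pytest.approx(
                nucleotide_diversity(piece), abs=1e-12)
            assert (st.S, st.L_eff) == segregating_sites(piece)

    def test_window_larger_than_alignment_rejected(self, tiny_alignment):
        with pytest.raises(ValueError):
            sliding_windows(tiny_alignment, None, window=10, step=1)


class TestHaplotypeClassify:
    def test_single_type(self):
        types, hd = haplotype_classify(_aln(["ACGT"] * 5))
        assert len(types) == 1 and hd == 0.0
        assert types[1] == [f"s{i}" for i in range(5)]

    def test_three_types_hand_value(self):
        types, hd = haplotype_classify(
            _aln(["AAAA", "AAAA", "TTTT", "TTTT", "GGGG"]))
        assert sorted(len(m) for m in types.values()) == [1, 2, 2]
        assert hd == pytest.approx(0.8, abs=1e-12)
        # tie between the two size-2 types broken by input order
        assert types[1] == ["s0", "s1"] and types[2] == ["s2", "s3"]

    def test_partition_invariant_to_order(self):
        rng = np.random.default_rng(8)
        seqs = ["AAAA", "AATT", "AAAA", "TTTT", "AATT", "AAAA"]
        aln = _aln(seqs)
        perm = rng.permutation(len(seqs))
        shuffled = _aln([seqs[i] for i in perm])
        part = lambda t: sorted(
            sorted(m) for m in
            ({s: k for k, ms in t.items() for s in ms},)[0].items())
        t1, h1 = haplotype_classify(aln)
        t2, h2 = haplotype_classify(shuffled)
        assert h1 == h2
        assert sorted(len(m) for m in t1.values()) == \
            sorted(len(m) for m in t2.values())


class TestFixedDifferences:
    def _two_pop(self, a_seqs, b_seqs):
        samples = [f"a{i}" for i in range(len(a_seqs))] + \
                  [f"b{i}" for i in range(len(b_seqs))]
        pops = {s: ("A" if s.startswith("a") else "B") for s in samples}
        return LocusAlignment("t", samples, pops, a_seqs + b_seqs)

    def test_full_fixation_reported(self):
        aln = self._two_pop(["TA", "TA"], ["GA", "GA"])
        out = fixed_differences(aln, "A", "B", freq_threshold=1.0)
        assert out == [(1, "T", "G", 1.0, 0.0)]

    def test_identical_populations_empty(self):
        aln = self._two_pop(["TACG", "TACG"], ["TACG", "TACG"])
        assert fixed_differences(aln, "A", "B") == []

    def test_near_fixed_threshold_boundary(self):
        a = ["T"] * 19 + ["G"]          # popA: 19/20 T
        b_low = ["G"] * 19 + ["T"]      # popB: T freq 0.05 <= 0.05
        b_high = ["G"] * 18 + ["T"] * 2  # popB: T freq 0.10 > 0.05
        aln = self._two_pop(a, b_low)
        assert len(fixed_differences(aln, "A", "B", 0.95)) == 1
        aln2 = self._two_pop(a, b_high)
        assert fixed_differences(aln2, "A", "B", 0.95) == []

    def test_threshold_validation(self):
        aln = self._two_pop(["TA", "TA"], ["GA", "GA"])
        with pytest.raises(ValueError):
            fixed_differences(aln, "A", "B", freq_threshold=0.4)


def test_locus_stats_consistent_with_parts(tiny_alignment):
    st = locus_stats(tiny_alignment, "wild")
    assert (st.S, st.L_eff) == segregating_sites(tiny_alignment)
    assert st.pi == pytest.approx(nucleotide_diversity(tiny_alignment))
    assert st.theta_w == pytest.approx(watterson_theta(tiny_alignment))
    assert st.hap_count == 3
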