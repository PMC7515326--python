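import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plzcmeg.complexity import (ComplexityParams, epoch_plzc, lz76_count,
                                ordinal_symbolize, plzc, plzc_array)

from oracles import lz76_exhaustive


class TestOrdinalSymbolize:
    def test_pair_motifs(self):
        seq = ordinal_symbolize([1, 3, 2], ComplexityParams(m=2))
        assert seq.symbols.tolist() == [0, 1]  # ascending 0, descending 1
        assert seq.alphabet_size == 2
        assert seq.source_length == 3

    def test_monotone_series_yields_identity_motifs(self):
        seq = ordinal_symbolize(np.arange(10.0), ComplexityParams(m=3))
        assert seq.symbols.tolist() == [0] * 8

    def test_tie_breaking_is_stable(self):
        # [2, 2, 1]: the smallest value (position 2) ranks first, the two
        # equal values keep occurrence order -> permutation (2, 0, 1),
        # lexicographic index 4 among the 6 permutations of 3 elements
        seq = ordinal_symbolize([2, 2, 1], ComplexityParams(m=3))
        assert seq.symbols.tolist() == [4]

    def test_symbol_count_and_range(self, rng):
        params = ComplexityParams(m=4, tau=2)
        x = rng.standard_normal(100)
        seq = ordinal_symbolize(x, params)
        assert len(seq) == 100 - 3 * 2
        assert seq.symbols.min() >= 0
        assert seq.symbols.max() < math.factorial(4)

    def test_all_permutations_reachable_and_distinct(self):
        # every ordering of 3 distinct values maps to a distinct symbol
        symbols = {
            ordinal_symbolize(list(perm), ComplexityParams(m=3)).symbols[0]
            for perm in itertools.permutations([1.0, 2.0, 3.0])
        }
        assert symbols == set(range(6))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ordinal_symbolize([1.0, 2.0], ComplexityParams(m=3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ordinal_symbolize([1.0, np.nan, 2.0, 3.0], ComplexityParams(m=2))


class TestLZ76:
    @pytest.mark.parametrize("seq,expected", [
        ([0], 1),
        ([0] * 8, 2),
        # classic exhaustive-history parse: 0|001|10|100|1000|101
        ([0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1], 6),
    ])
    def test_known_parses(self, seq, expected):
        assert lz76_exhaustive(seq) == expected  # oracle agrees on frozen value
        assert lz76_count(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lz76_count([])

    def test_matches_oracle_on_short_binary_sequences(self):
        for length in range(1, 11):
            for seq in itertools.product((0, 1), repeat=length):
                assert lz76_count(list(seq)) == lz76_exhaustive(seq), seq

    def test_matches_oracle_on_random_large_alphabet(self, rng):
        for _ in range(100):
            seq = rng.integers(0, 120, size=100)
            assert lz76_count(seq) == lz76_exhaustive(seq)


class TestPLZC:
    def test_constant_series_closed_form(self):
        # a constant series gives a single repeated symbol, c = 2
        v = plzc(np.ones(4000), ComplexityParams(m=5))
        alpha = 4000 - 4
        assert v.c_n == 2
        assert v.n_symbols == alpha
        assert v.plzc == pytest.approx(2 * math.log(alpha) / math.log(120) / alpha)

    def test_eq2_normalization(self, rng):
        x = rng.standard_normal(2000)
        v3 = plzc(x, ComplexityParams(m=4, normalization="eq3"))
        v2 = plzc(x, ComplexityParams(m=4, normalization="eq2"))
        assert v2.c_n == v3.c_n
        c, alpha = v2.c_n, v2.n_symbols
        assert v2.plzc == pytest.approx(
            c * (math.log(c) / math.log(24) + 1) / alpha)

    def test_bounds_on_noise_and_narrowband(self, rng):
        from plzcmeg import fir_bandpass, simulate_signal
        for i in range(10):
            white = rng.standard_normal(4000)
            assert 0 <= plzc(white).plzc <= 1.05
            narrow = fir_bandpass(simulate_signal(4.0, 1000.0, seed=i,
                                                  irregularity=0.5),
                                  "high_beta", 1000.0)
            assert 0 <= plzc(narrow).plzc <= 1.05

    def test_alphabet_larger_than_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            plzc(rng.standard_normal(100), ComplexityParams(m=5))  # 120 > 96

    def test_binary_motifs_match_direct_lz_normalization(self, rng):
        # for m=2 the PLZC of a series equals the normalized LZ76 complexity
        # of its own up/down symbol stream (internal consistency)
        x = rng.standard_normal(1000)
        params = ComplexityParams(m=2)
        seq = ordinal_symbolize(x, params)
        c = lz76_count(seq)
        alpha = len(seq)
        expected = c * math.log(alpha) / math.log(2) / alpha
        assert plzc(x, params).plzc == pytest.approx(expected)

    def test_plzc_array_matches_scalar_path(self, rng):
        x = rng.standard_normal((3, 2, 600))
        params = ComplexityParams(m=4)
        block = plzc_array(x, params)
        assert block.shape == (3, 2)
        for i in range(3):
            for j in range(2):
                assert block[i, j] == pytest.approx(plzc(x[i, j], params).plzc)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1))
def test_invariance_under_increasing_transforms(seed):
    """Ordinal patterns ignore amplitude: exp and affine maps leave PLZC exact."""
    x = np.random.default_rng(seed).standard_normal(500)
    params = ComplexityParams(m=4)
    base = plzc(x, params).plzc
    assert plzc(3.0 * x + 7.0, params).plzc == base
    assert plzc(np.exp(x), params).plzc == base


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1))
def test_time_reversal_preserves_bounds(seed):
    x = np.random.default_rng(seed).standard_normal(800)
    v = plzc(x[::-1], ComplexityParams(m=4))
    assert 0 <= v.plzc <= 1.05


class TestEpochPLZC:
    def test_identical_epochs_equal_single_epoch(self, rng):
        x = rng.standard_normal(500)
        params = ComplexityParams(m=4)
        assert epoch_plzc([x, x, x], params) == plzc(x, params).plzc

    def test_mean_of_two_epochs(self, rng):
        a, b = rng.standard_normal((2, 500))
        params = ComplexityParams(m=4)
        expected = (plzc(a, params).plzc + plzc(b, params).plzc) / 2
        assert epoch_plzc([a, b], params) == pytest.approx(expected)

    def test_epoch_mean_consistent_with_population(self, rng):
        # the 12-epoch mean stays within 3 SE of the single-epoch MC mean
        params = ComplexityParams(m=4)
        singles = np.array([plzc(rng.standard_normal(500), params).plzc
                            for _ in range(60)])
        mean12 = epoch_plzc([rng.standard_normal(500) for _ in range(12)], params)
        se = singles.std(ddof=1) / np.sqrt(12)
        assert abs(mean12 - singles.mean()) < 3 * se

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            epoch_plzc([])
        with pytest.raises(ValueError):
            epoch_plzc([rng.standard_normal(100), rng.standard_normal(101)],
                       ComplexityParams(m=3))
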