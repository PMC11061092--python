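import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbrain.symbolic import (
    OrdinalPatternSequence,
    SymbolizationParams,
    bandpass,
    connectivity_matrix,
    joint_symbol_distribution,
    jpe_inv,
    opposite_pattern_map,
    permutation_entropy,
    symbolize,
    wsmi,
)


def _seq(symbols, n=4, tau=1):
    return OrdinalPatternSequence(
        np.asarray(symbols), n=n, tau=tau,
        source_length=len(symbols) + (n - 1) * tau,
    )


class TestBandpass:
    fs = 500.0

    def test_in_band_sinusoid_retained(self):
        t = np.arange(4096) / self.fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, self.fs, (6.0, 13.0))
        mid = slice(500, -500)  # ignore filter edges
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(4096) / self.fs
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass(x, self.fs, (6.0, 13.0))
        rms_in = np.sqrt((x**2).mean())
        rms_out = np.sqrt((y**2).mean())
        assert rms_out <= 0.1 * rms_in

    def test_constant_series_killed(self):
        y = bandpass(np.full(2048, 3.7), self.fs, (0.5, 70.0))
        assert np.abs(y).max() < 1e-6

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), self.fs, (10.0, 300.0))


class TestSymbolize:
    def test_monotone_window_is_single_ascending_pattern(self):
        seq = symbolize(np.array([0.0, 1, 2, 3]), SymbolizationParams(n=4))
        assert len(seq) == 1
        assert seq.symbols[0] == 0  # lexicographically first = ascending

    def test_length_arithmetic(self):
        seq = symbolize(np.arange(10.0), SymbolizationParams(n=4, tau=2))
        assert len(seq) == 10 - 3 * 2

    def test_all_24_orderings_give_24_distinct_symbols(self):
        symbols = set()
        for perm in permutations(range(4)):
            s = symbolize(np.array(perm, float), SymbolizationParams(n=4))
            symbols.add(int(s.symbols[0]))
        assert symbols == set(range(24))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            symbolize(np.arange(3.0), SymbolizationParams(n=4, tau=1))

    def test_ties_rank_by_temporal_order(self):
        # (1, 1, 0): earlier of the tied samples ranks lower, so the
        # pattern equals that of (1, 1+eps, 0)
        a = symbolize(np.array([1.0, 1.0, 0.0]), SymbolizationParams(n=3))
        b = symbolize(np.array([1.0, 1.0 + 1e-12, 0.0]),
                      SymbolizationParams(n=3))
        assert a.symbols[0] == b.symbols[0]

    def test_tau_spaces_the_embedding(self):
        # with tau=2, the window reads x[0], x[2], x[4]
        x = np.array([0.0, 9.0, 1.0, 9.0, 2.0])
        seq = symbolize(x, SymbolizationParams(n=3, tau=2))
        ascending = symbolize(np.array([0.0, 1.0, 2.0]),
                              SymbolizationParams(n=3))
        assert seq.symbols[0] == ascending.symbols[0]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200)
        p = SymbolizationParams(n=4, tau=1)
        base = symbolize(x, p).symbols
        for f in (np.exp, np.tanh, lambda v: 3 * v + 7):
            np.testing.assert_array_equal(symbolize(f(x), p).symbols, base)


class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        seq = symbolize(np.arange(500.0), SymbolizationParams(n=4))
        assert permutation_entropy(seq) == 0.0

    def test_uniform_distribution_has_unit_entropy(self):
        seq = _seq(np.repeat(np.arange(24), 10))
        assert permutation_entropy(seq) == pytest.approx(1.0)

    def test_iid_noise_close_to_one_and_matches_histogram_oracle(self, rng):
        x = rng.normal(size=100_000)
        seq = symbolize(x, SymbolizationParams(n=4, tau=1))
        pe = permutation_entropy(seq)
        assert pe == pytest.approx(1.0, abs=0.01)
        # independent oracle: direct histogram entropy over pattern tuples
        windows = np.lib.stride_tricks.sliding_window_view(x, 4)
        patterns = [tuple(np.argsort(w)) for w in windows[:20_000]]
        from collections import Counter

        counts = Counter(patterns)
        p = np.array(list(counts.values())) / len(patterns)
        oracle = -(p * np.log(p)).sum() / math.log(24)
        seq2 = OrdinalPatternSequence(
            seq.symbols[:20_000], n=4, tau=1, source_length=20_003
        )
        assert permutation_entropy(seq2) == pytest.approx(oracle, abs=1e-12)


class TestJointDistribution:
    def test_identical_sequences_concentrate_on_diagonal(self):
        s = _seq([0, 3, 7, 3, 0])
        p = joint_symbol_distribution(s, s)
        assert p.sum() == pytest.approx(1.0)
        assert np.trace(p) == pytest.approx(1.0)

    def test_sums_to_one_and_nonnegative(self, rng):
        a = _seq(rng.integers(0, 24, size=1000))
        b = _seq(rng.integers(0, 24, size=1000))
        p = joint_symbol_distribution(a, b)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0)

    def test_independent_uniform_streams_approach_uniform_joint(self, rng):
        m = 2_000_000
        a = _seq(rng.integers(0, 24, size=m))
        b = _seq(rng.integers(0, 24, size=m))
        p = joint_symbol_distribution(a, b)
        assert np.abs(p - 1 / 576).max() < 5e-4

    def test_parameter_mismatch_rejected(self):
        a = _seq([0, 1], tau=1)
        b = _seq([0, 1], tau=2)
        with pytest.raises(ValueError):
            joint_symbol_distribution(a, b)


class TestOppositePatterns:
    def test_map_is_an_involution_without_fixed_points(self):
        opp = opposite_pattern_map(4)
        assert sorted(opp) == list(range(24))
        assert (opp[opp] == np.arange(24)).all()
        assert (opp != np.arange(24)).all()

    def test_matches_symbolization_of_negated_signal(self, rng):
        opp = opposite_pattern_map(4)
        x = rng.normal(size=500)
        p = SymbolizationParams(n=4)
        direct = symbolize(x, p).symbols
        negated = symbolize(-x, p).symbols
        np.testing.assert_array_equal(negated, opp[direct])


class TestWsmi:
    def test_self_coupling_is_masked_to_zero(self, rng):
        x = rng.normal(size=2000)
        s = symbolize(x, SymbolizationParams(n=4))
        assert wsmi(s, s) == 0.0
        assert wsmi(s, s, corrected=False) > 0.5

    def test_sign_inverted_signal_is_masked_to_zero(self, rng):
        x = rng.normal(size=2000)
        p = SymbolizationParams(n=4)
        a, b = symbolize(x, p), symbolize(-x, p)
        joint = joint_symbol_distribution(a, b)
        opp = opposite_pattern_map(4)
        # all mass sits on opposite-pattern cells, which carry zero weight
        assert joint[np.arange(24), opp].sum() == pytest.approx(1.0)
        assert wsmi(a, b) == 0.0

    def test_independent_streams_near_zero(self, rng):
        x = rng.normal(size=50_000)
        y = rng.normal(size=50_000)
        p = SymbolizationParams(n=4)
        val = wsmi(symbolize(x, p), symbolize(y, p))
        assert abs(val) < 0.01

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 3000))
        p = SymbolizationParams(n=4)
        a, b = symbolize(x, p), symbolize(y, p)
        assert wsmi(a, b) == pytest.approx(wsmi(b, a), abs=1e-12)

    def test_coupled_streams_exceed_independent(self, rng):
        x = rng.normal(size=20_000)
        y_dep = np.roll(x, 1) + 0.05 * rng.normal(size=20_000)
        y_ind = rng.normal(size=20_000)
        p = SymbolizationParams(n=4)
        sx = symbolize(x, p)
        assert wsmi(sx, symbolize(y_dep, p)) > wsmi(sx, symbolize(y_ind, p))


class TestJpeInv:
    def test_bounds(self, rng):
        p = SymbolizationParams(n=4)
        for _ in range(5):
            a = symbolize(rng.normal(size=500), p)
            b = symbolize(rng.normal(size=500), p)
            assert 0.0 <= jpe_inv(a, b) <= 1.0

    def test_independent_uniform_streams_near_zero(self, rng):
        m = 2_000_000
        a = _seq(rng.integers(0, 24, size=m))
        b = _seq(rng.integers(0, 24, size=m))
        assert jpe_inv(a, b) == pytest.approx(0.0, abs=0.02)

    def test_lag_coupled_streams_exceed_independent(self, rng):
        # paired comparison: a delayed near-copy versus fresh noise
        p = SymbolizationParams(n=4)
        coupled, independent = [], []
        for _ in range(5):
            x = rng.normal(size=10_000)
            y_dep = np.roll(x, 1) + 0.05 * rng.normal(size=10_000)
            y_ind = rng.normal(size=10_000)
            sx = symbolize(x, p)
            coupled.append(jpe_inv(sx, symbolize(y_dep, p)))
            independent.append(jpe_inv(sx, symbolize(y_ind, p)))
        assert min(coupled) > max(independent)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 3000))
        p = SymbolizationParams(n=4)
        a, b = symbolize(x, p), symbolize(y, p)
        assert jpe_inv(a, b) == pytest.approx(jpe_inv(b, a), abs=1e-12)

    def test_uncorrected_normalisation_uses_full_state_space(self, rng):
        m = 500_000
        a = _seq(rng.integers(0, 24, size=m))
        b = _seq(rng.integers(0, 24, size=m))
        assert jpe_inv(a, b, corrected=False) == pytest.approx(0.0, abs=0.02)


class TestConnectivityMatrix:
    def test_two_regions_symmetric(self, rng):
        p = SymbolizationParams(n=4)
        seqs = [symbolize(rng.normal(size=1000), p) for _ in range(2)]
        mat = connectivity_matrix(seqs, "wsmi")
        assert mat.values.shape == (2, 2)
        assert mat.values[0, 1] == mat.values[1, 0]
        assert mat.values[0, 0] == 0.0

    def test_region_permutation_equivariance(self, rng):
        p = SymbolizationParams(n=4)
        seqs = [symbolize(rng.normal(size=800), p) for _ in range(4)]
        mat = connectivity_matrix(seqs, "jpe_inv").values
        perm = [2, 0, 3, 1]
        mat_p = connectivity_matrix([seqs[i] for i in perm], "jpe_inv").values
        np.testing.assert_allclose(mat_p, mat[np.ix_(perm, perm)])

    def test_independent_noise_gives_near_zero_mean_wsmi(self, rng):
        p = SymbolizationParams(n=4)
        seqs = [symbolize(rng.normal(size=20_000), p) for _ in range(5)]
        mat = connectivity_matrix(seqs, "wsmi").values
        off = mat[~np.eye(5, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_run_averaging(self, rng):
        p = SymbolizationParams(n=4)
        runs = [
            [symbolize(rng.normal(size=500), p) for _ in range(3)]
            for _ in range(2)
        ]
        avg = connectivity_matrix(runs, "wsmi").values
        singles = [connectivity_matrix(r, "wsmi").values for r in runs]
        np.testing.assert_allclose(avg, np.mean(singles, axis=0))

    def test_unknown_measure_and_ragged_inputs(self, rng):
        p = SymbolizationParams(n=4)
        seqs = [symbolize(rng.normal(size=100), p) for _ in range(2)]
        with pytest.raises(ValueError):
            connectivity_matrix(seqs, "pli")
        ragged = [seqs[0], symbolize(rng.normal(size=50), p)]
        with pytest.raises(ValueError):
            connectivity_matrix(ragged, "wsmi")


class TestSymbolizationParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(n=1), dict(tau=0), dict(band=(13.0, 6.0))]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SymbolizationParams(**kwargs)
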