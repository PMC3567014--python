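import numpy as np
import pytest

from snosite import DEFAULT_ALPHABET, build_psaap, encode, frequency_matrix
from snosite.errors import EmptyTrainingSetError, FormatError, ParameterError, ShapeError
from snosite.psaap import PSAAPMatrix, encode_many, load_psaap, offsets, save_psaap


def naive_frequency(windows, pseudocount=0.0):
    """Independent per-cell counting oracle."""
    xi = windows[0].xi
    n = len(windows)
    out = np.zeros((21, 2 * xi))
    for i, sym in enumerate(DEFAULT_ALPHABET.symbols):
        for j in range(2 * xi):
            count = sum(1 for w in windows if w.flanks[j] == sym)
            out[i, j] = (count + pseudocount) / (n + 21 * pseudocount)
    return out


def random_windows(rng, n, xi, mk, label="unknown"):
    syms = DEFAULT_ALPHABET.symbols
    out = []
    for _ in range(n):
        flanks = rng.integers(0, 21, size=2 * xi)
        left = "".join(syms[i] for i in flanks[:xi])
        right = "".join(syms[i] for i in flanks[xi:])
        out.append(mk(left + "C" + right, label))
    return out


class TestFrequencyMatrix:
    def test_hand_counted_two_windows(self, mk):
        fm = frequency_matrix([mk("ACA"), mk("GCA")])
        a = DEFAULT_ALPHABET.index_of
        assert fm.values[a("A"), 0] == 0.5
        assert fm.values[a("G"), 0] == 0.5
        assert fm.values[a("A"), 1] == 1.0
        assert fm.values.sum() == pytest.approx(2.0)  # two columns, each sums to 1

    def test_single_window_point_mass(self, mk):
        fm = frequency_matrix([mk("XCX")])
        x = DEFAULT_ALPHABET.index_of("X")
        assert fm.values[x, 0] == 1.0 and fm.values[x, 1] == 1.0

    def test_columns_sum_to_one(self, mk, rng):
        ws = random_windows(rng, 37, 5, mk)
        fm = frequency_matrix(ws)
        np.testing.assert_allclose(fm.values.sum(axis=0), 1.0, atol=1e-12, rtol=0)

    def test_matches_naive_oracle(self, mk, rng):
        for n in (1, 3, 10):
            ws = random_windows(rng, n, 3, mk)
            fm = frequency_matrix(ws)
            np.testing.assert_array_equal(fm.values, naive_frequency(ws))

    def test_empty_raises(self):
        with pytest.raises(EmptyTrainingSetError):
            frequency_matrix([])

    def test_mixed_xi_raises(self, mk):
        with pytest.raises(ShapeError):
            frequency_matrix([mk("ACA"), mk("AACAA")])

    def test_negative_pseudocount_raises(self, mk):
        with pytest.raises(ParameterError):
            frequency_matrix([mk("ACA")], pseudocount=-1.0)


class TestBuildPsaap:
    def test_identical_classes_give_zero(self, mk, rng):
        ws = random_windows(rng, 8, 2, mk)
        Z = build_psaap(ws, list(ws))
        np.testing.assert_array_equal(Z.values, 0.0)

    def test_hand_computed_difference(self, mk):
        Z = build_psaap([mk("ACA"), mk("ACA")], [mk("GCG"), mk("GCG")])
        a = DEFAULT_ALPHABET.index_of
        assert Z.values[a("A"), 0] == 1.0
        assert Z.values[a("G"), 0] == -1.0
        assert Z.values[a("A"), 1] == 1.0
        assert Z.values[a("G"), 1] == -1.0
        assert np.count_nonzero(Z.values) == 4

    def test_antisymmetry_and_bounds(self, mk, rng):
        pos = random_windows(rng, 9, 4, mk)
        neg = random_windows(rng, 6, 4, mk)
        Z = build_psaap(pos, neg)
        Zswap = build_psaap(neg, pos)
        np.testing.assert_array_equal(Z.values, -Zswap.values)
        assert np.all(Z.values >= -1.0) and np.all(Z.values <= 1.0)

    def test_log_odds_sign_agrees_with_difference(self, mk):
        pos = [mk("ACA"), mk("ACA")]
        neg = [mk("GCG"), mk("GCG")]
        Zd = build_psaap(pos, neg, functional="difference")
        Zl = build_psaap(pos, neg, functional="log_odds")
        assert np.all(np.sign(Zl.values)[Zd.values != 0] == np.sign(Zd.values)[Zd.values != 0])

    def test_log_odds_needs_smoothing(self, mk):
        with pytest.raises(ParameterError):
            build_psaap([mk("ACA")], [mk("GCG")], functional="log_odds", pseudocount=0.0)


class TestEncode:
    def test_zero_matrix_gives_zero_vector(self, mk):
        Z = PSAAPMatrix(
            values=np.zeros((21, 4)), xi=2, functional="difference",
            pseudocount=0.0, n_pos=1, n_neg=1,
        )
        np.testing.assert_array_equal(encode(mk("AACAA"), Z), np.zeros(4))

    def test_lookup_of_hand_computed_matrix(self, mk):
        Z = build_psaap([mk("ACA"), mk("ACA")], [mk("GCG"), mk("GCG")])
        np.testing.assert_array_equal(encode(mk("ACA"), Z), [1.0, 1.0])
        np.testing.assert_array_equal(encode(mk("GCG"), Z), [-1.0, -1.0])

    def test_xi_mismatch_raises(self, mk):
        Z = build_psaap([mk("ACA")], [mk("GCG")])
        with pytest.raises(ShapeError):
            encode(mk("AACAA"), Z)

    def test_encode_many_matches_encode(self, mk, rng):
        pos = random_windows(rng, 5, 3, mk)
        neg = random_windows(rng, 5, 3, mk)
        Z = build_psaap(pos, neg)
        stacked = encode_many(pos, Z)
        for i, w in enumerate(pos):
            np.testing.assert_array_equal(stacked[i], encode(w, Z))


class TestSerialization:
    def test_round_trip_bitwise(self, mk, rng):
        Z = build_psaap(random_windows(rng, 7, 10, mk), random_windows(rng, 5, 10, mk))
        loaded = load_psaap(save_psaap(Z))
        np.testing.assert_array_equal(loaded.values, Z.values)
        assert (loaded.xi, loaded.functional, loaded.pseudocount) == (10, "difference", 0.0)
        assert (loaded.n_pos, loaded.n_neg) == (7, 5)

    def test_missing_row_raises(self, mk):
        text = save_psaap(build_psaap([mk("ACA")], [mk("GCG")]))
        truncated = "\n".join(text.splitlines()[:-1]) + "\n"  # drop the X row
        with pytest.raises(FormatError):
            load_psaap(truncated)

    def test_column_count_mismatch_raises(self, mk):
        text = save_psaap(build_psaap([mk("ACA")], [mk("GCG")]))
        broken = text.replace("xi=1", "xi=10")
        with pytest.raises(FormatError):
            load_psaap(broken)

    def test_bad_magic_raises(self):
        with pytest.raises(FormatError):
            load_psaap("residue\t-1\t1\n")

    def test_offsets_order(self):
        assert offsets(3) == [-3, -2, -1, 1, 2, 3]
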