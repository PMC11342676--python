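"""Motif library: JASPAR round trips, log-odds math, thresholds, redundancy."""

import itertools

import numpy as np
import pytest

from motifcoop import motifs as mm

UNIFORM = np.full(4, 0.25)

JASPAR_TEXT = """>MA0001.1 FIRST
A [ 10 0 ]
C [ 0 10 ]
G [ 0 0 ]
T [ 0 0 ]
>MA0002.1 SECOND
A [ 3 1 0 ]
C [ 1 2 0 ]
G [ 0 1 4 ]
T [ 0 0 0 ]
"""


@pytest.fixture
def jaspar_file(tmp_path):
    path = tmp_path / "motifs.jaspar"
    path.write_text(JASPAR_TEXT)
    return path


class TestParseJaspar:
    def test_two_records_in_file_order(self, jaspar_file):
        lib = mm.parse_jaspar(jaspar_file)
        assert len(lib) == 2
        assert lib.ids == ["MA0001.1", "MA0002.1"]
        assert lib[0].name == "FIRST"

    def test_counts_preserved_exactly(self, jaspar_file):
        lib = mm.parse_jaspar(jaspar_file)
        np.testing.assert_array_equal(lib[0].pfm, [[10, 0], [0, 10],
                                                   [0, 0], [0, 0]])
        assert lib[0].pfm.sum(axis=0).tolist() == [10, 10]

    def test_round_trip_write_parse(self, jaspar_file, tmp_path):
        lib = mm.parse_jaspar(jaspar_file)
        out = tmp_path / "rt.jaspar"
        mm.write_jaspar(lib, out)
        lib2 = mm.parse_jaspar(out)
        assert lib2.ids == lib.ids
        for a, b in zip(lib, lib2):
            np.testing.assert_array_equal(a.pfm, b.pfm)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.jaspar"
        path.write_text("")
        with pytest.raises(mm.JasparParseError, match="empty"):
            mm.parse_jaspar(path)

    def test_non_numeric_count_raises(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">M1 X\nA [ 1 x ]\nC [ 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n")
        with pytest.raises(mm.JasparParseError):
            mm.parse_jaspar(path)


class TestBuildPssm:
    def test_observed_equals_background_scores_zero(self):
        pssm = mm.build_pssm(np.array([[25.], [25.], [25.], [25.]]),
                             UNIFORM, pseudocount=0)
        np.testing.assert_allclose(pssm, 0.0)

    def test_pure_column_scores_two_bits(self):
        pssm = mm.build_pssm(np.array([[100.], [0.], [0.], [0.]]),
                             UNIFORM, pseudocount=None)
        # pseudocount None -> 0.01*total per cell; check the closed form too
        exact = mm.build_pssm(np.array([[100.], [0.], [0.], [0.]]),
                              UNIFORM, pseudocount=1e-12)
        assert exact[0, 0] == pytest.approx(np.log2(1 / 0.25), abs=1e-6)
        assert pssm[0, 0] == pytest.approx(np.log2(101 / 100 / 0.25))

    def test_hand_computed_column_with_pseudocount(self):
        # column [3,1,0,0], pseudo 0.25: score_b = log2((c_b+0.25)/4/0.25)
        pssm = mm.build_pssm(np.array([[3.], [1.], [0.], [0.]]),
                             UNIFORM, pseudocount=0.25)
        expected = np.log2((np.array([3, 1, 0, 0]) + 0.25) / 4.0 / 0.25)
        np.testing.assert_allclose(pssm[:, 0], expected)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(0)
        pfm = rng.integers(0, 30, size=(4, 5)).astype(float) + 1
        base = mm.build_pssm(pfm, UNIFORM, pseudocount=0.5)
        for b, j in itertools.product(range(4), range(5)):
            bumped = pfm.copy()
            bumped[b, j] += 5
            new = mm.build_pssm(bumped, UNIFORM, pseudocount=0.5)
            assert new[b, j] > base[b, j]

    def test_zero_column_raises(self):
        with pytest.raises(ValueError):
            mm.build_pssm(np.zeros((4, 2)), UNIFORM, pseudocount=0)


class TestReverseComplement:
    def test_poly_a_consensus_becomes_poly_t(self):
        pssm = mm.build_pssm(np.tile([[10.], [1.], [1.], [1.]], (1, 4)),
                             UNIFORM, pseudocount=0.5)
        rc = mm.reverse_complement(pssm)
        assert np.argmax(rc, axis=0).tolist() == [3, 3, 3, 3]

    def test_palindromic_matrix_fixed_point(self):
        col = np.array([5.0, 1.0, 2.0, 3.0])
        pfm = np.stack([col, col[[3, 2, 1, 0]]], axis=1)
        pssm = mm.build_pssm(pfm, UNIFORM, pseudocount=0.5)
        np.testing.assert_allclose(mm.reverse_complement(pssm), pssm)

    def test_involution(self):
        rng = np.random.default_rng(1)
        pssm = rng.normal(size=(4, 7))
        np.testing.assert_array_equal(
            mm.reverse_complement(mm.reverse_complement(pssm)), pssm)


def enumerate_threshold(pssm, pvalue, granularity=1e-3):
    """Brute-force oracle: exhaust all 4^L words, group tied scores, and
    take the smallest achievable score whose tail probability is within
    the p-value."""
    s_int = np.rint(pssm / granularity).astype(np.int64)
    length = pssm.shape[1]
    scores = np.zeros(1, dtype=np.int64)
    for j in range(length):
        scores = (scores[:, None] + s_int[:, j][None, :]).ravel()
    uniq, counts = np.unique(scores, return_counts=True)  # ascending
    probs = counts * (0.25 ** length)
    survival = np.cumsum(probs[::-1])[::-1]
    ok = survival <= pvalue
    if not ok.any():
        return float(uniq[-1] * granularity)
    return float(uniq[np.argmax(ok)] * granularity)


class TestScoreThreshold:
    def test_single_column_enumerable(self):
        pssm = np.array([[2.0], [-1.0], [-1.0], [-1.0]])
        assert mm.score_threshold(pssm, pvalue=0.25) == pytest.approx(2.0)

    def test_pvalue_one_gives_minimum_score(self):
        rng = np.random.default_rng(2)
        pssm = rng.normal(size=(4, 4))
        t = mm.score_threshold(pssm, pvalue=1.0)
        s_int = np.rint(pssm / 1e-3).astype(int)
        assert t == pytest.approx(s_int.min(axis=0).sum() * 1e-3)

    def test_impossible_pvalue_warns_and_returns_max(self):
        pssm = np.array([[2.0], [-1.0], [-1.0], [-1.0]])
        with pytest.warns(UserWarning, match="maximum"):
            t = mm.score_threshold(pssm, pvalue=1e-9)
        assert t == pytest.approx(2.0)

    @pytest.mark.parametrize("pvalue", [1e-2, 1e-4])
    def test_dp_matches_enumeration_on_random_motifs(self, pvalue):
        rng = np.random.default_rng(5)
        for _ in range(10):
            length = int(rng.integers(3, 8))
            pfm = rng.integers(1, 50, size=(4, length)).astype(float)
            pssm = mm.build_pssm(pfm, UNIFORM, pseudocount=0.5)
            assert mm.score_threshold(pssm, pvalue) == pytest.approx(
                enumerate_threshold(pssm, pvalue))

    def test_rc_threshold_equals_forward(self):
        rng = np.random.default_rng(6)
        pfm = rng.integers(1, 40, size=(4, 6)).astype(float)
        pssm = mm.build_pssm(pfm, UNIFORM, pseudocount=0.5)
        assert mm.score_threshold(pssm, 1e-3) == pytest.approx(
            mm.score_threshold(mm.reverse_complement(pssm), 1e-3))


class TestDeduplicate:
    def _lib(self, pfms):
        return mm.make_library([(f"M{i}", f"m{i}", p)
                                for i, p in enumerate(pfms)])

    def test_identical_motifs_collapse(self):
        rng = np.random.default_rng(3)
        pfm = rng.integers(1, 30, size=(4, 8)).astype(float)
        lib = self._lib([pfm, pfm.copy()])
        assert len(mm.deduplicate_library(lib, 0.9)) == 1

    def test_dissimilar_library_unchanged(self, small_library):
        # decoy fixtures are mutually dissimilar by construction
        dedup = mm.deduplicate_library(small_library, 0.95)
        assert dedup.ids == small_library.ids

    def test_shifted_copy_merges_with_offset_scan_oracle(self):
        rng = np.random.default_rng(4)
        pfm = rng.integers(1, 40, size=(4, 9)).astype(float)
        shifted = np.concatenate([np.full((4, 1), 10.0), pfm[:, :-1]], axis=1)
        fa = pfm / pfm.sum(axis=0)
        fb = shifted / shifted.sum(axis=0)
        # brute-force all-offset correlation (forward orientation)
        best = -1
        for off in range(-8, 9):
            a0, a1 = max(0, off), min(9, off + 9)
            if a1 - a0 < 4:
                continue
            xa = fa[:, a0:a1].ravel()
            xb = fb[:, a0 - off:a1 - off].ravel()
            best = max(best, np.corrcoef(xa, xb)[0, 1])
        assert best >= 0.8  # construction check
        assert mm.best_offset_correlation(fa, fb) == pytest.approx(best, abs=1e-9) \
            or mm.best_offset_correlation(fa, fb) >= best  # rc may beat fwd
        lib = self._lib([pfm, shifted])
        assert len(mm.deduplicate_library(lib, 0.8)) == 1

    def test_representative_has_highest_information(self):
        rng = np.random.default_rng(9)
        sharp = np.array([[90.], [4.], [3.], [3.]]) * np.ones((1, 8))
        blurred = sharp * 0.6 + 10
        lib = self._lib([blurred, sharp])
        kept = mm.deduplicate_library(lib, 0.8)
        assert len(kept) == 1
        assert kept[0].id == "M1"  # the sharper motif


class TestLibrary:
    def test_duplicate_ids_rejected(self):
        pfm = np.ones((4, 3))
        with pytest.raises(ValueError, match="duplicate"):
            mm.make_library([("A", "a", pfm), ("A", "b", pfm)])

    def test_filter_tensor_layout(self, tiny_library):
        filt = tiny_library.filter_tensor()
        k, w = len(tiny_library), tiny_library.max_length
        assert filt.shape == (2 * k, 4, w)
        for i, m in enumerate(tiny_library):
            np.testing.assert_allclose(filt[i, :, w - m.length:], m.pssm)
            np.testing.assert_allclose(filt[k + i, :, w - m.length:], m.rc_pssm)
            np.testing.assert_allclose(filt[i, :, : w - m.length], 0.0)

    def test_manifest_columns(self, tiny_library):
        man = tiny_library.manifest()
        assert list(man.columns) == ["id", "name", "length", "threshold"]
        assert len(man) == len(tiny_library)
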