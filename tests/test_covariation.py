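"""Matrix- and position-level covariation statistics."""

import itertools

import numpy as np
import pytest

from shapecov.covariation import (
    NarrowGrooveCall,
    binned_pcc,
    call_narrow_minor_groove,
    groove_profiles_by_residue,
    hypergeom_upper_tail,
    hypergeometric_map,
    matrix_pcc,
    mi_map,
    shuffle_null,
)
from shapecov.matrices import SimilarityMatrix
from shapecov.protein import ProteinCohort, load_substitution_matrix, protein_similarity
from shapecov.shape import ShapeProfile


def _sym(values, labels=None, metric="protein_blosum"):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"p{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(labels, values, metric)


def _profiles(mgw_rows, ids=None):
    mgw_rows = np.asarray(mgw_rows, dtype=float)
    n, L = mgw_rows.shape
    ids = ids or [f"p{i}" for i in range(n)]
    return [
        ShapeProfile(
            protein_id=pid,
            length=L,
            mgw=row,
            prot=np.zeros(L),
            roll=np.zeros(L - 1),
            helt=np.zeros(L - 1),
            n_sites=1,
        )
        for pid, row in zip(ids, mgw_rows)
    ]


class TestMatrixPCC:
    def test_self_correlation_is_one(self, rng):
        v = rng.normal(size=(5, 5))
        a = _sym(v + v.T)
        assert matrix_pcc(a, a)["pcc"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        v = rng.normal(size=(5, 5))
        a = _sym(v + v.T)
        b = _sym(-(v + v.T))
        assert matrix_pcc(a, b)["pcc"] == pytest.approx(-1.0)

    def test_four_by_four_oracle(self):
        a = _sym([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]])
        b = _sym([[0, 2, 1, 7], [2, 0, 3, 2], [1, 3, 0, 5], [7, 2, 5, 0]])
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 7, 3, 2, 5], dtype=float)
        expected = np.corrcoef(x, y)[0, 1]
        res = matrix_pcc(a, b)
        assert res["pcc"] == pytest.approx(expected)
        assert res["n_pairs"] == 6

    def test_reordering_both_matrices_is_invariant(self, rng):
        v = rng.normal(size=(6, 6))
        w = rng.normal(size=(6, 6))
        a, b = _sym(v + v.T), _sym(w + w.T)
        base = matrix_pcc(a, b)["pcc"]
        order = list(np.array(a.labels)[rng.permutation(6)])
        assert matrix_pcc(a.reordered(order), b.reordered(order))["pcc"] == pytest.approx(base)

    def test_label_mismatch_rejected(self, rng):
        v = rng.normal(size=(4, 4))
        a = _sym(v + v.T)
        b = _sym(v + v.T, labels=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError, match="labels"):
            matrix_pcc(a, b)

    def test_zero_variance_rejected(self):
        a = _sym(np.ones((4, 4)))
        b = _sym(np.arange(16.0).reshape(4, 4) + np.arange(16.0).reshape(4, 4).T)
        with pytest.raises(ValueError, match="variance"):
            matrix_pcc(a, b)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(5)
    n = 20
    msa = ["".join(rng.choice(list("ARNDCEQGH"), 30)) for _ in range(n)]
    cohort = ProteinCohort(ids=[f"p{i}" for i in range(n)], msa=msa)
    mat = load_substitution_matrix("BLOSUM45")
    sim = protein_similarity(cohort, mat)
    return cohort, mat, sim


class TestShuffleNull:
    def test_fixed_seed_reproducible(self, setup):
        cohort, mat, sim = setup
        other = _sym(sim.values * 2.0, labels=list(sim.labels))
        a = shuffle_null(cohort, other, mat, n_shuffles=50, seed=3)
        b = shuffle_null(cohort, other, mat, n_shuffles=50, seed=3)
        np.testing.assert_array_equal(a.distribution, b.distribution)

    def test_extreme_observation_hits_floor(self, setup):
        cohort, mat, sim = setup
        # comparing the matrix with itself: observed PCC 1, unreachable by
        # any non-identity relabeling of this unstructured cohort
        other = _sym(sim.values.copy(), labels=list(sim.labels))
        res = shuffle_null(cohort, other, mat, n_shuffles=100, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_empirical == pytest.approx(1 / 101)

    def test_null_mean_near_zero_without_structure(self, setup, rng):
        cohort, mat, sim = setup
        w = rng.normal(size=(20, 20))
        other = _sym(w + w.T, labels=list(sim.labels))
        res = shuffle_null(cohort, other, mat, n_shuffles=500, seed=1)
        assert abs(res.mean) < 0.02


class TestBinnedPCC:
    def test_large_bins_reduce_to_plain_pcc(self, rng):
        v = rng.uniform(0, 1, size=(8, 8))
        w = rng.uniform(0, 1, size=(8, 8))
        a, b = _sym((v + v.T) / 2), _sym((w + w.T) / 2)
        plain = matrix_pcc(a, b)["pcc"]
        res = binned_pcc(a, b, n_per_bin=10_000, seed=0)
        assert res["pcc"] == pytest.approx(plain)

    def test_binned_tracks_unbinned_within_sampling_error(self):
        rng = np.random.default_rng(9)
        n = 40
        w = rng.uniform(0, 1, size=(n, n))
        b_vals = (w + w.T) / 2
        a_vals = b_vals + rng.normal(0, 0.15, size=(n, n))
        a_vals = (a_vals + a_vals.T) / 2
        a, b = _sym(a_vals), _sym(np.clip(b_vals, 0, 1))
        plain = matrix_pcc(a, b)["pcc"]
        diffs = [
            binned_pcc(a, b, n_per_bin=60, seed=s)["pcc"] - plain for s in range(20)
        ]
        assert abs(np.mean(diffs)) < 0.05

    def test_empty_bins_rejected(self, rng):
        v = rng.normal(size=(5, 5))
        a = _sym(v + v.T)
        b = _sym(-np.abs(v + v.T) - 10.0)  # all pair values below every bin
        with pytest.raises(ValueError, match="empty"):
            binned_pcc(a, b, n_per_bin=5, seed=0)


class TestNarrowCalls:
    def test_threshold_boundary_inclusive(self):
        profs = _profiles([[5.12, 5.13, np.nan]])
        calls = call_narrow_minor_groove(profs)
        assert calls.calls[0, 0] == 1.0  # exactly at threshold: narrow
        assert calls.calls[0, 1] == 0.0
        assert np.isnan(calls.calls[0, 2])

    @pytest.mark.parametrize("thr", [4.9, 5.0, 5.1, 5.2])
    def test_threshold_override(self, thr):
        profs = _profiles([[5.05]])
        calls = call_narrow_minor_groove(profs, threshold=thr)
        assert calls.calls[0, 0] == float(5.05 <= thr)
        assert calls.threshold == thr


def _enum_upper_tail(k, N, s, m):
    """Exhaustive enumeration over all m-subsets of N items."""
    hits = total = 0
    basic = set(range(s))
    for narrow in itertools.combinations(range(N), m):
        total += 1
        if len(basic & set(narrow)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricMap:
    def test_small_case_matches_enumeration(self):
        # N=4, s=2, m=2, k=2: 1 of 6 subsets has full overlap
        assert hypergeom_upper_tail(2, 4, 2, 2) == pytest.approx(1 / 6)
        assert hypergeom_upper_tail(2, 4, 2, 2) == pytest.approx(
            _enum_upper_tail(2, 4, 2, 2)
        )

    def test_k_zero_gives_one(self):
        assert hypergeom_upper_tail(0, 10, 3, 4) == pytest.approx(1.0)

    def test_monotone_in_k(self):
        ps = [hypergeom_upper_tail(k, 10, 5, 6) for k in range(0, 6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_map_values_and_degenerate_flags(self):
        cohort = ProteinCohort(
            ids=["a", "b", "c", "d"], msa=["RA", "RA", "QA", "QA"]
        )
        calls = NarrowGrooveCall(
            labels=list(cohort.ids),
            calls=np.array([[1.0], [1.0], [0.0], [0.0]]),
            threshold=5.12,
        )
        maps = hypergeometric_map(cohort, calls)
        assert maps.hypergeom_p[0, 0] == pytest.approx(1 / 6)  # column of R/R/Q/Q
        assert maps.degenerate[1, 0]  # column 1 has no basic residue: s = 0
        assert maps.hypergeom_p[1, 0] == 1.0

    def test_planted_column_is_argmax(self, rng):
        n = 30
        residues = ["R"] * 15 + ["Q"] * 15
        msa = []
        for i in range(n):
            row = "".join(rng.choice(list("ACDEFGILMNPQSTVWY"), 10))
            msa.append(row[:4] + residues[i] + row[5:])
        cohort = ProteinCohort(ids=[f"p{i}" for i in range(n)], msa=msa)
        calls_arr = rng.random((n, 6)) < 0.3
        calls_arr[:, 2] = [r == "R" for r in residues]  # planted DNA position 2
        calls = NarrowGrooveCall(
            labels=list(cohort.ids), calls=calls_arr.astype(float), threshold=5.12
        )
        maps = hypergeometric_map(cohort, calls)
        assert maps.argmax_cell("neglog10_p") == (4, 2)


class TestMIMap:
    @staticmethod
    def _cohort_calls(symbols, calls01):
        n = len(symbols)
        cohort = ProteinCohort(
            ids=[f"p{i}" for i in range(n)], msa=[s + "A" for s in symbols]
        )
        calls = NarrowGrooveCall(
            labels=list(cohort.ids),
            calls=np.asarray(calls01, dtype=float).reshape(n, 1),
            threshold=5.12,
        )
        return cohort, calls

    def test_independent_by_construction_gives_zero(self):
        # product structure: every (residue, call) combination equally often
        symbols = ["R", "R", "Q", "Q"]
        calls01 = [1, 0, 1, 0]
        cohort, calls = self._cohort_calls(symbols, calls01)
        assert mi_map(cohort, calls).mi[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_dependence_is_one_bit(self):
        cohort, calls = self._cohort_calls(["R", "R", "Q", "Q"], [1, 1, 0, 0])
        assert mi_map(cohort, calls).mi[0, 0] == pytest.approx(1.0)

    def test_six_protein_table_matches_direct_summation(self):
        symbols = ["R", "R", "K", "Q", "Q", "Q"]
        calls01 = [1, 1, 0, 1, 0, 0]
        cohort, calls = self._cohort_calls(symbols, calls01)
        # independent plug-in summation
        from collections import Counter

        joint = Counter(zip(symbols, calls01))
        n = len(symbols)
        px = Counter(symbols)
        py = Counter(calls01)
        expected = sum(
            (c / n) * np.log2((c / n) / ((px[s] / n) * (py[v] / n)))
            for (s, v), c in joint.items()
        )
        assert mi_map(cohort, calls).mi[0, 0] == pytest.approx(expected)

    def test_relabeling_residues_is_invariant(self):
        cohort1, calls = self._cohort_calls(["R", "R", "K", "Q", "Q", "Q"], [1, 1, 0, 1, 0, 0])
        cohort2, _ = self._cohort_calls(["W", "W", "F", "Y", "Y", "Y"], [1, 1, 0, 1, 0, 0])
        a = mi_map(cohort1, calls).mi[0, 0]
        b = mi_map(cohort2, calls).mi[0, 0]
        assert a == pytest.approx(b)

    def test_bounded_by_one_bit_against_binary_call(self, rng):
        symbols = list(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), 40))
        calls01 = list((rng.random(40) < 0.5).astype(int))
        cohort, calls = self._cohort_calls(symbols, calls01)
        v = mi_map(cohort, calls).mi[0, 0]
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_basic_alphabet_mode(self):
        cohort, calls = self._cohort_calls(["R", "K", "Q", "Q"], [1, 1, 0, 0])
        v = mi_map(cohort, calls, alphabet="basic").mi[0, 0]
        assert v == pytest.approx(1.0)  # basic vs non-basic perfectly separates


class TestGrooveClassProfiles:
    def test_single_class_skips_tests(self):
        profs = _profiles(np.full((4, 5), 5.3))
        cohort = ProteinCohort(
            ids=[p.protein_id for p in profs], msa=["QQQQQ"] * 4
        )
        res = groove_profiles_by_residue(cohort, profs, column=0)
        assert res.pvalues == {}
        assert res.tests_skipped

    def test_planted_narrowing_flagged(self):
        rng = np.random.default_rng(2)
        n = 60
        mgw = rng.normal(5.4, 0.08, size=(n, 6))
        mgw[:30, 2] -= 0.5  # R carriers narrower at one position
        residues = ["R"] * 30 + ["Q"] * 30
        profs = _profiles(mgw, ids=[f"p{i}" for i in range(n)])
        cohort = ProteinCohort(
            ids=[f"p{i}" for i in range(n)], msa=[r + "AAAA" for r in residues]
        )
        res = groove_profiles_by_residue(cohort, profs, column=0)
        assert res.significant["R"][2]
        assert not res.significant["R"][[0, 1, 3, 4, 5]].any()
        gap = res.classes["other"][2] - res.classes["R"][2]
        assert gap == pytest.approx(0.5, abs=0.1)

    def test_type_one_error_controlled(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mgw = rng.normal(5.4, 0.1, size=(30, 6))
            residues = ["R"] * 15 + ["Q"] * 15
            profs = _profiles(mgw, ids=[f"p{i}" for i in range(30)])
            cohort = ProteinCohort(
                ids=[f"p{i}" for i in range(30)], msa=[r + "AA" for r in residues]
            )
            res = groove_profiles_by_residue(cohort, profs, column=0)
            if res.significant["R"].any():
                flagged += 1
        assert flagged <= 1  # alpha 5e-5 over 6 positions: false flags are rare
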