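"""Pentamer shape prediction, profile averaging and shape similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapecov._seq import all_kmers, canonical, revcomp
from shapecov.shape import (
    ShapeProfile,
    ShapeTable,
    average_shape_profile,
    load_shape_table,
    predict_shape,
    shape_similarity,
)

dna = st.text(alphabet="ACGT", min_size=8, max_size=20)


def _records_from(table: ShapeTable) -> dict:
    out = {}
    for row in table.to_frame().itertuples(index=False):
        out[row.pentamer] = {
            "mgw": row.MGW,
            "prot": row.ProT,
            "roll": (row.Roll1, row.Roll2),
            "helt": (row.HelT1, row.HelT2),
        }
    return out


class TestShapeTable:
    def test_canonical_512_round_trip(self, shape_table, tmp_path):
        path = tmp_path / "table.tsv"
        shape_table.to_tsv(path)
        reloaded = load_shape_table(path)
        np.testing.assert_allclose(reloaded.mgw, shape_table.mgw, atol=1e-9)
        np.testing.assert_allclose(reloaded.roll, shape_table.roll, atol=1e-9)
        assert len(reloaded.to_frame()) == 512

    def test_raw_1024_dialect_accepted(self, shape_table):
        records = _records_from(shape_table)
        full = dict(records)
        for p, rec in records.items():
            rc = revcomp(p)
            if rc not in full:
                full[rc] = {
                    "mgw": rec["mgw"],
                    "prot": rec["prot"],
                    "roll": rec["roll"][::-1],
                    "helt": rec["helt"][::-1],
                }
        reloaded = ShapeTable.from_records(full)
        np.testing.assert_allclose(reloaded.mgw, shape_table.mgw)

    def test_missing_pentamer_named(self, shape_table):
        records = _records_from(shape_table)
        records.pop("AAAAA")
        with pytest.raises(ValueError, match="AAAAA"):
            ShapeTable.from_records(records)

    def test_revcomp_inconsistency_rejected(self, shape_table):
        records = _records_from(shape_table)
        bad = dict(records)
        rec = records["AAAAA"]
        bad["TTTTT"] = {**rec, "mgw": rec["mgw"] + 1.0, "roll": rec["roll"][::-1]}
        with pytest.raises(ValueError, match="AAAAA.*TTTTT|TTTTT.*AAAAA"):
            ShapeTable.from_records(bad)

    def test_nonpositive_mgw_rejected(self, shape_table):
        records = _records_from(shape_table)
        records["AAAAA"] = {**records["AAAAA"], "mgw": -1.0}
        with pytest.raises(ValueError):
            ShapeTable.from_records(records)


class TestPredictShape:
    def test_window_arithmetic_8mer(self, shape_table):
        pred = predict_shape("ACGTACGT", shape_table)
        assert np.isfinite(pred["mgw"][2:6]).all()
        assert np.isnan(pred["mgw"][[0, 1, 6, 7]]).all()
        # steps: defined 1..5 (0-based), single pentamer context at 1 and 5
        assert np.isfinite(pred["roll"][1:6]).all()
        assert np.isnan(pred["roll"][[0, 6]]).all()

    def test_constant_table(self, constant_table):
        pred = predict_shape("ACGTACGTAC", constant_table)
        mgw = pred["mgw"]
        assert np.allclose(mgw[np.isfinite(mgw)], 5.0)
        roll = pred["roll"]
        assert np.allclose(roll[np.isfinite(roll)], 2.0)

    @settings(max_examples=60, deadline=None)
    @given(seq=dna)
    def test_strand_symmetry(self, shape_table, seq):
        fwd = predict_shape(seq, shape_table)
        rev = predict_shape(revcomp(seq), shape_table)
        np.testing.assert_allclose(fwd["mgw"], rev["mgw"][::-1], equal_nan=True)
        np.testing.assert_allclose(fwd["prot"], rev["prot"][::-1], equal_nan=True)
        # step j of the forward strand is step L-2-j of the reverse strand
        np.testing.assert_allclose(fwd["roll"], rev["roll"][::-1], equal_nan=True)
        np.testing.assert_allclose(fwd["helt"], rev["helt"][::-1], equal_nan=True)

    def test_rejects_short_and_ambiguous(self, shape_table):
        with pytest.raises(ValueError):
            predict_shape("ACGT", shape_table)
        with pytest.raises(ValueError):
            predict_shape("ACGTN", shape_table)


class TestAverageProfile:
    def test_mean_of_identical_sites_is_prediction(self, shape_table):
        seq = "TTAATTGC"
        prof = average_shape_profile([seq, seq], shape_table)
        pred = predict_shape(seq, shape_table)
        np.testing.assert_allclose(prof.mgw, pred["mgw"], equal_nan=True)
        np.testing.assert_allclose(prof.helt, pred["helt"], equal_nan=True)
        assert prof.n_sites == 2

    def test_palindromic_pair_gives_symmetric_profile(self, shape_table):
        s = "TTAGCTAA"
        prof = average_shape_profile([s, revcomp(s)], shape_table)
        np.testing.assert_allclose(prof.mgw, prof.mgw[::-1], equal_nan=True)

    def test_hand_summation_oracle(self, shape_table):
        # three 6-mers: each defines MGW at its positions 2 and 3 only
        sites = ["AATTCC", "TTAAGG", "ACGTAC"]
        prof = average_shape_profile(sites, shape_table)
        for pos in (2, 3):
            expected = np.mean(
                [shape_table.lookup(s[pos - 2 : pos + 3])["mgw"] for s in sites]
            )
            assert prof.mgw[pos] == pytest.approx(expected)
        assert np.isnan(prof.mgw[[0, 1, 4, 5]]).all()

    def test_empty_and_mismatched_inputs(self, shape_table):
        with pytest.raises(ValueError):
            average_shape_profile([], shape_table)
        with pytest.raises(ValueError):
            average_shape_profile(["AATTCC", "AATTCCA"], shape_table)

    def test_values_within_table_range(self, shape_table, rng):
        sites = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(20)]
        prof = average_shape_profile(sites, shape_table)
        lo, hi = shape_table.parameter_range("mgw")
        fin = prof.mgw[np.isfinite(prof.mgw)]
        assert ((fin >= lo) & (fin <= hi)).all()


def _profile(pid: str, mgw_vals) -> ShapeProfile:
    mgw = np.asarray(mgw_vals, dtype=float)
    L = len(mgw)
    return ShapeProfile(
        protein_id=pid,
        length=L,
        mgw=mgw,
        prot=np.zeros(L),
        roll=np.zeros(L - 1),
        helt=np.zeros(L - 1),
        n_sites=1,
    )


class TestShapeSimilarity:
    def test_identical_profiles_score_zero(self):
        sim = shape_similarity([_profile("a", [5.0, 5.5]), _profile("b", [5.0, 5.5])], "mgw")
        assert sim.values[0, 1] == 0.0

    def test_euclidean_value(self):
        sim = shape_similarity(
            [_profile("a", [5.0, 5.5]), _profile("b", [5.2, 5.1])], "mgw"
        )
        assert sim.values[0, 1] == pytest.approx(-np.sqrt(0.2), abs=1e-12)

    def test_nonpositive_and_symmetric(self, rng):
        profs = [_profile(f"p{i}", rng.normal(5.3, 0.3, 6)) for i in range(5)]
        sim = shape_similarity(profs, "mgw")
        assert (sim.values <= 1e-12).all()
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 0.0)

    def test_negated_values_obey_triangle_inequality(self, rng):
        profs = [_profile(f"p{i}", rng.normal(5.3, 0.3, 6)) for i in range(6)]
        d = -shape_similarity(profs, "mgw").values
        n = len(profs)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_missing_positions_dropped_pairwise(self):
        a = _profile("a", [np.nan, 5.0, 5.5])
        b = _profile("b", [5.9, 5.2, 5.1])
        sim = shape_similarity([a, b], "mgw")
        assert sim.values[0, 1] == pytest.approx(-np.sqrt(0.2))
        assert sim.meta["positions_used"] == 2

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            shape_similarity([_profile("a", [5.0, 5.0])], "mgw")
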