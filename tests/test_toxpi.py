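"""ToxPi scoring core: transform, filter, normalization, ranking, bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import toxscreen as ts
from toxscreen.hts import HitCall, PairResult
from toxscreen.toxpi import Band

from _oracles import oracle_toxpi


def active(z, ac50=1.0, cid="C", aid="A"):
    return PairResult(cid, aid, HitCall.ACTIVE, ac50, z)


class TestNeglogMolar:
    @pytest.mark.parametrize(
        "ac50_uM, expected", [(1.0, 6.0), (0.1, 7.0), (1_000_000.0, 0.0)]
    )
    def test_decade_scale(self, ac50_uM, expected):
        assert ts.neglog_molar(ac50_uM) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            ts.neglog_molar(bad)


class TestInputValue:
    def test_worked_example(self):
        assert ts.input_value(active(5.4)) == pytest.approx(11.4, abs=1e-12)

    def test_z_at_cutoff_excluded(self):
        assert ts.input_value(active(2.0)) == 0.0

    def test_inactive_scores_zero(self):
        assert ts.input_value(PairResult("C", "A", HitCall.INACTIVE)) == 0.0
        assert ts.input_value(PairResult("C", "A", HitCall.SINGLE_CONC)) == 0.0
        assert ts.input_value(PairResult("C", "A", HitCall.UNTESTED)) == 0.0

    def test_potency_plus_specificity_sum(self):
        assert ts.input_value(active(3.0, ac50=0.1)) == pytest.approx(10.0, abs=1e-12)

    def test_floored_at_zero_for_supramolar_ac50(self):
        # AC50 of 1e8 uM (100 M) gives -2 + 2.5 > 0, but 1e10 uM would go negative
        assert ts.input_value(active(2.5, ac50=1e10)) == 0.0

    @given(z=st.floats(-5, 20), log_ac50=st.floats(-3, 3))
    def test_nonnegative_and_filter_property(self, z, log_ac50):
        value = ts.input_value(active(z, ac50=10.0 ** log_ac50))
        assert value >= 0.0
        if z <= 2.0:
            assert value == 0.0


class TestInputMatrix:
    def test_all_inactive_gives_zeros(self, tiny_matrix):
        chems = [ts.ChemicalRecord("C1"), ts.ChemicalRecord("C2")]
        assays = [ts.AssayEndpoint("A1")]
        matrix = ts.HTSMatrix(
            chems, assays, [PairResult(c.chemical_id, "A1", HitCall.INACTIVE) for c in chems]
        )
        assert (ts.build_input_matrix(matrix) == 0.0).all().all()

    def test_single_active_entry(self, tiny_matrix):
        iv = ts.build_input_matrix(tiny_matrix)
        assert iv.at["C1", "A1"] == pytest.approx(11.4, abs=1e-12)
        assert iv.at["C1", "A3"] == 0.0  # untested pair scores 0
        assert (iv >= 0.0).all().all()


class TestSliceRawSums:
    def test_hand_sums(self, tiny_matrix):
        iv = ts.build_input_matrix(tiny_matrix)
        model = ts.ProcessModel(
            "m",
            (
                ts.SliceDef("pair", ("A1", "A2"), 0.5),
                ts.SliceDef("solo", ("A3",), 0.5),
            ),
        )
        sums = ts.slice_raw_sums(iv, model)
        assert sums.at["C1", "pair"] == pytest.approx(11.4, abs=1e-12)
        assert sums.at["C1", "solo"] == 0.0
        # one-assay slice equals that assay's input value
        assert sums.at["C2", "solo"] == iv.at["C2", "A3"]

    def test_missing_model_assays_contribute_zero(self, tiny_matrix):
        iv = ts.build_input_matrix(tiny_matrix)
        model = ts.ProcessModel("m", (ts.SliceDef("ghost", ("NOPE",), 1.0),))
        assert (ts.slice_raw_sums(iv, model) == 0.0).all().all()


def two_slice_model():
    return ts.ProcessModel(
        "m", (ts.SliceDef("s1", ("A1",), 0.5), ts.SliceDef("s2", ("A2",), 0.5))
    )


class TestToxPiScores:
    def test_max_in_every_slice_scores_one(self):
        iv = pd.DataFrame(
            {"A1": [10.0, 3.0, 0.0], "A2": [8.0, 1.0, 0.0]}, index=["top", "mid", "low"]
        )
        results = ts.toxpi_scores(iv, two_slice_model())
        assert results[0].chemical_id == "top"
        assert results[0].overall_score == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_chemicals_split_score(self):
        iv = pd.DataFrame({"A1": [10.0, 0.0], "A2": [0.0, 10.0]}, index=["A", "B"])
        results = ts.toxpi_scores(iv, two_slice_model())
        assert all(r.overall_score == pytest.approx(0.5, abs=1e-12) for r in results)

    def test_degenerate_slices_score_zero(self):
        iv = pd.DataFrame({"A1": [5.0, 5.0], "A2": [1.0, 1.0]}, index=["A", "B"])
        results = ts.toxpi_scores(iv, two_slice_model())
        assert all(r.overall_score == 0.0 for r in results)
        assert all(r.band is Band.NOT_ACTIVE for r in results)

    def test_fewer_than_two_chemicals_rejected(self):
        iv = pd.DataFrame({"A1": [5.0], "A2": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="population"):
            ts.toxpi_scores(iv, two_slice_model())

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        iv = pd.DataFrame(
            rng.uniform(0, 15, (7, 4)),
            index=[f"C{i}" for i in range(7)],
            columns=["A1", "A2", "A3", "A4"],
        )
        model = ts.ProcessModel(
            "m",
            tuple(ts.SliceDef(f"s{j}", (f"A{j + 1}",), 0.25) for j in range(4)),
        )
        for res in ts.toxpi_scores(iv, model):
            assert res.overall_score == pytest.approx(
                sum(res.slice_scores.values()), abs=1e-12
            )
            assert 0.0 <= res.overall_score <= 1.0
            for name, comp in res.slice_scores.items():
                assert 0.0 <= comp <= 0.25 + 1e-12

    def test_slice_shift_leaves_components_unchanged(self):
        rng = np.random.default_rng(11)
        iv = pd.DataFrame(
            rng.uniform(0, 15, (6, 2)), index=[f"C{i}" for i in range(6)],
            columns=["A1", "A2"],
        )
        shifted = iv.copy()
        shifted["A1"] += 7.0  # constant added to every raw sum of slice s1
        base = ts.toxpi_scores(iv, two_slice_model())
        after = ts.toxpi_scores(shifted, two_slice_model())
        for r1, r2 in zip(base, after):
            assert r1.chemical_id == r2.chemical_id
            assert r1.overall_score == pytest.approx(r2.overall_score, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_own_input(self, seed):
        rng = np.random.default_rng(seed)
        iv = pd.DataFrame(
            rng.uniform(0, 15, (5, 2)), index=[f"C{i}" for i in range(5)],
            columns=["A1", "A2"],
        )
        model = two_slice_model()
        before = {r.chemical_id: r.overall_score for r in ts.toxpi_scores(iv, model)}
        bumped = iv.copy()
        bumped.at["C0", "A1"] += 5.0
        after = {r.chemical_id: r.overall_score for r in ts.toxpi_scores(bumped, model)}
        assert after["C0"] >= before["C0"] - 1e-12
        affected_weight = 0.5
        for cid in before:
            if cid != "C0":
                assert after[cid] <= before[cid] + affected_weight + 1e-12

    def test_matches_straight_line_oracle(self):
        from conftest import random_hts_matrix

        for seed in range(20):
            matrix = random_hts_matrix(seed)
            iv = ts.build_input_matrix(matrix)
            model = ts.ProcessModel(
                "m",
                (
                    ts.SliceDef("s1", ("A0", "A1", "A2"), 0.25),
                    ts.SliceDef("s2", ("A3",), 0.25),
                    ts.SliceDef("s3", ("A4", "A5"), 0.5),
                ),
            )
            expected = oracle_toxpi(
                {c: dict(iv.loc[c]) for c in iv.index},
                [(s.slice_name, list(s.assay_ids), s.weight) for s in model.slices],
            )
            for res in ts.toxpi_scores(iv, model):
                comp, overall = expected[res.chemical_id]
                assert res.overall_score == pytest.approx(overall, abs=1e-12)
                for name, value in res.slice_scores.items():
                    assert value == pytest.approx(comp[name], abs=1e-12)


def make_results(scores):
    return [
        ts.ToxPiResult(f"C{i}", {}, s) for i, s in enumerate(scores)
    ]


class TestRankAndBand:
    def test_boundary_is_inclusive(self):
        # 1000 active chemicals; rank 50 sits exactly on the 5% boundary
        results = ts.rank_and_band(make_results(np.linspace(1000, 1, 1000)))
        at_50 = next(r for r in results if r.rank == 50)
        assert at_50.band is Band.TOP5

    def test_zero_score_is_not_active(self):
        results = ts.rank_and_band(make_results([1.0, 0.5, 0.0]))
        assert results[-1].band is Band.NOT_ACTIVE

    def test_top15_threshold(self):
        results = ts.rank_and_band(make_results(np.linspace(200, 1, 200)))
        at_25 = next(r for r in results if r.rank == 25)
        assert at_25.band is Band.TOP15  # 25/200 = 0.125

    def test_ties_share_minimum_rank(self):
        results = ts.rank_and_band(make_results([3.0, 2.0, 2.0, 1.0]))
        ranks = {r.chemical_id: r.rank for r in results}
        assert ranks["C1"] == ranks["C2"] == 2
        assert ranks["C3"] == 4

    def test_full_library_denominator(self):
        scores = [1.0, 0.9] + [0.0] * 38  # 2 active of 40 total
        active_only = ts.rank_and_band(make_results(scores), "active_only")
        full = ts.rank_and_band(make_results(scores), "full_library")
        second_ao = next(r for r in active_only if r.rank == 2)
        second_fl = next(r for r in full if r.rank == 2)
        assert second_ao.band is Band.NONE  # 2/2 = 1.0
        assert second_fl.band is Band.TOP5  # 2/40 = 0.05


class TestPrioritize:
    def test_top5_in_one_model_flags(self):
        a = ts.ToxPiResult("C1", {}, 0.9, 1, Band.TOP5)
        b = ts.ToxPiResult("C2", {}, 0.1, 2, Band.NONE)
        assert ts.prioritize({"m1": [a, b]}) == {"C1"}

    def test_top15_everywhere_does_not_flag(self):
        results = {
            f"m{i}": [ts.ToxPiResult("C1", {}, 0.2, 10, Band.TOP15)] for i in range(6)
        }
        assert ts.prioritize(results) == set()

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            ts.prioritize({})


class TestRarScores:
    def test_bounds_and_rank_agreement_with_raw_sums(self):
        rng = np.random.default_rng(5)
        rar = ts.rar_model()
        iv = pd.DataFrame(
            rng.uniform(0, 12, (8, len(rar.assay_ids))),
            index=[f"C{i}" for i in range(8)],
            columns=rar.assay_ids,
        )
        scores = ts.rar_scores(iv, rar)
        raw = iv.sum(axis=1)
        # single-slice normalization: order-isomorphic to the raw sums
        assert list(scores.sort_values(ascending=False).index) == list(
            raw.sort_values(ascending=False).index
        )
        assert scores.loc[raw.idxmax()] == pytest.approx(1.0, abs=1e-12)

    def test_inactive_everywhere_scores_zero(self):
        rar = ts.rar_model()
        iv = pd.DataFrame(
            [[0.0] * 4, [1.0, 0.0, 0.0, 0.0]], index=["dead", "live"],
            columns=rar.assay_ids,
        )
        assert ts.rar_scores(iv, rar)["dead"] == 0.0
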