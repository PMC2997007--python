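"""Unit and property tests for the spot-to-ratio processing chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoarray import array_processing as ap
from phytoarray import synthetic_data as sd

from conftest import random_ratio_matrix


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "fg,bg,expected", [(500, 100, 400), (50, 100, 1), (100, 100, 1), (1.5, 0, 1.5)]
    )
    def test_subtraction_with_floor(self, fg, bg, expected):
        assert ap.background_correct(fg, bg) == expected

    def test_vectorized_matches_elementwise_oracle(self, rng):
        fg = rng.uniform(0, 5000, size=1000)
        bg = rng.uniform(0, 1000, size=1000)
        out = ap.background_correct(fg, bg)
        oracle = np.array([max(f - b, 1.0) for f, b in zip(fg, bg)])
        np.testing.assert_array_equal(out, oracle)

    @pytest.mark.parametrize("fg,bg", [(-1, 0), (np.nan, 0), (0, np.inf), (0, -5)])
    def test_rejects_invalid_intensities(self, fg, bg):
        with pytest.raises(ap.ValidationError):
            ap.background_correct(fg, bg, probe_id="p1", channel="ch_test_fg")


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "ratios,method,expected",
        [
            ([1.0, 1.0, 1.0, 1.0], "median", 1.0),
            ([0.30, 0.32, 0.34, 0.40], "median", 0.33),
            ([2.0], "median", 2.0),
            ([1.0, 2.0, 3.0, 6.0], "mean", 3.0),
        ],
    )
    def test_examples(self, ratios, method, expected):
        assert ap.aggregate_replicates(ratios, method) == pytest.approx(expected)

    def test_zero_usable_replicates_is_an_error(self):
        with pytest.raises(ap.ValidationError):
            ap.aggregate_replicates([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=4))
    def test_median_matches_numpy(self, ratios):
        assert ap.aggregate_replicates(ratios) == np.median(ratios)


class TestNormalization:
    def test_reference_row_exactly_one_and_idempotent(self, rng):
        m = random_ratio_matrix(rng, n_genes=20, treatments=tuple("abcdef"))
        m.index = ["ACTB"] + list(m.index[1:])
        normed = ap.normalize_to_reference(m, "ACTB")
        assert (normed.loc["ACTB"] == 1.0).all()
        again = ap.normalize_to_reference(normed, "ACTB")
        pd.testing.assert_frame_equal(again, normed)

    def test_direct_recomputation_oracle(self, rng):
        m = random_ratio_matrix(rng, n_genes=10)
        normed = ap.normalize_to_reference(m, "g0")
        for g in m.index:
            for c in m.columns:
                assert normed.loc[g, c] == m.loc[g, c] / m.loc["g0", c]

    def test_unit_reference_leaves_matrix_unchanged(self, rng):
        m = random_ratio_matrix(rng)
        m.loc["g0"] = 1.0
        pd.testing.assert_frame_equal(ap.normalize_to_reference(m, "g0"), m)

    def test_missing_reference_errors(self, rng):
        with pytest.raises(ap.ValidationError, match="not in matrix"):
            ap.normalize_to_reference(random_ratio_matrix(rng), "ACTB")

    def test_nonpositive_reference_names_conditions(self, rng):
        m = random_ratio_matrix(rng)
        m.loc["g0", "b"] = np.nan
        with pytest.raises(ap.ValidationError, match="b"):
            ap.normalize_to_reference(m, "g0")

    def test_non_housekeeping_reference_rejected_with_design(self, rng):
        m = random_ratio_matrix(rng, n_genes=3)
        design = pd.DataFrame(
            {
                "gene_symbol": ["g0", "g1", "g2"],
                "gene_id": [1, 2, 3],
                "category": ["other"] * 3,
                "is_housekeeping": [False, True, False],
            }
        )
        with pytest.raises(ap.ValidationError, match="housekeeping"):
            ap.normalize_to_reference(m, "g0", design)
        ap.normalize_to_reference(m, "g1", design)  # housekeeping gene is fine

    def test_estimator_transform_equals_function(self, rng):
        m = random_ratio_matrix(rng)
        m.index = ["ACTB"] + list(m.index[1:])
        est = ap.ReferenceNormalizer().fit(m)
        pd.testing.assert_frame_equal(est.transform(m), ap.normalize_to_reference(m, "ACTB"))
        assert est.get_params() == {"reference_gene": "ACTB"}


class TestRatioOfRatios:
    @pytest.mark.parametrize("a,b,expected", [(0.5, 1.0, 0.5), (0.96, 3.0, 0.32), (7.3, 7.3, 1.0)])
    def test_examples(self, a, b, expected):
        assert ap.ratio_of_ratios(a, b) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ap.ValidationError):
            ap.ratio_of_ratios(0.0, 1.0)

    def test_treatment_vs_lps_requires_matching_time(self):
        m = pd.DataFrame(
            [[2.0, 3.0]],
            index=["g"],
            columns=pd.MultiIndex.from_tuples(
                [("LPS", 0.5), ("shikonin+LPS", 2.0)], names=["treatment", "time_h"]
            ),
        )
        with pytest.raises(ap.ValidationError, match="no LPS column at time"):
            ap.treatment_vs_lps(m)


class TestFoldChangeFilter:
    def test_inclusive_boundaries(self):
        m = pd.DataFrame({"t": [1.0, 3.0, 1 / 3, 2.99, 0.34]},
                         index=["null", "up_edge", "down_edge", "near_up", "near_down"])
        hits = ap.filter_fold_change(m, treatments=["t"])
        assert dict(zip(hits["gene_symbol"], hits["direction"])) == {
            "up_edge": "up", "down_edge": "down"
        }

    @pytest.mark.parametrize("rule", ["any_treatment", "all_treatments"])
    @pytest.mark.parametrize("direction", ["up", "down", "both"])
    def test_matches_bruteforce_double_loop(self, rng, rule, direction):
        for _ in range(25):
            m = random_ratio_matrix(rng, n_genes=15)
            hits = ap.filter_fold_change(m, rule=rule, direction=direction)
            got = set(zip(hits["gene_symbol"], hits["direction"]))
            expected = set()
            for g in m.index:
                for direc, passes in (
                    ("up", [m.loc[g, t] >= 3 for t in m.columns]),
                    ("down", [m.loc[g, t] <= 1 / 3 for t in m.columns]),
                ):
                    if direction not in (direc, "both"):
                        continue
                    ok = any(passes) if rule == "any_treatment" else all(passes)
                    if ok:
                        expected.add((g, direc))
            assert got == expected

    def test_nan_never_triggers_and_fails_all_rule(self):
        m = pd.DataFrame({"a": [5.0, np.nan], "b": [np.nan, 4.0]}, index=["g1", "g2"])
        any_hits = ap.filter_fold_change(m, rule="any_treatment")
        assert set(any_hits["gene_symbol"]) == {"g1", "g2"}
        all_hits = ap.filter_fold_change(m, rule="all_treatments")
        assert all_hits.empty

    def test_empty_treatment_set_errors(self, rng):
        with pytest.raises(ap.ValidationError, match="empty treatment"):
            ap.filter_fold_change(random_ratio_matrix(rng), treatments=[])

    def test_threshold_must_exceed_one(self, rng):
        with pytest.raises(ap.ValidationError):
            ap.filter_fold_change(random_ratio_matrix(rng), threshold=1.0)

    def test_printed_table_rows_retained(self):
        # NFATC3 emodin 0.06 at 0.5 h -> down; MAP2K4 BF 3.56 at 4 h -> up
        t1 = sd.table_ratio_matrix("table1")
        hits1 = ap.filter_fold_change(t1, treatments=["shikonin", "emodin"],
                                      direction="down", time_h=0.5)
        row = hits1[hits1["gene_symbol"] == "NFATC3"]
        assert len(row) == 1 and row["emodin"].iloc[0] == 0.06
        t2 = sd.table_ratio_matrix("table2")
        hits2 = ap.filter_fold_change(t2, treatments=["cytopiloyne", "BF"],
                                      direction="up", time_h=4.0)
        row = hits2[hits2["gene_symbol"] == "MAP2K4"]
        assert len(row) == 1 and row["BF"].iloc[0] == 3.56

    def test_hit_table_sorted_by_category_then_gene_id(self):
        fx = sd.load_fixture("table1")
        hits = ap.filter_fold_change(
            sd.table_ratio_matrix("table1"),
            treatments=["shikonin", "emodin"], direction="down", time_h=0.5,
            design=fx.payload[["gene_symbol", "gene_id", "category"]].assign(
                is_housekeeping=False),
        )
        cat_rank = hits["category"].map(
            {c: i for i, c in enumerate(ap.CATEGORIES)}).to_numpy()
        assert (np.diff(cat_rank) >= 0).all()
        for cat in hits["category"].unique():
            ids = hits.loc[hits["category"] == cat, "gene_id"].to_numpy()
            assert (np.diff(ids) >= 0).all()

    def test_estimator_wraps_function(self, rng):
        m = random_ratio_matrix(rng)
        est = ap.FoldChangeFilter(direction="up").fit(m)
        pd.testing.assert_frame_equal(
            est.transform(m), ap.filter_fold_change(m, direction="up")
        )


class TestFullChainRoundTrip:
    def test_planted_noiseless_effects_recovered_exactly(self, small_experiment):
        sim = small_experiment
        matrix = ap.process_experiment(sim.spot_tables, sim.manifest, sim.design)
        vs_lps = ap.treatment_vs_lps(matrix)
        for row in sim.truth.itertuples(index=False):
            if row.treatment == "LPS":
                continue
            got = vs_lps.loc[row.gene_symbol, (row.treatment[:-4], row.time_h)]
            lps_e = sim.truth.query(
                "gene_symbol == @row.gene_symbol and treatment == 'LPS' "
                "and time_h == @row.time_h"
            )["effect"].iloc[0]
            assert got == pytest.approx(row.effect / lps_e, abs=1e-9)

    def test_flagged_spots_excluded_and_all_flagged_gene_missing(self, small_experiment):
        sim = small_experiment
        hyb = sim.manifest["hybridization_id"].iloc[0]
        spots = sim.spot_tables[hyb].copy()
        # corrupt 3 of 4 replicates of G003 but flag them 'bad'
        mask = (spots["gene_symbol"] == "G003") & (spots["replicate"] < 4)
        spots.loc[mask, ["ch_test_fg", "flag"]] = [9e9, "bad"]
        spots.loc[spots["gene_symbol"] == "G004", "flag"] = "bad"
        ratios = ap.process_hybridization(spots, sim.design)
        clean = ap.process_hybridization(sim.spot_tables[hyb], sim.design)
        assert ratios["G003"] == pytest.approx(clean["G003"])
        assert np.isnan(ratios["G004"])

    def test_matrix_tsv_round_trip(self, small_experiment, tmp_path):
        sim = small_experiment
        matrix = ap.process_experiment(sim.spot_tables, sim.manifest, sim.design)
        path = tmp_path / "ratios.tsv"
        ap.write_ratio_matrix(matrix, path)
        back = ap.read_ratio_matrix(path)
        assert list(back.columns) == list(matrix.columns)
        np.testing.assert_allclose(back.to_numpy(), matrix.to_numpy(), rtol=1e-12)
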