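"""Data containers, CSV dialects, standardization and packaged fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specscreen import tables
from specscreen.tables import (PeakTable, ValidationError, load_peak_table,
                               load_fixture, standardize_peaks,
                               write_peak_table)


class TestLoadPeakTable:
    def test_samples_dialect_parses_matrix(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1,G2\nP1,1,2\nP2,3,4\n")
        t = load_peak_table(f, dialect="samples")
        assert t.peak_ids == ["P1", "P2"]
        assert t.observations == ["G1", "G2"]
        np.testing.assert_array_equal(t.areas.to_numpy(), [[1, 2], [3, 4]])

    def test_duplicate_peak_id_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1\nP1,1\nP1,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_peak_table(f)

    def test_negative_area_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1,G2\nP1,1,-2\n")
        with pytest.raises(ValidationError, match="negative"):
            load_peak_table(f)

    def test_plus_minus_cells_parse_to_mean_and_sd(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1,G2,compound\nP1,10 ± 1,20 ± 2,alpha\n"
                     "P2,30 ± 3,40 ± 4,beta\n")
        t = load_peak_table(f, dialect="group_means")
        assert t.areas.loc["P1", "G2"] == 20
        assert t.area_sd.loc["P2", "G1"] == 3
        assert t.meta.loc["P1", "compound"] == "alpha"

    def test_ragged_group_means_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1,G2\nP1,10 ± 1,20 ± 2\nP2,30 ± 3,\n")
        with pytest.raises(ValidationError):
            load_peak_table(f, dialect="group_means")

    def test_missing_values_abort_rather_than_impute(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("peak,G1,G2\nP1,1,\n")
        with pytest.raises(ValidationError):
            load_peak_table(f)


class TestRoundTrip:
    @pytest.mark.parametrize("with_sd", [False, True])
    def test_write_read_reproduces_12_significant_digits(self, tmp_path,
                                                         small_peaks, with_sd):
        t = small_peaks
        if with_sd:
            t = PeakTable(areas=t.areas, area_sd=t.areas * 0.05,
                          meta=pd.DataFrame({"compound": "c"}, index=t.areas.index))
        f = tmp_path / "t.csv"
        write_peak_table(t, f)
        back = load_peak_table(f, "group_means" if with_sd else "samples")
        np.testing.assert_allclose(back.areas, t.areas, rtol=1e-12)
        if with_sd:
            np.testing.assert_allclose(back.area_sd, t.area_sd, rtol=1e-12)

    def test_efficacy_round_trip(self, tmp_path, table6):
        f = tmp_path / "e.csv"
        tables.write_efficacy_panel(table6, f)
        back = tables.load_efficacy_panel(f)
        np.testing.assert_allclose(back.values, table6.values, rtol=1e-12)


class TestStandardize:
    def test_arithmetic_sequence(self):
        t = PeakTable(areas=pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"],
                                         columns=list("abc")))
        z = standardize_peaks(t).areas.to_numpy().ravel()
        np.testing.assert_allclose(z, [-1, 0, 1], atol=1e-12)

    def test_hand_zscore(self):
        row = [2, 4, 4, 4, 5, 5, 7, 9]
        t = PeakTable(areas=pd.DataFrame([row], index=["P1"],
                                         columns=[f"o{i}" for i in range(8)]))
        z = standardize_peaks(t).areas.to_numpy().ravel()
        # mean 5, sample sd 2.138089935...; frozen from the hand z-score
        assert z[0] == pytest.approx(-1.403121520040228, abs=1e-12)

    def test_constant_row_maps_to_zero_with_warning(self):
        t = PeakTable(areas=pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                                         index=["P1", "P2"],
                                         columns=list("abc")))
        with pytest.warns(UserWarning, match="constant"):
            z = standardize_peaks(t)
        np.testing.assert_array_equal(z.areas.loc["P1"], [0, 0, 0])

    def test_single_observation_rejected(self):
        t = PeakTable(areas=pd.DataFrame([[1.0]], index=["P1"], columns=["a"]))
        with pytest.raises(ValidationError):
            standardize_peaks(t)

    @given(st.lists(st.lists(st.floats(0.1, 1e6), min_size=4, max_size=4),
                    min_size=1, max_size=6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rows_have_zero_mean_unit_sd(self, rows):
        areas = pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))],
                             columns=list("abcd"))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            z = standardize_peaks(PeakTable(areas=areas)).areas.to_numpy()
        sd = z.std(axis=1, ddof=1)
        constant = np.ptp(np.asarray(rows), axis=1) < 1e-30
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(sd[~constant], 1.0, atol=1e-9)


class TestFixtures:
    def test_unknown_fixture_lists_available(self):
        with pytest.raises(KeyError, match="table3"):
            load_fixture("nope")

    def test_peak_area_table_spot_checks(self, table3):
        assert table3.areas.shape == (57, 4)
        checks = {
            ("A11", "PW4"): 765815, ("A11", "PW1"): 695037,
            ("A1", "PW1"): 2998, ("A1", "PW2"): 17988,
            ("A24", "PW4"): 8451971, ("A27", "PW2"): 53118,
            ("A34", "PW3"): 2233245, ("A40", "PW3"): 28551,
            ("B6", "PW3"): 524700, ("B16", "PW4"): 4097,
            ("B17", "PW2"): 1193, ("B17", "PW1"): 0,
        }
        for (peak, grp), v in checks.items():
            assert table3.areas.loc[peak, grp] == v
        assert table3.area_sd.loc["A11", "PW4"] == 23316
        assert table3.meta.loc["A11", "compound"] == "Geniposide"
        assert table3.meta.loc["A24", "herb"] == "SR"

    def test_efficacy_panel_spot_checks(self, table6):
        v = table6.values
        assert v.shape == (4, 8)
        assert v.loc["PW4", "Overall rating"] == 51.46
        assert v.loc["PW1", "Overall rating"] == 43.35
        assert v.loc["PW1", "W/D ratio of Lung"] == 4.88
        assert v.loc["PW2", "TNF-α"] == 80.12
        assert v.loc["PW3", "Lung injury score"] == 53.49
        assert v.loc["PW4", "Neutrophils in BALF"] == 75.00
        assert v.loc["PW3", "IL-6"] == 36.13
        assert v.loc["PW2", "IL-1β"] == 66.79
        assert v.loc["PW1", "Protein in BALF"] == 36.62
        assert v.loc["PW2", "Overall rating"] == 47.17

    def test_consensus_sets_spot_checks(self, table8):
        assert len(table8) == 8
        assert table8["Lung injury score"] == ["A40", "A27", "A11", "B14", "B16"]
        assert table8["Neutrophils in BALF"] == ["A24", "A26", "A30", "A34",
                                                 "A17", "B11"]
        assert table8["TNF-α"] == ["A7", "A32", "A18", "A6"]
        assert table8["Overall rating"] == ["A11", "B16", "A27", "A1", "B17"]

    def test_centrality_table_spot_checks(self, table9):
        assert table9.shape[0] == 20
        assert table9.loc["A27", "degree"] == 5
        assert table9.loc["A27", "betweenness"] == 0.1878
        assert table9.loc["A27", "closeness"] == 0.4531
        assert table9.loc["A18", "closeness"] == 0.4028
        assert table9.loc["B14", "closeness"] == 0.3537
        assert table9.loc["A40", "degree"] == 2
        assert table9.loc["A1", "degree"] == 4
        assert table9.loc["B11", "betweenness"] == 0.0611
        assert int(table9["median_flag"].sum()) == 8
        assert table9.loc["A11", "median_flag"] == 1

    def test_published_weights(self, published_weights):
        assert published_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert published_weights["Lung injury score"] == 0.3080
        assert published_weights["Protein in BALF"] == 0.0168

    def test_herb_maps_cover_all_peaks(self, table3, herb_map):
        assert set(herb_map.unique()) == {"SR", "GF"}
        assert len(herb_map) == 57
        alt = load_fixture("herb_map_network")
        assert set(alt.index) <= set(herb_map.index)
        # the two published tables genuinely disagree for a few compounds
        disagreements = [p for p in alt.index if alt[p] != herb_map[p]]
        assert "A27" in disagreements
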