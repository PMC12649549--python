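import math

import numpy as np
import pandas as pd
import pytest

from permamp import (
    AssayError,
    Condition,
    DoseResponse,
    MICPanel,
    MICValue,
    Strain,
    compare_to_parent,
    estimate_hc10,
    export_heatmap_matrix,
    geometric_mean_mic,
    hemolysis_percent,
    leakage_percent,
    parse_mic_cell,
    repair_rate,
    round_half_up,
    therapeutic_index,
    ti_report,
    write_ti_report,
)
from reference_values import SELECTIVITY_TABLE


class TestParseMicCell:
    def test_censored_cell(self):
        assert parse_mic_cell(">50") == MICValue(50.0, "above")

    def test_exact_cell(self):
        assert parse_mic_cell("0.78") == MICValue(0.78, "exact")

    @pytest.mark.parametrize("bad", ["≤0", "", ">", "fifty", ">-3", "0"])
    def test_malformed_cells_raise_with_context(self, bad):
        with pytest.raises(AssayError, match="row 3, col MIC|cell"):
            parse_mic_cell(bad, context="row 3, col MIC")


class TestGeometricMean:
    def test_parent_all_strains(self, mic_panel):
        gm = geometric_mean_mic(mic_panel.mic_values("W5K/A9W"))
        assert round_half_up(gm, 1) == 4.1

    def test_censored_substitution(self):
        vals = [parse_mic_cell(c) for c in ["50", "25", ">50", "25", ">50"]]
        assert round_half_up(geometric_mean_mic(vals), 1) == 50.0

    def test_constant_values(self):
        assert geometric_mean_mic([MICValue(6.25)] * 4) == pytest.approx(6.25)

    def test_bounds_of_substituted_values(self, mic_panel):
        for pep in mic_panel.peptides():
            vals = mic_panel.mic_values(pep)
            subs = [100.0 if v.censor == "above" else v.concentration for v in vals]
            gm = geometric_mean_mic(vals)
            assert min(subs) <= gm <= max(subs)

    def test_censoring_never_decreases_gm(self):
        vals = [MICValue(12.5), MICValue(25.0), MICValue(50.0)]
        base = geometric_mean_mic(vals)
        for i in range(len(vals)):
            worse = list(vals)
            worse[i] = MICValue(50.0, "above")
            assert geometric_mean_mic(worse) >= base

    def test_empty_rejected(self):
        with pytest.raises(AssayError):
            geometric_mean_mic([])


class TestSignalFormulas:
    @pytest.mark.parametrize(
        "sample,expected", [(0.05, 0.0), (1.25, 100.0), (0.65, 50.0)]
    )
    def test_hemolysis_blank_full_midpoint(self, sample, expected):
        assert hemolysis_percent(sample, 0.05, 1.25) == pytest.approx(expected)

    def test_hemolysis_zero_denominator(self):
        with pytest.raises(AssayError):
            hemolysis_percent(0.5, 1.0, 1.0)

    def test_hemolysis_negative_preserved(self):
        assert hemolysis_percent(0.03, 0.05, 1.25) < 0

    @pytest.mark.parametrize("F,expected", [(120.0, 0.0), (900.0, 100.0), (510.0, 50.0)])
    def test_leakage_formula(self, F, expected):
        assert leakage_percent(F, 120.0, 900.0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a0,a24,expected", [(100.0, 0.0, 1.0), (80.0, 80.0, 0.0), (100.0, 25.0, 0.75)]
    )
    def test_repair_rate(self, a0, a24, expected):
        assert repair_rate(a0, a24) == pytest.approx(expected)

    def test_repair_rate_negative_when_gap_grows(self):
        assert repair_rate(100.0, 130.0) == pytest.approx(-0.3)

    def test_repair_rate_rejects_nonpositive_area(self):
        with pytest.raises(AssayError):
            repair_rate(0.0, 10.0)


class TestEstimateHC10:
    def test_exact_hit_returned_verbatim(self):
        curve = DoseResponse((10.0,), (10.0,))
        est = estimate_hc10(curve)
        assert est.value == 10.0 and not est.censored

    def test_all_below_threshold_returns_cap(self):
        curve = DoseResponse((1.0, 2.0, 4.0), (1.0, 2.0, 5.0))
        est = estimate_hc10(curve)
        assert est.value == 108.7 and est.censored

    @pytest.mark.parametrize("hc50,hill", [(30.0, 1.0), (60.0, 2.0), (20.0, 4.0)])
    def test_against_closed_form_logistic_inverse(self, hc50, hill):
        grid = np.array([108.7 / 2.0 ** k for k in range(9, -1, -1)])
        resp = 100.0 / (1.0 + (hc50 / grid) ** hill)
        est = estimate_hc10(DoseResponse(tuple(grid), tuple(resp)))
        analytic = hc50 * 9.0 ** (-1.0 / hill)
        assert abs(math.log2(est.value / analytic)) <= 1.0

    def test_matches_dense_brute_force_scan(self):
        hc50, hill = 45.0, 2.5
        grid = np.array([108.7 / 2.0 ** k for k in range(7, -1, -1)])
        resp = 100.0 / (1.0 + (hc50 / grid) ** hill)
        est = estimate_hc10(DoseResponse(tuple(grid), tuple(resp)))
        dense = np.logspace(math.log10(grid[0]), math.log10(grid[-1]), 200000)
        dense_resp = np.interp(np.log10(dense), np.log10(grid), resp)
        brute = dense[np.argmax(dense_resp >= 10.0)]
        assert est.value == pytest.approx(brute, rel=1e-3)

    def test_nonmonotone_curve_flagged_first_crossing_used(self):
        curve = DoseResponse((1.0, 2.0, 4.0, 8.0), (5.0, 3.0, 15.0, 80.0))
        est = estimate_hc10(curve)
        assert est.nonmonotone
        assert 2.0 < est.value < 4.0

    def test_first_point_already_above_threshold(self):
        curve = DoseResponse((1.0, 2.0), (40.0, 90.0))
        assert estimate_hc10(curve).value == 1.0


class TestTherapeuticIndex:
    def test_unit_ratio(self):
        assert therapeutic_index(5.0, 5.0) == 1.0

    def test_parent_combined_cell(self, mic_panel):
        gm = geometric_mean_mic(mic_panel.mic_values("W5K/A9W"))
        assert round_half_up(therapeutic_index(30.0, gm), 1) == 7.3

    def test_censored_hc10_cell(self, mic_panel):
        gm = geometric_mean_mic(mic_panel.mic_values("W5K10"))
        assert round_half_up(therapeutic_index(108.7, gm), 1) == 20.0

    def test_anti_monotone_in_gm_linear_in_hc10(self):
        assert therapeutic_index(100.0, 4.0) < therapeutic_index(100.0, 2.0)
        assert therapeutic_index(100.0, 4.0) == pytest.approx(
            2.0 * therapeutic_index(50.0, 4.0)
        )


class TestSelectivityTable:
    """Full reconstruction of the published GM / TI table from panel inputs."""

    def test_all_rows_reproduce_at_printed_precision(self, mic_panel, hc10_table):
        hc10 = dict(zip(hc10_table["peptide"], hc10_table["hc10_ug_ml"]))
        report = ti_report(mic_panel, hc10).set_index("peptide")
        ti_off = 0
        for pep, (gm_n, gm_p, gm_a, hc, ti_n, ti_p, ti_a) in SELECTIVITY_TABLE.items():
            row = report.loc[pep]
            assert round_half_up(row["GM_neg"], 1) == gm_n, pep
            assert round_half_up(row["GM_pos"], 1) == gm_p, pep
            assert round_half_up(row["GM_all"], 1) == gm_a, pep
            assert row["HC10"] == hc, pep
            # TI agrees to the printed digit; allow one last-digit tick for
            # the source table's inconsistent rounding of ratios.
            for col, printed in (("TI_neg", ti_n), ("TI_pos", ti_p), ("TI_all", ti_a)):
                computed = round_half_up(row[col], 1)
                assert abs(computed - printed) <= 0.1 + 1e-9, (pep, col)
                ti_off += computed != printed
        assert ti_off <= 1

    def test_report_restricted_to_baseline_medium(self, mic_panel, hc10_table):
        other = mic_panel.data.copy()
        other["medium"] = "LYM"
        other["mic"] = other["mic"] * 4
        mixed = MICPanel(pd.concat([mic_panel.data, other], ignore_index=True))
        hc10 = dict(zip(hc10_table["peptide"], hc10_table["hc10_ug_ml"]))
        baseline = ti_report(mic_panel, hc10)
        assert ti_report(mixed, hc10).equals(baseline)

    def test_missing_hc10_is_an_error(self, mic_panel):
        with pytest.raises(AssayError, match="no HC10"):
            ti_report(mic_panel, {"W5K/A9W": 30.0})

    def test_writer_rounds_to_one_decimal(self, mic_panel, hc10_table, tmp_path):
        hc10 = dict(zip(hc10_table["peptide"], hc10_table["hc10_ug_ml"]))
        report = ti_report(mic_panel, hc10)
        out = tmp_path / "ti.csv"
        write_ti_report(report, out)
        back = pd.read_csv(out)
        assert back.loc[back["peptide"] == "W5K/A9W", "GM_all"].iloc[0] == 4.1


class TestPanelAndComparisons:
    def test_wide_round_trip_preserves_censoring(self, mic_panel, tmp_path):
        path = tmp_path / "panel.csv"
        mic_panel.to_long_csv(path)
        back = MICPanel.from_long_csv(path)
        assert back.data.equals(mic_panel.data)

    def test_duplicate_triples_rejected(self, mic_panel):
        dup = pd.concat([mic_panel.data, mic_panel.data.iloc[[0]]], ignore_index=True)
        with pytest.raises(AssayError, match="duplicate"):
            MICPanel(dup)

    def test_unknown_gram_label_rejected(self, mic_panel):
        bad = mic_panel.data.copy()
        bad.loc[0, "gram"] = "unknown"
        with pytest.raises(AssayError, match="gram"):
            MICPanel(bad)

    def test_condition_validation(self):
        with pytest.raises(AssayError):
            Condition(NaCl_mM=-1)
        with pytest.raises(AssayError):
            Condition(pH=15)

    def test_compare_to_parent_cells(self, mic_panel):
        cmp = compare_to_parent(mic_panel, "W5K/A9W").set_index(["peptide", "strain"])
        cell = cmp.loc[("W5K01", "E. coli ATCC 25922")]
        assert cell["ratio"] == pytest.approx(12.5 / 3.13)
        assert cell["dilution_steps"] == pytest.approx(2.0, abs=0.01)
        assert not cell["at_or_below_parent"]
        equal = cmp.loc[("W5K12", "E. coli ATCC 25922")]
        assert equal["ratio"] == pytest.approx(1.0)
        assert equal["at_or_below_parent"]

    def test_censored_member_never_qualifies(self, mic_panel):
        cmp = compare_to_parent(mic_panel, "W5K/A9W").set_index(["peptide", "strain"])
        cell = cmp.loc[("W5K08", "A. baumannii 14B0091")]
        assert cell["ratio_bound"] == "lower"
        assert cell["ratio"] > 4
        assert not cell["at_or_below_parent"]

    def test_bold_mask_matches_published_count(self, mic_panel):
        # the published baseline table bolds exactly the at-or-below-parent cells
        cmp = compare_to_parent(mic_panel, "W5K/A9W")
        by_pep = cmp.groupby("peptide")["at_or_below_parent"].sum()
        assert by_pep["W5K11"] == 9  # at/below parent on all strains but E. coli
        assert by_pep["W5K03"] == 0

    def test_heatmap_export_shape_and_censored_cells(self, mic_panel, tmp_path):
        path = tmp_path / "heatmap.tsv"
        export_heatmap_matrix(mic_panel, path)
        wide = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        assert wide.shape == (10, 13)
        assert wide.loc["A. baumannii 14B0091", "W5K08"] == ">50"
        assert wide.loc["E. coli ATCC 25922", "W5K/A9W"] == "3.13"
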