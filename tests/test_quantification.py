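"""XICs, peak integration, PRM, normalizations, isotope dilution."""

import numpy as np
import pandas as pd
import pytest

from epilipid.identification import CentroidSpectrum
from epilipid.quantification import (
    CalibrationModel,
    Chromatogram,
    EmptyWindow,
    InternalStandardMap,
    Transition,
    ZeroStandardArea,
    back_calculate,
    coq_redox_metrics,
    external_calibration,
    extract_xic,
    integrate_peak,
    isotope_dilution_amount,
    normalize_to_internal_standard,
    normalize_to_protein,
    prm_quantify,
    quinone_transitions,
)
from epilipid.synthetic import SimulationConfig, simulate_prm_run


def _scan(rt, peaks, prec=500.0):
    return CentroidSpectrum(precursor_mz=prec, rt=rt, polarity="positive",
                            peaks=tuple(peaks), precursor_intensity=1e6)


class TestExtractXic:
    def test_gaussian_profile_reproduced(self):
        rts = np.arange(9.0, 11.0, 0.02)
        target = 500.0
        profile = 1e5 * np.exp(-0.5 * ((rts - 10.0) / 0.1) ** 2)
        run = [_scan(rt, [(target, p)]) for rt, p in zip(rts, profile)]
        chrom = extract_xic(run, target, 5.0)
        assert np.allclose(chrom.intensity, profile)

    def test_far_target_gives_zero_trace(self):
        run = [_scan(1.0, [(500.0, 1e5)]), _scan(2.0, [(500.0, 1e5)])]
        chrom = extract_xic(run, 500.0 * (1 + 100e-6), 5.0)
        assert (chrom.intensity == 0).all()

    def test_only_in_tolerance_peak_contributes(self):
        inside = 500.0 * (1 + 2e-6)
        outside = 500.0 * (1 + 50e-6)
        run = [_scan(1.0, [(inside, 300.0), (outside, 700.0)])]
        chrom = extract_xic(run, 500.0, 5.0)
        assert chrom.intensity[0] == pytest.approx(300.0)


class TestIntegratePeak:
    def test_unit_triangle(self):
        rt = np.array([0.0, 0.5, 1.0])
        chrom = Chromatogram(rt, np.array([0.0, 1.0, 0.0]), 500.0, 5.0)
        assert integrate_peak(chrom, (0.0, 1.0)) == pytest.approx(0.5)

    def test_all_zero_trace(self):
        chrom = Chromatogram(np.linspace(0, 1, 11), np.zeros(11), 500.0, 5.0)
        assert integrate_peak(chrom, (0.0, 1.0)) == 0.0

    def test_gaussian_recovered_within_1pc(self):
        area, sigma = 5e5, 0.1
        rt = np.arange(9.0, 11.0 + 1e-9, 0.02)
        y = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((rt - 10.0) / sigma) ** 2)
        chrom = Chromatogram(rt, y, 500.0, 5.0)
        got = integrate_peak(chrom, (9.5, 10.5))
        assert got == pytest.approx(area, rel=0.01)

    def test_bad_window(self):
        chrom = Chromatogram(np.linspace(0, 1, 11), np.zeros(11), 500.0, 5.0)
        with pytest.raises(EmptyWindow):
            integrate_peak(chrom, (0.9, 0.2))


class TestPrmQuantify:
    def _transitions(self):
        return [
            Transition("a", 880.72, 197.08, expected_rt=10.0),
            Transition("b", 810.60, 315.19, expected_rt=14.0),
        ]

    def test_noiseless_recovery_within_1pc(self):
        trans = self._transitions()
        amounts = {"a": 2.0, "b": 0.7}
        run, truth = simulate_prm_run(trans, amounts, SimulationConfig(seed=0))
        table = prm_quantify(run, trans)
        for name in amounts:
            assert table.loc[name, "area"] == pytest.approx(truth[name], rel=0.01)

    def test_unmatched_transition_flagged_not_fatal(self):
        trans = self._transitions()
        run, _ = simulate_prm_run(trans[:1], {"a": 1.0}, SimulationConfig(seed=0))
        table = prm_quantify(run, trans)
        assert table.loc["b", "flag"] == "no_matching_isolation"
        assert np.isnan(table.loc["b", "area"])
        assert table.loc["a", "matched_scans"] > 0

    def test_linearity_in_intensity(self):
        trans = self._transitions()[:1]
        run, _ = simulate_prm_run(trans, {"a": 1.0}, SimulationConfig(seed=0))
        doubled = [
            CentroidSpectrum(
                precursor_mz=s.precursor_mz, rt=s.rt, polarity=s.polarity,
                peaks=tuple((m, 2 * i) for m, i in s.peaks),
                precursor_intensity=s.precursor_intensity,
                ms_level=s.ms_level, isolation_width=s.isolation_width)
            for s in run
        ]
        a1 = prm_quantify(run, trans).loc["a", "area"]
        a2 = prm_quantify(doubled, trans).loc["a", "area"]
        assert a2 == pytest.approx(2 * a1, rel=1e-9)


class TestNormalizations:
    def test_internal_standard_ratio(self):
        areas = pd.DataFrame({"s1": [2e6, 1e6]}, index=["TG 52:2", "IS_TG"])
        is_map = InternalStandardMap({"TG": ("IS_TG", 1.0)})
        out = normalize_to_internal_standard(areas, {"TG 52:2": "TG", "IS_TG": "TG"}, is_map)
        assert out.loc["TG 52:2", "s1"] == pytest.approx(2.0)

    def test_global_rescaling_cancels(self):
        areas = pd.DataFrame({"s1": [3e6, 1.5e6]}, index=["TG 52:2", "IS_TG"])
        is_map = InternalStandardMap({"TG": ("IS_TG", 1.0)})
        classes = {"TG 52:2": "TG", "IS_TG": "TG"}
        a = normalize_to_internal_standard(areas, classes, is_map)
        b = normalize_to_internal_standard(areas * 7.5, classes, is_map)
        pd.testing.assert_frame_equal(a, b)

    def test_unmapped_class_is_error(self):
        areas = pd.DataFrame({"s1": [1.0]}, index=["CE 18:1"])
        is_map = InternalStandardMap({"TG": ("IS_TG", 1.0)})
        with pytest.raises(KeyError):
            normalize_to_internal_standard(areas, {"CE 18:1": "CE"}, is_map)

    def test_protein_normalization(self):
        table = pd.DataFrame({"s1": [4.0], "s2": [9.0]}, index=["x"])
        out = normalize_to_protein(table, pd.Series({"s1": 2.0, "s2": 3.0}))
        assert out.loc["x", "s1"] == 2.0 and out.loc["x", "s2"] == 3.0

    def test_zero_protein_is_error(self):
        table = pd.DataFrame({"s1": [4.0]}, index=["x"])
        with pytest.raises(ValueError):
            normalize_to_protein(table, pd.Series({"s1": 0.0}))


class TestIsotopeDilution:
    def test_equal_areas_return_spike_amount(self):
        assert isotope_dilution_amount(1e6, 1e6, 2.5) == pytest.approx(2.5)

    def test_zero_analyte(self):
        assert isotope_dilution_amount(0.0, 1e6, 2.5) == 0.0

    def test_zero_standard_is_error(self):
        with pytest.raises(ZeroStandardArea):
            isotope_dilution_amount(1e6, 0.0, 2.5)

    def test_spiked_run_recovery(self):
        # analyte and labelled standard elute as Gaussian PRM peaks;
        # isotope dilution recovers the planted amount
        qt = quinone_transitions()
        trans = [
            Transition("CoQ10", float(qt.loc[qt["name"] == "CoQ10", "precursor_mz"].iloc[0]),
                       float(qt.loc[qt["name"] == "CoQ10", "product_mz"].iloc[0]),
                       expected_rt=22.4),
            Transition("CoQ10-d6", float(qt.loc[qt["name"] == "CoQ10-d6", "precursor_mz"].iloc[0]),
                       float(qt.loc[qt["name"] == "CoQ10-d6", "product_mz"].iloc[0]),
                       expected_rt=22.4),
        ]
        run, _ = simulate_prm_run(trans, {"CoQ10": 1.7, "CoQ10-d6": 2.5},
                                  SimulationConfig(seed=11))
        areas = prm_quantify(run, trans)
        amount = isotope_dilution_amount(
            areas.loc["CoQ10", "area"], areas.loc["CoQ10-d6", "area"], 2.5)
        assert amount == pytest.approx(1.7, rel=0.01)


class TestRedoxMetrics:
    def test_printed_style_summary(self):
        m = coq_redox_metrics(0.4, 0.6, 2000.0)
        assert m.fraction_reduced == pytest.approx(0.6)
        assert m.coq_per_neutral_lipid == pytest.approx(1 / 2000)

    def test_zero_reduced(self):
        assert coq_redox_metrics(1.0, 0.0, 100.0).fraction_reduced == 0.0

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            coq_redox_metrics(0.0, 0.0, 100.0)


class TestExternalCalibration:
    def test_exact_line(self):
        model = external_calibration([(0, 0), (1, 2), (2, 4), (5, 10)])
        conc, extrapolated = back_calculate(model, 10.0)
        assert conc == pytest.approx(5.0)
        assert not extrapolated
        assert model.r_squared == pytest.approx(1.0)

    def test_single_level_is_error(self):
        with pytest.raises(ValueError):
            external_calibration([(1.0, 2.0), (1.0, 2.1)])

    def test_extrapolation_flagged(self):
        model = external_calibration([(1, 2), (2, 4)])
        _, extrapolated = back_calculate(model, 100.0)
        assert extrapolated

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(5)
        conc = np.array([0.5, 1, 2, 4, 8, 16])
        resp = 3.0 * conc + rng.normal(0, 0.05, size=conc.size)
        model = external_calibration(list(zip(conc, resp)))
        assert model.slope == pytest.approx(3.0, rel=0.05)


class TestQuinoneTransitionTable:
    def test_mz_recomputed_from_formulas(self):
        qt = quinone_transitions().set_index("name")
        assert round(qt.loc["CoQ10", "product_mz"], 4) == 197.0808
        assert round(qt.loc["CoQ10-d6", "product_mz"], 5) == 203.11904
        assert round(qt.loc["alpha-tocopherol", "product_mz"], 3) == 165.091
        assert round(qt.loc["vitamin K1", "product_mz"], 4) == 187.0754
        assert round(qt.loc["CoQ10", "precursor_mz"], 1) == 880.7
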