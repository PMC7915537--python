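"""Quantitation chain: EIC extraction, integration, calibration, ratios."""

import numpy as np
import pytest

from meiboquant.chromatogram_io import ScanSet
from meiboquant.eic_quant import (
    ChromPeak,
    EICTrace,
    ResponseFactors,
    calibrate_response,
    chain_profile,
    chl_ce_ratio,
    class_balance,
    compare_groups,
    detect_and_integrate,
    extract_eic,
    quantify_sample,
)
from meiboquant.lipid_registry import (
    CE_LABEL_GROUPS,
    IonChannel,
    STEROL_FRAGMENT_MZ,
    build_assignment_table,
    ce_id,
)
from meiboquant.synthetic_data import (
    CompositionSpec,
    SimConfig,
    SpeciesSignal,
    make_preset,
    simulate_chromatogram,
)


def _gaussian_trace(centers, heights, sigma=0.1, step=0.01, span=10.0, baseline=0.0):
    rt = np.arange(0.0, span, step)
    y = np.full_like(rt, baseline)
    for c, h in zip(centers, heights):
        y += h * np.exp(-((rt - c) ** 2) / (2 * sigma**2))
    ch = IonChannel("test", "M+H", 500.0)
    return EICTrace(ch, rt, y)


class TestExtraction:
    def test_window_edge_centroid_included(self):
        ch = IonChannel("x", "M+H", 500.0, window_mda=50.0)
        scans = ScanSet(np.array([0.0]), [np.array([500.025])], [np.array([7.0])])
        trace = extract_eic(scans, ch)
        assert trace.intensity[0] == 7.0

    def test_centroid_just_outside_window_excluded(self):
        ch = IonChannel("x", "M+H", 500.0, window_mda=50.0)
        scans = ScanSet(np.array([0.0]), [np.array([500.0251])], [np.array([7.0])])
        assert extract_eic(scans, ch).intensity[0] == 0.0

    def test_absent_channel_gives_zero_trace(self, wt_scans_noiseless):
        ch = IonChannel("nothing", "M+H", 1500.0)
        trace = extract_eic(wt_scans_noiseless, ch)
        assert np.all(trace.intensity == 0.0)

    def test_window_monotonicity(self, wt_scans_noisy, registry):
        base = registry.sterol_channel()
        prev = None
        for width in (10.0, 25.0, 50.0, 100.0):
            ch = IonChannel(base.species_id, base.adduct, base.target_mz, width)
            total = extract_eic(wt_scans_noisy, ch).intensity
            if prev is not None:
                assert np.all(total >= prev - 1e-9)
            prev = total

    def test_empty_scanset_rejected(self):
        ch = IonChannel("x", "M+H", 500.0)
        with pytest.raises(ValueError):
            extract_eic(ScanSet(np.array([]), [], []), ch)


class TestIntegration:
    def test_single_gaussian_area_matches_analytic(self):
        h, s = 1000.0, 0.1
        trace = _gaussian_trace([5.0], [h], sigma=s)
        peaks = detect_and_integrate(trace)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(h * s * np.sqrt(2 * np.pi), rel=0.01)
        assert peaks[0].rt_apex == pytest.approx(5.0, abs=0.02)

    def test_two_separated_gaussians(self):
        h1, h2, s = 800.0, 300.0, 0.1
        trace = _gaussian_trace([3.0, 7.0], [h1, h2], sigma=s)
        peaks = sorted(detect_and_integrate(trace), key=lambda p: p.rt_apex)
        assert len(peaks) == 2
        for p, h in zip(peaks, (h1, h2)):
            assert p.area == pytest.approx(h * s * np.sqrt(2 * np.pi), rel=0.01)

    def test_flat_trace_has_no_peaks(self):
        trace = _gaussian_trace([], [], baseline=40.0)
        assert detect_and_integrate(trace) == []

    def test_intensity_scaling_scales_areas(self):
        trace = _gaussian_trace([3.0, 7.0], [500.0, 900.0])
        scaled = EICTrace(trace.channel, trace.rt, trace.intensity * 3.0)
        a1 = sorted(p.area for p in detect_and_integrate(trace))
        a2 = sorted(p.area for p in detect_and_integrate(scaled))
        assert np.allclose(a2, 3.0 * np.asarray(a1), rtol=1e-9)

    def test_baseline_offset_does_not_change_area(self):
        t1 = _gaussian_trace([5.0], [1000.0], baseline=0.0)
        t2 = _gaussian_trace([5.0], [1000.0], baseline=200.0)
        a1 = detect_and_integrate(t1)[0].area
        a2 = detect_and_integrate(t2)[0].area
        assert a2 == pytest.approx(a1, rel=1e-3)


class TestCalibration:
    def test_noiseless_standard_recovers_embedded_factors(self, factors_noiseless):
        assert factors_noiseless.factors["Chl"] == 1.0
        assert factors_noiseless.factors["CE 18:1"] == pytest.approx(2.21, abs=1e-6)
        assert factors_noiseless.factors["CE 24:1"] == pytest.approx(2.41, abs=1e-6)
        assert factors_noiseless.factors["TAG 54:3"] == pytest.approx(1.0, abs=1e-6)
        assert factors_noiseless.factors["WE 42:1"] == pytest.approx(1.0, abs=1e-6)

    def test_concentration_invariance(self, registry, noiseless_cfg, factors_noiseless):
        half = make_preset("standard_mix").scaled(0.5)
        scans = simulate_chromatogram(half, noiseless_cfg, registry)
        factors = calibrate_response(scans, registry)
        for sid, v in factors_noiseless.factors.items():
            assert factors.factors[sid] == pytest.approx(v, rel=1e-6)

    def test_equal_responses_give_unit_factors(self, registry, noiseless_cfg):
        comp = CompositionSpec({
            "Chl": SpeciesSignal(1.0, response=1.0, fragment_yield=1.0),
            "CE 18:1": SpeciesSignal(1.0, response=1.0, fragment_yield=1.0),
            "CE 24:1": SpeciesSignal(1.0, response=1.0, fragment_yield=1.0),
            "TAG 54:3": SpeciesSignal(1.0),
            "WE 42:1": SpeciesSignal(1.0),
        })
        scans = simulate_chromatogram(comp, noiseless_cfg, registry)
        factors = calibrate_response(scans, registry)
        for v in factors.factors.values():
            assert v == pytest.approx(1.0, rel=1e-6)

    def test_missing_cholesterol_is_an_error(self, registry, noiseless_cfg):
        comp = CompositionSpec({"WE 42:1": SpeciesSignal(1.0)})
        scans = simulate_chromatogram(comp, noiseless_cfg, registry)
        with pytest.raises(ValueError, match="cholesterol"):
            calibrate_response(scans, registry)

    def test_ce_factor_interpolates_between_anchors(self, factors_noiseless):
        f = factors_noiseless
        assert f.ce_factor(16.0) == pytest.approx(2.21, abs=1e-6)
        assert f.ce_factor(22.0) == pytest.approx(2.41, abs=1e-6)
        assert f.ce_factor(19.0) == pytest.approx(2.31, abs=1e-4)
        assert f.ce_factor(10.0) == pytest.approx(2.21, abs=1e-6)  # clamped
        assert f.ce_factor(30.0) == pytest.approx(2.41, abs=1e-6)  # clamped

    def test_chl_must_be_normalized(self):
        with pytest.raises(ValueError):
            ResponseFactors({"Chl": 2.0})

    def test_json_round_trip(self, factors_noiseless, tmp_path):
        path = tmp_path / "factors.json"
        factors_noiseless.to_json(path)
        back = ResponseFactors.from_json(path)
        assert back.factors == pytest.approx(factors_noiseless.factors)
        assert back.ce_anchors == factors_noiseless.ce_anchors


class TestChlCeRatio:
    def test_noiseless_round_trip_to_1e6(self, wt_scans_noiseless, registry,
                                         factors_noiseless):
        peaks = detect_and_integrate(extract_eic(wt_scans_noiseless,
                                                 registry.sterol_channel()))
        ratio = chl_ce_ratio(peaks, factors_noiseless, registry)
        assert ratio == pytest.approx(7.0, rel=1e-6)

    def test_chl_only_gives_100_percent(self, registry, noiseless_cfg,
                                        factors_noiseless):
        comp = CompositionSpec({"Chl": SpeciesSignal(5.0, 1.0, 1.0)})
        scans = simulate_chromatogram(comp, noiseless_cfg, registry)
        peaks = detect_and_integrate(extract_eic(scans, registry.sterol_channel()))
        assert chl_ce_ratio(peaks, factors_noiseless, registry) == 100.0

    def test_no_sterol_signal_is_an_error(self, registry, factors_noiseless):
        assert_error = pytest.raises(ValueError, match="sterol")
        with assert_error:
            chl_ce_ratio([], factors_noiseless, registry)

    def test_sub_lloq_ce_contributes_zero(self, registry, factors_noiseless,
                                          noisy_cfg):
        # trace CE far below the noise floor must not move the ratio
        comp = CompositionSpec({
            "Chl": SpeciesSignal(10.0, 1.0, 1.0),
            "CE 18:1": SpeciesSignal(1e-7, 2.21, 1.0),
        })
        scans = simulate_chromatogram(comp, noisy_cfg, registry)
        peaks = detect_and_integrate(extract_eic(scans, registry.sterol_channel()))
        assert chl_ce_ratio(peaks, factors_noiseless, registry,
                            lloq_snr=10.0) == 100.0


class TestProfilesAndBalance:
    def test_single_ce_species_is_100_percent(self, registry, noiseless_cfg):
        table = build_assignment_table(registry)
        comp = CompositionSpec({ce_id(24, 1): SpeciesSignal(3.0, 1.0, 0.5)})
        scans = simulate_chromatogram(comp, noiseless_cfg, registry)
        peaks = detect_and_integrate(extract_eic(
            scans, registry.channel(ce_id(24, 1), "M+H")))
        profile = chain_profile(peaks, "adduct", table, registry)
        assert profile == {"C22:0/C24:1-CE": pytest.approx(100.0)}

    def test_wt_fragment_profile_recovers_generative_fractions(
            self, wt_scans_noiseless, registry, factors_noiseless):
        # expected profile built from the preset amounts alone: species
        # sharing an equivalent chain length co-elute into one fragment
        # peak, which the assignment table maps to a reporting label
        from meiboquant.lipid_registry import STEROL_FRAGMENT_MZ, assign_peak

        table = build_assignment_table(registry)
        comp = make_preset("wild_type")
        truth: dict[str, float] = {}
        for sid, sig in comp.species.items():
            sp = registry.get(sid)
            if sp.lipid_class != "CE":
                continue
            label = assign_peak(STEROL_FRAGMENT_MZ, sp.nominal_rt_min, table)
            truth[label] = truth.get(label, 0.0) + sig.amount
        total = sum(truth.values())
        truth = {k: 100.0 * v / total for k, v in truth.items()}

        peaks = detect_and_integrate(extract_eic(wt_scans_noiseless,
                                                 registry.sterol_channel()))
        profile = chain_profile([p for p in peaks if p.rt_apex > 10.0],
                                "fragment", table, registry,
                                factors=factors_noiseless)
        assert set(profile) == set(truth)
        for label, expected in truth.items():
            assert profile[label] == pytest.approx(expected, rel=0.02), label

    def test_profile_sums_to_100(self, wt_scans_noisy, registry, factors_noisy):
        table = build_assignment_table(registry)
        peaks = detect_and_integrate(extract_eic(wt_scans_noisy,
                                                 registry.sterol_channel()))
        profile = chain_profile(peaks, "fragment", table, registry, factors_noisy)
        assert sum(profile.values()) == pytest.approx(100.0, abs=1e-9)

    def test_class_balance_normalizes_to_100(self):
        balance = class_balance({"Chl": 2.0, "CE": 31.0, "WE": 58.0, "TAG": 9.0})
        assert sum(balance.values()) == pytest.approx(100.0, abs=1e-9)

    def test_only_we_gives_100_percent_we(self):
        balance = class_balance({"Chl": 0.0, "CE": 0.0, "WE": 5.0, "TAG": 0.0})
        assert balance["WE"] == pytest.approx(100.0)

    def test_all_zero_classes_rejected(self):
        with pytest.raises(ValueError):
            class_balance({"Chl": 0.0, "CE": 0.0})


class TestQuantifySample:
    def test_wild_type_report(self, wt_scans_noisy, registry, factors_noisy):
        report = quantify_sample(wt_scans_noisy, registry, factors_noisy,
                                 genotype="wild_type")
        assert report.chl_ce_ratio_percent == pytest.approx(7.0, abs=1.0)
        balance = report.class_balance_percent
        assert sum(balance.values()) == pytest.approx(100.0, abs=1e-9)
        # generative class split: Chl 7/3, CE 31, WE 58, TAG 26/3
        assert balance["WE"] == pytest.approx(58.0, abs=2.0)
        assert balance["CE"] == pytest.approx(31.0, abs=2.0)
        assert sum(report.chain_profile_adduct.values()) == pytest.approx(100.0)

    def test_null_report(self, null_scans_noisy, registry, factors_noisy):
        report = quantify_sample(null_scans_noisy, registry, factors_noisy,
                                 genotype="soat1_null")
        assert report.chl_ce_ratio_percent >= 99.0
        assert report.class_balance_percent["Chl"] >= 30.0


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        _, pairs = compare_groups({"a": vals, "b": list(vals)})
        assert pairs.loc[0, "p_value"] == pytest.approx(1.0)
        assert pairs.loc[0, "t"] == pytest.approx(0.0)

    def test_well_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 7), "b": rng.normal(5, 1, 7)}
        summary, pairs = compare_groups(groups)
        assert pairs.loc[0, "p_value"] < 0.001
        assert summary.loc["a", "mean"] == pytest.approx(np.mean(groups["a"]))
        assert summary.loc["b", "n"] == 7

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
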