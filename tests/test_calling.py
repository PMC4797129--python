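"""Bin calibration, allele assignment, quality rules, and profile assembly."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

import strexpert as sx
from strexpert.calling import (AlleleCall, BinSet, LadderCalibrationError,
                               apply_rules, assemble_profile, assign_alleles,
                               calibrate_bins, compute_phr)
from strexpert.sizing import SizedPeak


def _sized(channel, size, height, fwhm_bases=0.4):
    return SizedPeak(channel=channel, apex_scan=0.0, height=height,
                     area=height, fwhm_scans=3.0, size=size,
                     fwhm_bases=fwhm_bases)


def _call(locus, designation, size, height, flags=()):
    return AlleleCall(locus=locus, designation=designation, size=size,
                      height=height, flags=set(flags))


class TestCalibrateBins:
    def test_noise_free_ladder_yields_210_bins_at_nominal(self, panel,
                                                          quiet_params):
        ladder = sx.simulate_ladder_run(panel, quiet_params)
        sized, _, _, _ = sx.condition_and_size(ladder, panel)
        bins = calibrate_bins(sized, panel)
        n = sum(len(v) for v in bins.bins.values())
        assert n == 210
        for locus in panel.loci:
            for allele, nominal in locus.ladder_alleles:
                center, half = bins.bins[locus.name][allele]
                assert center == pytest.approx(nominal, abs=0.05)
                assert half == panel.bin_half_width

    def test_missing_fragment_fails_naming_it(self, panel, quiet_params):
        ladder = sx.simulate_ladder_run(panel, quiet_params)
        sized, _, _, _ = sx.condition_and_size(ladder, panel)
        th01 = panel.locus("TH01")
        gone = th01.size_of("9.3")
        pruned = [p for p in sized
                  if not (p.channel == th01.dye.detector_index
                          and abs(p.size - gone) < 0.5)]
        with pytest.raises(LadderCalibrationError, match="TH01 allele 9.3"):
            calibrate_bins(pruned, panel)


@pytest.fixture(scope="module")
def nominal_bins(panel):
    """Bins centered exactly on nominal sizes (no sizing error)."""
    return BinSet(bins={
        l.name: {a: (s, panel.bin_half_width) for a, s in l.ladder_alleles}
        for l in panel.loci})


class TestAssignAlleles:
    def test_peak_at_bin_center_gets_designation(self, panel, nominal_bins):
        th01 = panel.locus("TH01")
        peaks = [_sized(th01.dye.detector_index, th01.size_of("9.3"), 1500.0)]
        [call] = assign_alleles(peaks, nominal_bins, panel)
        assert (call.locus, call.designation) == ("TH01", "9.3")
        assert not call.flags

    def test_peak_between_bins_is_off_ladder(self, panel, nominal_bins):
        th01 = panel.locus("TH01")
        peaks = [_sized(th01.dye.detector_index, th01.size_of("8") + 1.7, 1500.0)]
        [call] = assign_alleles(peaks, nominal_bins, panel)
        assert call.designation == "OL"
        assert "off_ladder" in call.flags

    def test_peak_outside_every_locus_span_not_called(self, panel, nominal_bins):
        # 150 bases on FL sits between D3S1358 (<=143) and TH01 (>=156)
        assert assign_alleles([_sized(0, 150.0, 1500.0)], nominal_bins,
                              panel) == []

    def test_noise_free_end_to_end_matches_truth(self, panel, quiet_params,
                                                 quiet_bins):
        g = sx.sample_genotype(panel, seed=17)
        trace = sx.simulate_sample(g, panel, replace(quiet_params, seed=4))
        result = sx.analyze_sample(trace, quiet_bins, panel)
        for locus in panel.loci:
            called = sorted(c.designation
                            for c in result.locus_results[locus.name].passing_calls)
            assert called == sorted(set(g.calls[locus.name]))


class TestComputePHR:
    @pytest.mark.parametrize("h1,h2,expect", [(700, 1000, 0.7),
                                              (1000, 1000, 1.0),
                                              (500, 1000, 0.5)])
    def test_ratio(self, h1, h2, expect):
        calls = [_call("vWA", "14", 140.0, h1), _call("vWA", "16", 148.0, h2)]
        assert compute_phr(calls) == pytest.approx(expect)

    @pytest.mark.parametrize("n", [0, 1, 3])
    def test_not_applicable_outside_pairs(self, n):
        calls = [_call("vWA", str(10 + i), 140.0 + 4 * i, 800.0)
                 for i in range(n)]
        assert compute_phr(calls) is None

    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, h1, h2, k):
        a = [_call("vWA", "14", 140.0, h1), _call("vWA", "16", 148.0, h2)]
        b = [_call("vWA", "14", 140.0, h1 * k), _call("vWA", "16", 148.0, h2 * k)]
        assert compute_phr(b) == pytest.approx(compute_phr(a), rel=1e-9)


class TestApplyRules:
    def test_stutter_ratio_below_threshold_filtered(self, panel):
        vwa = panel.locus("vWA")  # stutter_threshold 0.15
        calls = [_call("vWA", "16", vwa.size_of("16"), 1000.0),
                 _call("vWA", "15", vwa.size_of("16") - 4.0, 80.0)]
        res = apply_rules(calls, panel)["vWA"]
        weak = next(c for c in res.calls if c.designation == "15")
        assert "stutter_filtered" in weak.flags
        assert res.status == "called"

    def test_stutter_position_retained_when_ratio_high(self, panel):
        vwa = panel.locus("vWA")
        calls = [_call("vWA", "16", vwa.size_of("16"), 1000.0),
                 _call("vWA", "15", vwa.size_of("16") - 4.0, 200.0)]
        res = apply_rules(calls, panel)["vWA"]
        # survives the stutter rule (0.20 > 0.15) ...
        assert all("stutter_filtered" not in c.flags for c in res.calls)
        # ... and the PHR rule then flags the weaker call (0.2 < threshold)
        weak = next(c for c in res.calls if c.designation == "15")
        assert "phr_imbalance" in weak.flags

    def test_below_threshold_flagged(self, panel):
        calls = [_call("vWA", "16", 147.0, panel.analytical_threshold - 1)]
        res = apply_rules(calls, panel)["vWA"]
        assert "below_threshold" in res.calls[0].flags
        assert res.status == "flagged_only"

    def test_phr_imbalance_flags_weaker_call(self, panel):
        vwa = panel.locus("vWA")
        calls = [_call("vWA", "14", vwa.size_of("14"), 1000.0),
                 _call("vWA", "18", vwa.size_of("18"), 300.0)]
        res = apply_rules(calls, panel)["vWA"]
        weak = next(c for c in res.calls if c.designation == "18")
        strong = next(c for c in res.calls if c.designation == "14")
        assert "phr_imbalance" in weak.flags and not strong.flags
        assert res.phr is None  # no surviving heterozygous pair

    def test_more_than_two_survivors_all_flagged_for_review(self, panel):
        vwa = panel.locus("vWA")
        calls = [_call("vWA", d, vwa.size_of(d), 900.0)
                 for d in ("12", "15", "18")]
        res = apply_rules(calls, panel)["vWA"]
        assert all("phr_imbalance" in c.flags for c in res.calls)
        assert res.status == "flagged_only"

    def test_empty_locus_is_dropout(self, panel):
        res = apply_rules([], panel)
        assert all(r.status == "dropout" for r in res.values())


class TestAssembleProfile:
    def _results(self, panel, status_by_locus):
        from strexpert.calling import LocusResult
        out = {}
        for locus in panel.loci:
            status = status_by_locus.get(locus.name, "called")
            calls = ([_call(locus.name, locus.designations[0],
                            locus.ladder_alleles[0][1], 900.0)]
                     if status == "called" else [])
            out[locus.name] = LocusResult(locus.name, calls, status=status)
        return out

    def test_all_called_is_full(self, panel):
        prof = assemble_profile(self._results(panel, {}), panel)
        assert prof.category == "full"
        assert prof.codis_locus_count == 13

    def test_none_called_is_fail(self, panel):
        status = {l.name: "dropout" for l in panel.loci}
        prof = assemble_profile(self._results(panel, status), panel)
        assert prof.category == "fail"
        assert prof.codis_locus_count == 0

    def test_some_called_is_partial_with_searchability(self, panel):
        dropped = [l.name for l in panel.loci if l.is_codis][:5]
        prof = assemble_profile(
            self._results(panel, {n: "dropout" for n in dropped}), panel)
        assert prof.category == "partial"
        assert prof.codis_locus_count == 8
        assert not prof.codis_searchable

    def test_missing_locus_rejected(self, panel):
        results = self._results(panel, {})
        results.pop(panel.loci[0].name)
        with pytest.raises(ValueError, match="missing locus"):
            assemble_profile(results, panel)


class TestLowTemplateBehaviour:
    def test_very_low_mass_gives_partial_with_locus_dropouts(self, panel,
                                                             default_bins):
        """A low-template sample loses loci to dropout (the small-volume
        phenomenology: sparse partial profiles with few CODIS loci)."""
        params = sx.SimulationParams(template_mass=50.0, seed=12345)
        g = sx.sample_genotype(panel, seed=99)
        trace = sx.simulate_sample(g, panel, params)
        result = sx.analyze_sample(trace, default_bins, panel)
        statuses = [r.status for r in result.locus_results.values()]
        assert result.profile.category == "partial"
        assert statuses.count("dropout") >= 1
        assert result.profile.codis_locus_count < 10
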