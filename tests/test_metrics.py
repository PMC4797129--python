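"""Validation metrics: precision, resolution, PHR, concordance, tabulation,
sensitivity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import strexpert as sx
from strexpert import metrics
from strexpert.metrics import (ConcordanceTally, concordance, phr_report,
                               precision_report, resolution,
                               sensitivity_curve, tabulate_status_grid)
from strexpert.sizing import SizedPeak

SQRT_8LN2 = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _peak(size, sigma_bases, height=1000.0):
    return SizedPeak(channel=0, apex_scan=0.0, height=height, area=height,
                     fwhm_scans=1.0, size=size,
                     fwhm_bases=sigma_bases * SQRT_8LN2)


class TestPrecision:
    def test_identical_runs_zero_sd_pass(self):
        run = {("A", "8"): 120.0, ("A", "9"): 124.0}
        rep = precision_report([run, dict(run), dict(run)])
        assert rep.max_sd == 0.0 and rep.passed

    def test_sample_sd_closed_form(self):
        runs = [{("A", "8"): s} for s in (99.9, 100.0, 100.1)]
        rep = precision_report(runs)
        assert rep.sd_by_fragment[("A", "8")] == pytest.approx(0.1)

    def test_mismatched_fragment_sets_rejected(self):
        with pytest.raises(ValueError, match="fragment set"):
            precision_report([{("A", "8"): 120.0}, {("A", "9"): 124.0}])

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            precision_report([{("A", "8"): 120.0}])


class TestResolution:
    def test_single_peak_quarter_base_sigma_gives_r_one(self):
        # sigma 0.25 bases -> baseline width 4*sigma = 1.0 base -> R = 1.0
        assert resolution(_peak(200.0, 0.25)) == pytest.approx(1.0, rel=1e-9)

    def test_single_peak_sigma_125_gives_r_point_two(self):
        assert resolution(_peak(400.0, 1.25)) == pytest.approx(0.2, rel=1e-9)

    def test_coincident_pair_gives_zero(self):
        a, b = _peak(200.0, 0.25), _peak(200.0, 0.25)
        assert resolution(a, b) == 0.0

    def test_pair_one_base_apart_matches_single_peak_convention(self):
        a, b = _peak(200.0, 0.25), _peak(201.0, 0.25)
        assert resolution(a, b) == pytest.approx(resolution(a), rel=1e-9)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            resolution(_peak(200.0, 0.0))

    def test_r_grows_without_bound_as_width_shrinks(self):
        rs = [resolution(_peak(200.0, s)) for s in (0.5, 0.05, 0.005)]
        assert rs == sorted(rs) and rs[-1] > 40


class TestPHRReport:
    def _profile(self, panel, phr_by_locus):
        from strexpert.calling import LocusResult, SampleProfile
        results = {}
        for locus in panel.loci:
            phr = phr_by_locus.get(locus.name)
            results[locus.name] = LocusResult(locus.name, [], phr=phr,
                                              status="called")
        return SampleProfile("s", results, "full", 13)

    def test_single_het_locus(self, panel):
        df = phr_report([self._profile(panel, {"vWA": 0.7})])
        assert len(df) == 1
        assert df.iloc[0]["locus"] == "vWA"
        assert df.iloc[0]["mean_phr"] == pytest.approx(0.7)
        assert np.isnan(df.iloc[0]["sd_phr"])

    def test_all_homozygote_input_empty(self, panel):
        assert len(phr_report([self._profile(panel, {})])) == 0

    def test_amelogenin_excluded(self, panel):
        df = phr_report([self._profile(panel, {"AMEL": 0.5, "vWA": 0.8})])
        assert list(df["locus"]) == ["vWA"]

    def test_simulated_default_phr_means_in_expected_band(self, panel,
                                                          default_bins):
        """Under the default imbalance model the per-locus mean PHR sits in
        the 0.7-0.8 band (within Monte-Carlo error of the band edges)."""
        profiles = []
        seeds = np.random.SeedSequence(2024).generate_state(50) % 2**31
        geno_rng = np.random.default_rng(7)
        for s in seeds:
            g = sx.sample_genotype(panel, seed=geno_rng)
            tr = sx.simulate_sample(g, panel,
                                    sx.SimulationParams(seed=int(s)))
            profiles.append(sx.analyze_sample(tr, default_bins, panel).profile)
        df = phr_report(profiles)
        pooled = np.average(df["mean_phr"], weights=df["n"])
        assert 0.7 <= pooled <= 0.8
        for _, row in df.iterrows():
            se = (row["sd_phr"] / np.sqrt(row["n"])
                  if row["n"] > 1 and np.isfinite(row["sd_phr"]) else 0.05)
            assert 0.7 - 3 * se <= row["mean_phr"] <= 0.8 + 3 * se


class TestConcordance:
    def test_printed_tally_percentage(self):
        tally = ConcordanceTally(n_assessed=8094, n_concordant=8091,
                                 n_discordant=3, n_dropout=3)
        assert tally.percent_concordant == 99.963

    def test_perfect_profile_is_100(self, panel):
        from strexpert.calling import AlleleCall, LocusResult, SampleProfile
        g = sx.sample_genotype(panel, seed=5)
        results = {}
        for locus in panel.loci:
            calls = [AlleleCall(locus.name, d, locus.size_of(d), 900.0)
                     for d in g.calls[locus.name]]
            results[locus.name] = LocusResult(locus.name, calls, status="called")
        prof = SampleProfile("s", results, "full", 13)
        tally = concordance(prof, g)
        assert tally.percent_concordant == 100.0
        assert tally.n_assessed == sum(len(v) for v in g.calls.values())

    def test_flagged_call_counts_as_dropout(self, panel):
        from strexpert.calling import AlleleCall, LocusResult, SampleProfile
        g = sx.Genotype({l.name: (l.designations[0],) for l in panel.loci})
        results = {}
        for i, locus in enumerate(panel.loci):
            call = AlleleCall(locus.name, locus.designations[0],
                              locus.ladder_alleles[0][1], 900.0,
                              flags={"phr_imbalance"} if i == 0 else set())
            results[locus.name] = LocusResult(locus.name, [call], status="called")
        prof = SampleProfile("s", results, "full", 13)
        tally = concordance(prof, g)
        assert tally.n_dropout == 1
        assert tally.n_discordant == 1
        assert tally.n_assessed == 16

    def test_extra_unflagged_call_is_dropin(self, panel):
        from strexpert.calling import AlleleCall, LocusResult, SampleProfile
        g = sx.Genotype({l.name: (l.designations[0],) for l in panel.loci})
        results = {}
        for locus in panel.loci:
            calls = [AlleleCall(locus.name, locus.designations[0],
                                locus.ladder_alleles[0][1], 900.0)]
            if locus.name == "TPOX":
                calls.append(AlleleCall("TPOX", "12", 290.0, 500.0))
            results[locus.name] = LocusResult(locus.name, calls, status="called")
        prof = SampleProfile("s", results, "full", 13)
        tally = concordance(prof, g)
        assert tally.n_dropin == 1
        assert tally.n_concordant == 16

    def test_invariant_concordant_plus_discordant(self):
        with pytest.raises(ValueError):
            ConcordanceTally(n_assessed=10, n_concordant=9, n_discordant=2)


class TestStatusGrid:
    def test_bundled_grid_matches_published_tabulation(self):
        from strexpert.io_formats import load_status_grid
        from importlib import resources
        ref = resources.files("strexpert.data").joinpath(
            "table1_status_grid.csv")
        with resources.as_file(ref) as path:
            grid = load_status_grid(path)
        counts = tabulate_status_grid(grid)
        assert (counts.n_full, counts.n_partial, counts.n_fail) == (91, 4, 1)
        assert counts.n_profiles == 95

    def test_all_full_grid(self):
        counts = tabulate_status_grid(["Y"] * 10)
        assert (counts.n_full, counts.n_partial, counts.n_fail) == (10, 0, 0)

    def test_empty_grid_zeros(self):
        counts = tabulate_status_grid([])
        assert (counts.n_full, counts.n_partial, counts.n_fail,
                counts.n_profiles) == (0, 0, 0, 0)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown status code"):
            tabulate_status_grid([["Y", "?"]])

    def test_dataframe_and_nested_list_agree(self):
        rows = [["Y", "Y*"], ["F", "Y"]]
        a = tabulate_status_grid(rows)
        b = tabulate_status_grid(pd.DataFrame(rows))
        assert (a.n_full, a.n_partial, a.n_fail) == (b.n_full, b.n_partial,
                                                     b.n_fail)


class TestSensitivity:
    def test_curve_monotone_and_saturating(self, panel):
        """Called-locus count rises monotonically with template mass and the
        full-profile fraction reaches 1 at high input."""
        masses = [20.0, 70.0, 200.0, 500.0, 1000.0]
        df = sensitivity_curve(masses, n_reps=8, panel=panel, seed=3)
        called = df["mean_called_loci"].to_numpy()
        assert (np.diff(called) >= 0).all()
        assert df["frac_full"].iloc[-1] == 1.0
        assert df["frac_fail"].iloc[0] > df["frac_fail"].iloc[-1]

    def test_vanishing_mass_fails_everything(self, panel):
        df = sensitivity_curve([1e-3], n_reps=4, panel=panel, seed=1)
        assert df["frac_fail"].iloc[0] == 1.0

    def test_invalid_inputs_rejected(self, panel):
        with pytest.raises(ValueError):
            sensitivity_curve([-1.0], 2, panel)
        with pytest.raises(ValueError):
            sensitivity_curve([100.0], 0, panel)
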