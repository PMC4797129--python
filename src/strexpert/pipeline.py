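"""End-to-end analysis: raw trace in, flagged profile out.

Chains the conditioning, ILS sizing, ladder bin calibration, and rule-based
calling stages exactly as the CLI and the validation metrics use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import (BinSet, LocusResult, SampleProfile, apply_rules,
                      assemble_profile, assign_alleles, calibrate_bins)
from .panel import PanelDefinition
from .signal import correct_baseline, color_correct, detect_peaks
from .simulate import Electropherogram
from .sizing import (ILSAssessment, SizeCalibration, SizedPeak, evaluate_ils,
                     fit_calibration, size_peaks)

__all__ = ["AnalysisResult", "condition_and_size", "calibrate_from_ladder",
           "analyze_sample", "ILSFailure"]


class ILSFailure(RuntimeError):
    """Raised when a run's internal lane standard fails its strict criteria."""


@dataclass
class AnalysisResult:
    profile: SampleProfile
    locus_results: dict[str, LocusResult]
    sized_peaks: list[SizedPeak]
    ils_assessment: ILSAssessment
    calibration: SizeCalibration
    conditioned: Electropherogram = field(repr=False, default=None)


def condition_and_size(trace: Electropherogram, panel: PanelDefinition,
                       min_fwhm_scans: float = 2.0,
                       saturation: float | None = None,
                       method: str = "least-squares-cubic",
                       ) -> tuple[list[SizedPeak], ILSAssessment,
                                  SizeCalibration, Electropherogram]:
    """Condition a raw trace and size its peaks through its own ILS.

    Returns (sized peaks, ILS assessment, calibration, conditioned trace);
    raises :class:`ILSFailure` when the ILS does not pass.
    """
    conditioned = color_correct(correct_baseline(trace),
                                panel.crosstalk_matrix())
    peaks = detect_peaks(conditioned, min_height=panel.analytical_threshold,
                         min_fwhm_scans=min_fwhm_scans, saturation=saturation)
    ils_ch = panel.ils.dye.detector_index
    ils_peaks = [p for p in peaks if p.channel == ils_ch]
    assessment = evaluate_ils(ils_peaks, panel.ils)
    if not assessment.passed:
        raise ILSFailure("; ".join(assessment.failure_reasons))
    calibration = fit_calibration(assessment, method=method)
    locus_peaks = [p for p in peaks if p.channel != ils_ch]
    sized = size_peaks(locus_peaks, calibration, panel.sizing_range)
    return sized, assessment, calibration, conditioned


def calibrate_from_ladder(ladder_trace: Electropherogram,
                          panel: PanelDefinition, **kwargs) -> BinSet:
    """Size a ladder run through its ILS and calibrate allele bins from it."""
    sized, _, _, _ = condition_and_size(ladder_trace, panel, **kwargs)
    return calibrate_bins(sized, panel, run_id=ladder_trace.sample_id)


def analyze_sample(trace: Electropherogram, bins: BinSet,
                   panel: PanelDefinition, **kwargs) -> AnalysisResult:
    """Full analysis of one sample trace against calibrated bins."""
    sized, assessment, calibration, conditioned = condition_and_size(
        trace, panel, **kwargs)
    calls = assign_alleles(sized, bins, panel)
    locus_results = apply_rules(calls, panel)
    profile = assemble_profile(locus_results, panel, sample_id=trace.sample_id)
    return AnalysisResult(profile=profile, locus_results=locus_results,
                          sized_peaks=sized, ils_assessment=assessment,
                          calibration=calibration, conditioned=conditioned)
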