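"""Allele-bin calibration, designation assignment, and quality rules.

The caller mirrors an expert-system workflow: an allelic-ladder run that
passed ILS sizing fixes the allele bins (observed ladder sizes become bin
centers); sample peaks falling in a locus's dye channel and size span are
assigned the designation of the containing bin (off-ladder otherwise); then
quality rules fire in a fixed order — analytical threshold, stutter filter,
heterozygote peak-height ratio — attaching flags rather than deleting
calls. Flagged calls stay visible in the allele table and plots but are
excluded from CODIS export downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import PanelDefinition
from .sizing import SizedPeak

__all__ = [
    "BinSet",
    "AlleleCall",
    "LocusResult",
    "SampleProfile",
    "LadderCalibrationError",
    "calibrate_bins",
    "assign_alleles",
    "compute_phr",
    "apply_rules",
    "assemble_profile",
    "OFF_LADDER",
]

OFF_LADDER = "OL"

FLAG_BELOW_THRESHOLD = "below_threshold"
FLAG_PHR_IMBALANCE = "phr_imbalance"
FLAG_STUTTER = "stutter_filtered"
FLAG_OFF_LADDER = "off_ladder"
FLAG_SATURATED = "saturated"

#: tolerance in bases for matching a candidate to the n-1 stutter position
STUTTER_POSITION_TOL = 0.5


class LadderCalibrationError(RuntimeError):
    """Raised when the allelic ladder fails its strict evaluation criteria."""


@dataclass
class BinSet:
    """Per-locus allele bins calibrated from an allelic-ladder run."""

    bins: dict[str, dict[str, tuple[float, float]]]  # locus -> {allele: (center, half_width)}
    source_run: str = ""

    def locus_span(self, locus: str) -> tuple[float, float]:
        entries = self.bins[locus]
        lows = [c - h for c, h in entries.values()]
        highs = [c + h for c, h in entries.values()]
        return min(lows), max(highs)

    def designation_for(self, locus: str, size: float) -> str | None:
        for allele, (center, half) in self.bins[locus].items():
            if abs(size - center) <= half:
                return allele
        return None


@dataclass
class AlleleCall:
    locus: str
    designation: str  # allele label, or "OL" for off-ladder
    size: float
    height: float
    flags: set[str] = field(default_factory=set)

    @property
    def passing(self) -> bool:
        return not self.flags


@dataclass
class LocusResult:
    """All calls at one locus plus the PHR (heterozygous pairs) and a status."""

    locus: str
    calls: list[AlleleCall]
    phr: float | None = None
    status: str = "dropout"  # called | dropout | flagged_only

    @property
    def passing_calls(self) -> list[AlleleCall]:
        return [c for c in self.calls if c.passing]


@dataclass
class SampleProfile:
    sample_id: str
    locus_results: dict[str, LocusResult]
    category: str  # full | partial | fail
    codis_locus_count: int

    @property
    def codis_searchable(self) -> bool:
        """Searchability annotation: at least 10 CODIS loci called."""
        return self.codis_locus_count >= 10

    def all_calls(self) -> list[AlleleCall]:
        return [c for r in self.locus_results.values() for c in r.calls]


def calibrate_bins(ladder_peaks: list[SizedPeak], panel: PanelDefinition,
                   run_id: str = "ladder") -> BinSet:
    """Match sized ladder peaks to every expected ladder fragment.

    Every expected fragment must have a peak within ``bin_half_width`` of its
    nominal size; bin centers are set to the observed sizes. A missing
    fragment, or an unexpected above-threshold peak inside a locus span,
    fails the ladder with the offending fragment named.
    """
    half = panel.bin_half_width
    bins: dict[str, dict[str, tuple[float, float]]] = {}
    problems: list[str] = []
    for locus in panel.loci:
        chan_peaks = [p for p in ladder_peaks
                      if p.channel == locus.dye.detector_index and p.in_range]
        lo, hi = locus.size_span
        span_peaks = [p for p in chan_peaks if lo - half <= p.size <= hi + half]
        used: set[int] = set()
        entries: dict[str, tuple[float, float]] = {}
        for allele, nominal in locus.ladder_alleles:
            best, best_d = -1, float("inf")
            for j, p in enumerate(span_peaks):
                if j in used:
                    continue
                d = abs(p.size - nominal)
                if d < best_d:
                    best, best_d = j, d
            if best < 0 or best_d > half:
                problems.append(f"{locus.name} allele {allele} "
                                f"({nominal:g} bases) not found in ladder")
                continue
            used.add(best)
            entries[allele] = (span_peaks[best].size, half)
        extras = [p for j, p in enumerate(span_peaks)
                  if j not in used and p.height >= panel.analytical_threshold]
        for p in extras:
            problems.append(f"{locus.name}: unexpected ladder peak at "
                            f"{p.size:.2f} bases")
        bins[locus.name] = entries
    if problems:
        raise LadderCalibrationError("; ".join(problems))
    return BinSet(bins=bins, source_run=run_id)


def assign_alleles(sample_peaks: list[SizedPeak], bins: BinSet,
                   panel: PanelDefinition) -> list[AlleleCall]:
    """Assign designations to sized peaks by dye channel and bin membership.

    A peak inside a locus's dye channel and calibrated size span gets the
    designation of the bin containing its size, or off-ladder ("OL") if no
    bin contains it. Peaks outside every locus span are not called.
    """
    calls: list[AlleleCall] = []
    for locus in panel.loci:
        if locus.name not in bins.bins or not bins.bins[locus.name]:
            continue
        lo, hi = bins.locus_span(locus.name)
        for p in sample_peaks:
            if p.channel != locus.dye.detector_index or not p.in_range:
                continue
            if not lo <= p.size <= hi:
                continue
            designation = bins.designation_for(locus.name, p.size)
            call = AlleleCall(locus=locus.name,
                              designation=designation or OFF_LADDER,
                              size=p.size, height=p.height)
            if designation is None:
                call.flags.add(FLAG_OFF_LADDER)
            if p.saturated:
                call.flags.add(FLAG_SATURATED)
            calls.append(call)
    return calls


def compute_phr(calls: list[AlleleCall]) -> float | None:
    """Peak-height ratio of a heterozygous pair: weakest / strongest height.

    Returns None (not applicable) unless given exactly two calls.
    """
    if len(calls) != 2:
        return None
    h1, h2 = calls[0].height, calls[1].height
    return min(h1, h2) / max(h1, h2)


def apply_rules(calls: list[AlleleCall],
                panel: PanelDefinition) -> dict[str, LocusResult]:
    """Fire the quality rules in order: threshold, stutter, PHR.

    1. height < analytical_threshold -> ``below_threshold``;
    2. a call one repeat unit below a taller unflagged same-locus parent
       with height ratio <= the locus stutter threshold -> ``stutter_filtered``;
    3. exactly two surviving calls with PHR < phr_threshold -> the weaker
       call gets ``phr_imbalance``; more than two surviving calls -> all
       flagged ``phr_imbalance`` for review.

    Returns one LocusResult per panel locus (status ``dropout`` when empty,
    ``flagged_only`` when every call carries a flag).
    """
    by_locus: dict[str, list[AlleleCall]] = {l.name: [] for l in panel.loci}
    for c in calls:
        by_locus[c.locus].append(c)

    results: dict[str, LocusResult] = {}
    for locus in panel.loci:
        lcalls = sorted(by_locus[locus.name], key=lambda c: c.size)
        for c in lcalls:
            if c.height < panel.analytical_threshold:
                c.flags.add(FLAG_BELOW_THRESHOLD)
        # stutter: compare against the tallest unflagged call >= one repeat larger
        for c in lcalls:
            target = c.size + locus.repeat_unit
            parents = [p for p in lcalls
                       if p is not c and p.passing
                       and abs(p.size - target) <= STUTTER_POSITION_TOL]
            if not parents:
                continue
            parent = max(parents, key=lambda p: p.height)
            if c.height / parent.height <= locus.stutter_threshold:
                c.flags.add(FLAG_STUTTER)
        survivors = [c for c in lcalls if c.passing]
        if len(survivors) == 2:
            ratio = compute_phr(survivors)
            if ratio is not None and ratio < panel.phr_threshold:
                weaker = min(survivors, key=lambda c: c.height)
                weaker.flags.add(FLAG_PHR_IMBALANCE)
        elif len(survivors) > 2:
            for c in survivors:
                c.flags.add(FLAG_PHR_IMBALANCE)
        remaining = [c for c in lcalls if c.passing]
        # PHR is recorded only for a surviving heterozygous pair
        phr = compute_phr(remaining) if len(remaining) == 2 else None
        if remaining:
            status = "called"
        elif lcalls:
            status = "flagged_only"
        else:
            status = "dropout"
        results[locus.name] = LocusResult(locus=locus.name, calls=lcalls,
                                          phr=phr, status=status)
    return results


def assemble_profile(locus_results: dict[str, LocusResult],
                     panel: PanelDefinition,
                     sample_id: str = "sample") -> SampleProfile:
    """Categorize a sample: full (all loci called), fail (none), else partial."""
    missing = [l.name for l in panel.loci if l.name not in locus_results]
    if missing:
        raise ValueError(f"missing locus result(s): {missing}")
    n_called = sum(1 for r in locus_results.values() if r.status == "called")
    if n_called == len(panel.loci):
        category = "full"
    elif n_called == 0:
        category = "fail"
    else:
        category = "partial"
    codis = sum(1 for l in panel.loci
                if l.is_codis and locus_results[l.name].status == "called")
    return SampleProfile(sample_id=sample_id, locus_results=dict(locus_results),
                         category=category, codis_locus_count=codis)
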