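"""Developmental-validation metrics.

Implements the statistics a validation study reports for an STR system:

* sizing **precision** — per-ladder-fragment standard deviation of
  calibrated size across repeated injections, judged against an acceptance
  bound (default 0.16 bases);
* **resolution** R — fragment-size separation divided by the mean baseline
  peak width (baseline width of a Gaussian = 4 sigma = 2 FWHM / sqrt(2 ln 2));
  a single peak is scored against a hypothetical equal-width twin one base
  away, i.e. R = 1 / baseline width in bases;
* **peak-height-ratio** statistics per locus over heterozygous calls;
* **concordance** of called profiles against reference genotypes, with
  dropouts counted discordant and drop-ins tallied separately;
* **reproducibility** tabulation of full/partial/fail status grids;
* a **sensitivity** curve: called-locus counts and profile-category
  fractions as a function of template mass, by end-to-end Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import SampleProfile
from .panel import PanelDefinition
from .pipeline import analyze_sample, calibrate_from_ladder
from .simulate import (Genotype, SimulationParams, sample_genotype,
                       simulate_ladder_run, simulate_sample)
from .sizing import SizedPeak

__all__ = [
    "PrecisionReport", "ResolutionReport", "ConcordanceTally",
    "ReproducibilityCounts", "precision_report", "resolution", "phr_report",
    "concordance", "tabulate_status_grid", "sensitivity_curve",
    "ladder_fragment_sizes", "precision_study", "resolution_sweep",
    "PRECISION_BOUND",
]

#: acceptance bound on per-fragment sizing SD, bases
PRECISION_BOUND = 0.16

_BASELINE_PER_FWHM = 2.0 / math.sqrt(2.0 * math.log(2.0))  # W_b = this * FWHM


@dataclass
class PrecisionReport:
    """Per-fragment sizing SD across runs, with a pass/fail acceptance flag."""

    sd_by_fragment: dict[tuple[str, str], float]  # (locus, allele) -> SD, bases
    bound: float

    @property
    def max_sd(self) -> float:
        return max(self.sd_by_fragment.values())

    @property
    def passed(self) -> bool:
        return self.max_sd < self.bound

    def to_frame(self) -> pd.DataFrame:
        rows = [{"locus": l, "allele": a, "sd_bases": sd}
                for (l, a), sd in self.sd_by_fragment.items()]
        return pd.DataFrame(rows)


def precision_report(runs: list[dict[tuple[str, str], float]],
                     bound: float = PRECISION_BOUND) -> PrecisionReport:
    """Sample SD (n-1 denominator) of each fragment's size across runs.

    ``runs`` holds one mapping per injection: (locus, allele) -> observed
    size in bases. All runs must cover the identical fragment set.
    """
    if len(runs) < 2:
        raise ValueError("precision needs at least 2 runs")
    keys = set(runs[0])
    for i, run in enumerate(runs[1:], start=2):
        if set(run) != keys:
            raise ValueError(f"run {i} fragment set differs from run 1")
    sd = {k: float(np.std([run[k] for run in runs], ddof=1)) for k in keys}
    return PrecisionReport(sd_by_fragment=sd, bound=bound)


def resolution(peak: SizedPeak, other: SizedPeak | None = None) -> float:
    """Resolution R from one or two sized peaks.

    For a pair: R = (S2 - S1) / (0.5 * (Wb1 + Wb2)) with Wb the baseline
    width (4 sigma for a Gaussian). For a single peak, R is evaluated for a
    hypothetical twin of equal width one base away: R = 1 / Wb.
    """
    wb1 = _BASELINE_PER_FWHM * peak.fwhm_bases
    if not wb1 > 0:
        raise ValueError("peak width must be positive")
    if other is None:
        return 1.0 / wb1
    wb2 = _BASELINE_PER_FWHM * other.fwhm_bases
    if not wb2 > 0:
        raise ValueError("peak width must be positive")
    return abs(other.size - peak.size) / (0.5 * (wb1 + wb2))


@dataclass
class ResolutionReport:
    """R evaluated per fragment size across the sizing range."""

    r_by_size: dict[float, float]

    @property
    def min_r(self) -> float:
        return min(self.r_by_size.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.r_by_size.items()),
                            columns=["size_bases", "R"])


def phr_report(profiles: list[SampleProfile],
               exclude: tuple[str, ...] = ("AMEL",)) -> pd.DataFrame:
    """Per-locus mean and SD of peak-height ratio over heterozygous loci.

    Only loci with a recorded PHR (a surviving heterozygous pair)
    contribute. Amelogenin is excluded by default: its X/Y imbalance is
    sex-dependent, not a measure of amplification balance.
    """
    obs: dict[str, list[float]] = {}
    for prof in profiles:
        for name, res in prof.locus_results.items():
            if name in exclude or res.phr is None:
                continue
            obs.setdefault(name, []).append(res.phr)
    rows = []
    for name, values in obs.items():
        rows.append({
            "locus": name,
            "n": len(values),
            "mean_phr": float(np.mean(values)),
            "sd_phr": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["locus", "n", "mean_phr", "sd_phr"])


@dataclass
class ConcordanceTally:
    """Allele-level concordance bookkeeping against reference genotypes."""

    n_assessed: int
    n_concordant: int
    n_discordant: int
    n_dropout: int = 0
    n_dropin: int = 0

    def __post_init__(self):
        if self.n_concordant + self.n_discordant != self.n_assessed:
            raise ValueError("concordant + discordant must equal assessed")

    @property
    def percent_concordant(self) -> float:
        """Percent of assessed alleles concordant, to 3 decimals."""
        if self.n_assessed == 0:
            return float("nan")
        return round(100.0 * self.n_concordant / self.n_assessed, 3)

    def __add__(self, other: "ConcordanceTally") -> "ConcordanceTally":
        return ConcordanceTally(
            self.n_assessed + other.n_assessed,
            self.n_concordant + other.n_concordant,
            self.n_discordant + other.n_discordant,
            self.n_dropout + other.n_dropout,
            self.n_dropin + other.n_dropin)


def concordance(profile: SampleProfile, reference: Genotype) -> ConcordanceTally:
    """Tally a called profile against its reference genotype.

    Every reference allele designation is assessed: a matching unflagged
    call is concordant; a missing one is a dropout (counted discordant).
    An unflagged call with no matching reference allele is a drop-in
    (tallied separately, outside the assessed denominator).
    """
    assessed = concordant = dropout = dropin = 0
    for locus, ref_alleles in reference.calls.items():
        res = profile.locus_results.get(locus)
        called = ([c.designation for c in res.passing_calls] if res else [])
        remaining = list(called)
        for allele in ref_alleles:
            assessed += 1
            if allele in remaining:
                remaining.remove(allele)
                concordant += 1
            else:
                dropout += 1
        dropin += len(remaining)
    return ConcordanceTally(n_assessed=assessed, n_concordant=concordant,
                            n_discordant=assessed - concordant,
                            n_dropout=dropout, n_dropin=dropin)


@dataclass
class ReproducibilityCounts:
    n_full: int
    n_partial: int
    n_fail: int

    @property
    def n_profiles(self) -> int:
        """Samples that generated a profile (full + partial)."""
        return self.n_full + self.n_partial


_STATUS_CODES = {"Y": "full", "Y*": "partial", "F": "fail"}


def tabulate_status_grid(grid) -> ReproducibilityCounts:
    """Count full/partial/fail from a grid of status codes Y / Y* / F.

    ``grid`` may be a DataFrame, a nested list, or any flat iterable of
    codes. Unknown codes raise.
    """
    if isinstance(grid, pd.DataFrame):
        codes = grid.to_numpy().ravel().tolist()
    else:
        codes = []
        for row in grid:
            if isinstance(row, str):
                codes.append(row)
            else:
                codes.extend(row)
    counts = {"full": 0, "partial": 0, "fail": 0}
    for code in codes:
        code = str(code).strip()
        if code not in _STATUS_CODES:
            raise ValueError(f"unknown status code {code!r}")
        counts[_STATUS_CODES[code]] += 1
    return ReproducibilityCounts(n_full=counts["full"],
                                 n_partial=counts["partial"],
                                 n_fail=counts["fail"])


def ladder_fragment_sizes(ladder_trace, panel: PanelDefinition
                          ) -> dict[tuple[str, str], float]:
    """Size a ladder run end-to-end and return (locus, allele) -> size in bases.

    Every expected ladder fragment must be matched within the panel's bin
    half-width; anything else raises, as in bin calibration.
    """
    from .pipeline import condition_and_size
    from .calling import calibrate_bins
    sized, _, _, _ = condition_and_size(ladder_trace, panel)
    bins = calibrate_bins(sized, panel, run_id=ladder_trace.sample_id)
    return {(locus, allele): center
            for locus, entries in bins.bins.items()
            for allele, (center, _) in entries.items()}


def precision_study(panel: PanelDefinition, n_runs: int = 20,
                    params: SimulationParams | None = None, seed: int = 0,
                    bound: float = PRECISION_BOUND) -> PrecisionReport:
    """Simulate ``n_runs`` ladder injections and report per-fragment sizing SD."""
    from dataclasses import replace
    base = params or SimulationParams()
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_runs)]
    runs = []
    for i in range(n_runs):
        ladder = simulate_ladder_run(panel, replace(base, seed=seeds[i]),
                                     run_id=f"ladder_{i:02d}")
        runs.append(ladder_fragment_sizes(ladder, panel))
    return precision_report(runs, bound=bound)


def resolution_sweep(panel: PanelDefinition,
                     params: SimulationParams | None = None,
                     size_range: tuple[float, float] = (100.0, 500.0),
                     ) -> ResolutionReport:
    """Single-peak resolution R for every ladder fragment in ``size_range``.

    Simulates one noise-free ladder run under the default width model,
    sizes its peaks end-to-end, and evaluates R = 1 / baseline width for
    each fragment. Deterministic.
    """
    from dataclasses import replace
    from .pipeline import condition_and_size
    base = params or SimulationParams()
    quiet = replace(base, noise_sd=0.0, baseline_amplitude=0.0,
                    stutter_mean=0.0, stutter_sd=0.0,
                    stutter_mean_penta=0.0, stutter_sd_penta=0.0)
    ladder = simulate_ladder_run(panel, quiet, run_id="resolution")
    sized, _, _, _ = condition_and_size(ladder, panel)
    lo, hi = size_range
    r_by_size: dict[float, float] = {}
    for locus in panel.loci:
        for _allele, nominal in locus.ladder_alleles:
            if not lo <= nominal <= hi:
                continue
            near = [p for p in sized
                    if p.channel == locus.dye.detector_index
                    and abs(p.size - nominal) <= panel.bin_half_width]
            if not near:
                continue
            peak = max(near, key=lambda p: p.height)
            r_by_size[nominal] = resolution(peak)
    return ResolutionReport(r_by_size=r_by_size)


def sensitivity_curve(template_masses: list[float], n_reps: int,
                      panel: PanelDefinition,
                      params: SimulationParams | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo sensitivity study: end-to-end analysis across a mass series.

    For each template mass, ``n_reps`` genotypes are drawn, simulated,
    and analyzed against a freshly calibrated ladder; reports the mean
    called-locus count and the full/partial/fail category fractions.
    Reproducible from ``seed``.
    """
    if any(m <= 0 for m in template_masses):
        raise ValueError("template masses must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = params or SimulationParams()
    root = np.random.SeedSequence(seed)
    ladder_seed, geno_seed, sample_root = root.spawn(3)
    from dataclasses import replace
    ladder = simulate_ladder_run(
        panel, replace(base, seed=int(ladder_seed.generate_state(1)[0] % 2**31)))
    bins = calibrate_from_ladder(ladder, panel)
    geno_rng = np.random.default_rng(geno_seed)
    genotypes = [sample_genotype(panel, seed=geno_rng) for _ in range(n_reps)]
    sample_seeds = [int(s.generate_state(1)[0] % 2**31)
                    for s in sample_root.spawn(n_reps)]

    rows = []
    for mass in template_masses:
        cats = {"full": 0, "partial": 0, "fail": 0}
        called_counts = []
        for rep in range(n_reps):
            p = replace(base, template_mass=float(mass), seed=sample_seeds[rep])
            trace = simulate_sample(genotypes[rep], panel, p,
                                    sample_id=f"m{mass:g}_r{rep}")
            result = analyze_sample(trace, bins, panel)
            cats[result.profile.category] += 1
            called_counts.append(sum(
                1 for r in result.locus_results.values() if r.status == "called"))
        rows.append({
            "template_mass_pg": float(mass),
            "mean_called_loci": float(np.mean(called_counts)),
            "frac_full": cats["full"] / n_reps,
            "frac_partial": cats["partial"] / n_reps,
            "frac_fail": cats["fail"] / n_reps,
        })
    return pd.DataFrame(rows)
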