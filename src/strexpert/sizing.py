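"""Internal-lane-standard evaluation and scan-to-size calibration.

Every injection carries an ILS: a set of dye-labeled fragments of known
size. Sizing proceeds in three steps: (1) match the detected ILS-channel
peaks to the expected fragments under strict criteria (every fragment
matched exactly once, monotone, small fit residuals); (2) fit a monotone
size-to-scan mapping — a global least-squares cubic by default, classic
Local Southern as an alternative; (3) convert every sample peak's apex scan
to a size in bases through the inverse mapping, and its FWHM to bases
through the local slope.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .panel import ILSDefinition
from .signal import Peak

__all__ = [
    "ILSAssessment",
    "SizeCalibration",
    "SizedPeak",
    "CalibrationError",
    "evaluate_ils",
    "fit_calibration",
    "size_peaks",
]

#: maximum |fit residual| in bases for an ILS "pass"
DEFAULT_RESIDUAL_BOUND = 0.25
#: fraction of the local inter-fragment scan gap used as assignment tolerance
DEFAULT_GAP_TOLERANCE = 0.25


class CalibrationError(RuntimeError):
    """Raised when size calibration cannot be constructed."""


@dataclass
class ILSAssessment:
    """Outcome of matching detected ILS peaks against expected fragments."""

    status: str  # "pass" | "fail"
    matched_fragments: list[tuple[float, float]]  # (expected size, apex scan)
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _fit_cubic(sizes: np.ndarray, scans: np.ndarray) -> np.polynomial.Polynomial:
    deg = min(3, len(sizes) - 1)
    return np.polynomial.Polynomial.fit(sizes, scans, deg).convert()


def evaluate_ils(peaks: list[Peak], ils: ILSDefinition,
                 residual_bound: float = DEFAULT_RESIDUAL_BOUND,
                 gap_tolerance: float = DEFAULT_GAP_TOLERANCE) -> ILSAssessment:
    """Match ILS-channel peaks to the expected fragment sizes.

    Strategy: anchor an affine size->scan guess on the outermost prominent
    peaks, then greedily assign each expected fragment to the nearest unused
    peak within ``gap_tolerance`` of the local predicted inter-fragment gap,
    enforcing monotonicity; finally refit a cubic on the matches and demand
    every |residual| <= ``residual_bound`` bases. Spurious small peaks
    between fragments are simply left unmatched. Failure is a status with
    reasons, never an exception.
    """
    expected = np.asarray(ils.fragment_sizes, dtype=float)
    m = len(expected)
    if len(peaks) < 2:
        return ILSAssessment("fail", [], [
            f"expected {m} ILS fragments, detected only {len(peaks)} peaks"])

    cand = sorted(peaks, key=lambda p: p.apex_scan)
    scans = np.array([p.apex_scan for p in cand])
    heights = np.array([p.height for p in cand])
    # Anchor on prominent peaks: ILS fragments are near-uniform in height,
    # spurs are usually smaller.
    ref = np.median(np.sort(heights)[-m:])
    prominent = scans[heights >= 0.5 * ref]
    if len(prominent) < 2:
        return ILSAssessment("fail", [], ["too few prominent ILS peaks"])
    a = (prominent[-1] - prominent[0]) / (expected[-1] - expected[0])
    b = prominent[0] - a * expected[0]
    predicted = a * expected + b
    gaps = np.diff(predicted)

    matched: list[tuple[float, float]] = []
    reasons: list[str] = []
    used = np.zeros(len(cand), dtype=bool)
    last_scan = -np.inf
    for i, size in enumerate(expected):
        local_gap = min(gaps[max(0, i - 1)], gaps[min(i, len(gaps) - 1)])
        tol = gap_tolerance * local_gap
        best, best_d = -1, np.inf
        for j in range(len(cand)):
            if used[j] or scans[j] <= last_scan:
                continue
            d = abs(scans[j] - predicted[i])
            if d < best_d:
                best, best_d = j, d
        if best < 0 or best_d > tol:
            reasons.append(f"missing fragment: {size:g} bases")
            continue
        used[best] = True
        last_scan = scans[best]
        matched.append((float(size), float(scans[best])))

    if reasons:
        return ILSAssessment("fail", matched, reasons)

    ms = np.array([s for s, _ in matched])
    mx = np.array([x for _, x in matched])
    if np.any(np.diff(mx) <= 0):
        return ILSAssessment("fail", matched, ["matched scans not strictly increasing"])
    poly = _fit_cubic(ms, mx)
    slope = poly.deriv()(ms)
    resid_bases = (mx - poly(ms)) / slope
    worst = float(np.max(np.abs(resid_bases)))
    if worst > residual_bound:
        return ILSAssessment("fail", matched, [
            f"max fit residual {worst:.3f} bases exceeds bound {residual_bound:g}"])
    return ILSAssessment("pass", matched)


@dataclass
class SizeCalibration:
    """A monotone scan -> size mapping over the calibrated ILS interval."""

    method: str  # "least-squares-cubic" | "local-southern"
    fragment_sizes: np.ndarray
    fragment_scans: np.ndarray
    residuals: dict[float, float]  # expected size -> size error in bases
    _poly: np.polynomial.Polynomial | None = None

    @property
    def scan_range(self) -> tuple[float, float]:
        return float(self.fragment_scans[0]), float(self.fragment_scans[-1])

    @property
    def size_range(self) -> tuple[float, float]:
        return float(self.fragment_sizes[0]), float(self.fragment_sizes[-1])

    def size_to_scan(self, size: float) -> float:
        if self._poly is not None:
            return float(self._poly(size))
        raise CalibrationError("local-southern has no forward mapping")

    def scan_to_size(self, scan: float) -> float:
        if self._poly is not None:
            lo, hi = self.size_range
            lo, hi = lo - 30.0, hi + 30.0
            f = lambda s: self._poly(s) - scan
            if f(lo) * f(hi) > 0:
                raise CalibrationError(f"scan {scan:.1f} outside invertible range")
            return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-9))
        return self._local_southern(scan)

    def slope_scan_per_base(self, size: float) -> float:
        if self._poly is not None:
            return float(self._poly.deriv()(size))
        # numerical slope of the piecewise mapping
        eps = 0.5
        x0 = self._ls_forward(size - eps)
        x1 = self._ls_forward(size + eps)
        return (x1 - x0) / (2 * eps)

    # -- Local Southern -----------------------------------------------------
    # Classic fragment-sizing method: fit size = c/(scan - m) + k through two
    # overlapping triples of ILS fragments bracketing the peak and average
    # the two size predictions.

    @staticmethod
    def _reciprocal_fit(sizes, scans):
        # closed-form solve of s_i = c/(x_i - m) + k through three points
        (x1, x2, x3), (s1, s2, s3) = scans, sizes
        denom = (s2 - s3) * (x2 - x1)
        if abs(denom) < 1e-12:
            raise CalibrationError("degenerate ILS triple for local-southern")
        r = (s1 - s2) * (x3 - x2) / denom
        if abs(1.0 - r) < 1e-9:  # mobility locally linear; push pole to -inf
            raise CalibrationError("locally linear triple")
        m0 = (x3 - r * x1) / (1.0 - r)
        c = (s1 - s2) * (x1 - m0) * (x2 - m0) / (x2 - x1)
        k = s1 - c / (x1 - m0)
        return c, m0, k

    def _local_southern(self, scan: float) -> float:
        xs = self.fragment_scans
        ss = self.fragment_sizes
        i = bisect.bisect_left(list(xs), scan)
        preds = []
        for start in (i - 2, i - 1):
            start = min(max(start, 0), len(xs) - 3)
            try:
                c, m0, k = self._reciprocal_fit(ss[start:start + 3],
                                                xs[start:start + 3])
            except CalibrationError:
                continue
            if abs(scan - m0) < 1e-9:
                continue
            preds.append(c / (scan - m0) + k)
        if not preds:
            raise CalibrationError("local-southern fit degenerate at this scan")
        return float(np.mean(preds))

    def _ls_forward(self, size: float) -> float:
        # crude forward mapping by interpolation (for slope only)
        return float(np.interp(size, self.fragment_sizes, self.fragment_scans))


def fit_calibration(assessment: ILSAssessment,
                    method: str = "least-squares-cubic") -> SizeCalibration:
    """Build a scan->size calibration from a passing ILS assessment.

    The default fits a least-squares cubic in the size->scan direction
    (exactly invertible for cubic electrophoretic mobility) and inverts it by
    monotone root finding; residuals are reported per fragment in bases.
    """
    if not assessment.passed:
        raise CalibrationError(
            "cannot calibrate: ILS assessment failed "
            f"({'; '.join(assessment.failure_reasons)})")
    sizes = np.array([s for s, _ in assessment.matched_fragments])
    scans = np.array([x for _, x in assessment.matched_fragments])
    if method == "least-squares-cubic":
        poly = _fit_cubic(sizes, scans)
        slope = poly.deriv()(sizes)
        if np.any(poly.deriv()(np.linspace(sizes[0], sizes[-1], 200)) <= 0):
            raise CalibrationError("fitted mapping is not strictly increasing")
        resid = {float(s): float(r)
                 for s, r in zip(sizes, (scans - poly(sizes)) / slope)}
        return SizeCalibration(method, sizes, scans, resid, _poly=poly)
    if method == "local-southern":
        cal = SizeCalibration(method, sizes, scans, {}, _poly=None)
        resid = {}
        for s, x in zip(sizes, scans):
            try:
                resid[float(s)] = float(cal._local_southern(x) - s)
            except CalibrationError:
                resid[float(s)] = float("nan")
        cal.residuals = resid
        return cal
    raise ValueError(f"unknown calibration method {method!r}")


@dataclass(frozen=True)
class SizedPeak:
    """A detected peak with its calibrated size in bases."""

    channel: int
    apex_scan: float
    height: float
    area: float
    fwhm_scans: float
    size: float
    fwhm_bases: float
    in_range: bool = True
    saturated: bool = False


def size_peaks(peaks: list[Peak], calibration: SizeCalibration,
               sizing_range: tuple[float, float] | None = None) -> list[SizedPeak]:
    """Convert peak apex scans to sizes in bases through the calibration.

    Peaks outside the calibrated scan interval or the panel sizing range are
    kept but marked ``in_range=False``.
    """
    lo_scan, hi_scan = calibration.scan_range
    out: list[SizedPeak] = []
    for p in peaks:
        if not lo_scan <= p.apex_scan <= hi_scan:
            out.append(SizedPeak(p.channel, p.apex_scan, p.height, p.area,
                                 p.fwhm_scans, size=float("nan"),
                                 fwhm_bases=float("nan"), in_range=False,
                                 saturated=p.saturated))
            continue
        size = calibration.scan_to_size(p.apex_scan)
        slope = calibration.slope_scan_per_base(size)
        fwhm_bases = p.fwhm_scans / slope
        in_range = (sizing_range is None
                    or sizing_range[0] <= size <= sizing_range[1])
        out.append(SizedPeak(p.channel, p.apex_scan, p.height, p.area,
                             p.fwhm_scans, size=float(size),
                             fwhm_bases=float(fwhm_bases),
                             in_range=in_range, saturated=p.saturated))
    return out
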