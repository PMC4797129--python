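"""Synthetic capillary-electrophoresis trace generator.

Emulates four-dye STR electropherograms: Gaussian peaks on a nonlinear
size-to-scan mobility warp, exponential size-dependent signal decay
(degradation), lognormal heterozygote imbalance, n-1 repeat stutter,
template-mass-dependent per-allele dropout on a logistic-in-log-mass curve,
linear spectral crosstalk between dye channels, slow baseline drift, white
detector noise, and hard clipping at the camera saturation ceiling.

All randomness in one simulated run flows from ``SimulationParams.seed``
through a single generator stream. The stream is consumed in a fixed order
that does not depend on which alleles survive dropout, so two runs differing
only in ``template_mass`` share their dropout uniforms — this is what makes
called-locus counts deterministically monotone in template mass for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import PanelDefinition

__all__ = [
    "Genotype",
    "SimulationParams",
    "Electropherogram",
    "simulate_sample",
    "simulate_ladder_run",
    "sample_genotype",
    "default_crosstalk",
]


@dataclass(frozen=True)
class Genotype:
    """Per-locus allele calls: one designation (homozygote) or two (heterozygote)."""

    calls: dict[str, tuple[str, ...]]

    def alleles(self, locus: str) -> tuple[str, ...]:
        return self.calls[locus]


def default_crosstalk(n: int = 4, bleed: float = 0.03) -> np.ndarray:
    """Adjacent-channel spectral bleed matrix (diagonally dominant, invertible)."""
    m = np.eye(n)
    for i in range(n - 1):
        m[i, i + 1] = bleed
        m[i + 1, i] = bleed
    return m


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the trace generator. Defaults define the study conditions.

    template_mass        pg of genomic DNA amplified (default 500 pg)
    height_scale         RFU per pg of template at size 0 (before decay)
    imbalance_dispersion lognormal sigma of the per-allele height multiplier;
                         0.27 puts the mean heterozygote peak-height ratio
                         near 0.76
    stutter_mean/sd      per-allele stutter ratio distribution (truncated
                         >= 0); loci with repeat unit >= 5 use the separate
                         *_penta values, mirroring the low stutter of
                         pentanucleotide loci
    noise_sd             white detector noise, RFU
    baseline_amplitude   amplitude of the slow sinusoidal drift, RFU
    crosstalk            dye -> detector mixing matrix (square, invertible)
    saturation           camera ceiling, RFU (hard clip)
    degradation_rate     per-base exponential decay of allele peak height
    dropout_m50          template mass (pg) at 50% per-allele dropout;
                         <= 0 disables dropout entirely
    dropout_slope        logistic steepness in log mass
    warp                 size -> scan cubic coefficients (c0..c3), strictly
                         increasing on the sizing range
    width_intercept/slope  peak sigma in scans as an affine function of size,
                         floored at width_floor scans
    ladder_height        nominal ladder fragment height, RFU
    ils_height           ILS fragment height, RFU
    seed                 master seed of the run
    """

    template_mass: float = 500.0
    height_scale: float = 6.0
    imbalance_dispersion: float = 0.27
    stutter_mean: float = 0.07
    stutter_sd: float = 0.015
    # pentanucleotide loci stutter far less than tetranucleotide loci
    stutter_mean_penta: float = 0.02
    stutter_sd_penta: float = 0.008
    noise_sd: float = 4.0
    baseline_amplitude: float = 20.0
    crosstalk: np.ndarray = field(default_factory=default_crosstalk, compare=False)
    saturation: float = 30000.0
    degradation_rate: float = 0.0015
    dropout_m50: float = 72.0
    dropout_slope: float = 3.0
    warp: tuple[float, float, float, float] = (200.0, 10.0, 1e-4, 1e-7)
    width_intercept: float = -0.57
    width_slope: float = 0.01526
    width_floor: float = 1.2
    ladder_height: float = 1200.0
    ils_height: float = 1000.0
    seed: int = 0

    def warp_scan(self, size):
        """Map fragment size in bases to (sub-)scan position."""
        c0, c1, c2, c3 = self.warp
        s = np.asarray(size, dtype=float)
        return c0 + c1 * s + c2 * s**2 + c3 * s**3

    def warp_slope(self, size):
        """d(scan)/d(size) of the mobility warp."""
        _, c1, c2, c3 = self.warp
        s = np.asarray(size, dtype=float)
        return c1 + 2 * c2 * s + 3 * c3 * s**2

    def sigma_scans(self, size):
        """Peak sigma in scans at a given fragment size."""
        s = np.asarray(size, dtype=float)
        return np.maximum(self.width_floor,
                          self.width_intercept + self.width_slope * s)

    def dropout_probability(self, template_mass: float | None = None) -> float:
        """Per-allele dropout probability: logistic in log template mass."""
        m = self.template_mass if template_mass is None else template_mass
        if self.dropout_m50 <= 0 or m <= 0:
            return 0.0 if m > 0 else 1.0
        return 1.0 / (1.0 + (m / self.dropout_m50) ** self.dropout_slope)

    def n_scans_for(self, panel: PanelDefinition) -> int:
        top = max(max(panel.ils.fragment_sizes), panel.sizing_range[1])
        return int(np.ceil(self.warp_scan(top + 20.0))) + 60


@dataclass
class Electropherogram:
    """Scan-indexed multi-channel fluorescence trace plus run metadata."""

    values: np.ndarray  # (n_scans, n_channels), RFU
    sample_id: str = "sample"
    panel_id: str = "panel"
    run_kind: str = "sample"  # sample | ladder | ils
    dye_names: tuple[str, ...] = ()

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "Electropherogram":
        return replace(self, values=values)


def _render(pure: np.ndarray, channel: int, size: float, height: float,
            params: SimulationParams) -> None:
    """Add one Gaussian peak (in the pure per-dye signal) in place."""
    apex = float(params.warp_scan(size))
    sigma = float(params.sigma_scans(size))
    lo = max(0, int(apex - 6 * sigma))
    hi = min(pure.shape[0], int(apex + 6 * sigma) + 2)
    if hi <= lo:
        return
    x = np.arange(lo, hi, dtype=float)
    pure[lo:hi, channel] += height * np.exp(-0.5 * ((x - apex) / sigma) ** 2)


def _finish(pure: np.ndarray, params: SimulationParams,
            rng: np.random.Generator) -> np.ndarray:
    """Mix through crosstalk, add drift and noise, clip at saturation."""
    n_scans, n_ch = pure.shape
    mixed = pure @ np.asarray(params.crosstalk, dtype=float).T
    if params.baseline_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        x = np.arange(n_scans, dtype=float)
        for c in range(n_ch):
            mixed[:, c] += params.baseline_amplitude * (
                0.5 + 0.5 * np.sin(2 * np.pi * 2.0 * x / n_scans + phases[c]))
    else:
        rng.uniform(0, 2 * np.pi, size=n_ch)  # keep stream alignment
    if params.noise_sd > 0:
        mixed += rng.normal(0.0, params.noise_sd, size=mixed.shape)
    else:
        rng.normal(0.0, 1.0, size=mixed.shape)
    return np.minimum(mixed, params.saturation)


def _add_ils(pure: np.ndarray, panel: PanelDefinition,
             params: SimulationParams) -> None:
    ch = panel.ils.dye.detector_index
    for size in panel.ils.fragment_sizes:
        _render(pure, ch, size, params.ils_height, params)


def simulate_sample(genotype: Genotype, panel: PanelDefinition,
                    params: SimulationParams | None = None,
                    sample_id: str = "sample") -> Electropherogram:
    """Simulate one sample electropherogram for a genotype.

    Homozygous loci carry both template copies in one peak (double height).
    Each allele copy set survives dropout independently; each surviving
    allele spawns one n-1 stutter peak. The ILS is always present.
    """
    params = params or SimulationParams()
    loci = {l.name: l for l in panel.loci}
    for name in genotype.calls:
        if name not in loci:
            raise KeyError(f"genotype locus {name!r} not in panel")

    rng = np.random.default_rng(params.seed)
    order = sorted(genotype.calls)
    # Fixed-order stream consumption: dropout uniforms for every allele slot
    # first, then imbalance, then stutter — independent of survival.
    drop_u = {loc: rng.uniform(size=2) for loc in order}
    imb = {loc: np.exp(params.imbalance_dispersion * rng.normal(size=2))
           for loc in order}
    stut = {}
    for loc in order:
        if loci[loc].repeat_unit >= 5:
            mean, sd = params.stutter_mean_penta, params.stutter_sd_penta
        else:
            mean, sd = params.stutter_mean, params.stutter_sd
        stut[loc] = np.maximum(0.0, rng.normal(mean, sd, size=2))

    p_drop = params.dropout_probability()
    pure = np.zeros((params.n_scans_for(panel), panel.n_channels))
    for loc_name in order:
        locus = loci[loc_name]
        alleles = genotype.calls[loc_name]
        copies = 2 if len(alleles) == 1 else 1
        for k, designation in enumerate(alleles):
            if drop_u[loc_name][k] < p_drop:
                continue
            size = locus.size_of(designation)
            height = (params.height_scale * params.template_mass * copies
                      * np.exp(-params.degradation_rate * size)
                      * imb[loc_name][k])
            _render(pure, locus.dye.detector_index, size, height, params)
            ratio = stut[loc_name][k]
            if ratio > 0:
                _render(pure, locus.dye.detector_index,
                        size - locus.repeat_unit, height * ratio, params)
    _add_ils(pure, panel, params)
    values = _finish(pure, params, rng)
    return Electropherogram(values=values, sample_id=sample_id,
                            panel_id=panel.name, run_kind="sample",
                            dye_names=tuple(d.name for d in panel.dyes))


def simulate_ladder_run(panel: PanelDefinition,
                        params: SimulationParams | None = None,
                        run_id: str = "ladder") -> Electropherogram:
    """Simulate an allelic-ladder injection: every ladder fragment of every
    locus at a fixed nominal height, plus the ILS, plus trace noise."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    pure = np.zeros((params.n_scans_for(panel), panel.n_channels))
    for locus in panel.loci:
        for _, size in locus.ladder_alleles:
            _render(pure, locus.dye.detector_index, size,
                    params.ladder_height, params)
    _add_ils(pure, panel, params)
    values = _finish(pure, params, rng)
    return Electropherogram(values=values, sample_id=run_id,
                            panel_id=panel.name, run_kind="ladder",
                            dye_names=tuple(d.name for d in panel.dyes))


def sample_genotype(panel: PanelDefinition,
                    allele_frequencies: dict[str, dict[str, float]] | None = None,
                    seed: int | np.random.Generator = 0) -> Genotype:
    """Draw a genotype under Hardy-Weinberg equilibrium, one locus at a time.

    ``allele_frequencies`` maps locus name to {designation: frequency}; when
    omitted, frequencies are uniform over each locus's ladder alleles.
    Frequencies at each locus must sum to 1 within 1e-9.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    calls: dict[str, tuple[str, ...]] = {}
    for locus in panel.loci:
        if allele_frequencies and locus.name in allele_frequencies:
            table = allele_frequencies[locus.name]
            labels = list(table)
            probs = np.array([table[a] for a in labels], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{locus.name}: allele frequencies sum to {probs.sum()}, not 1")
            for lab in labels:
                locus.size_of(lab)  # must be a ladder allele
        else:
            labels = list(locus.designations)
            probs = np.full(len(labels), 1.0 / len(labels))
        a, b = (str(x) for x in rng.choice(labels, size=2, p=probs))
        calls[locus.name] = (a,) if a == b else tuple(
            sorted((a, b), key=locus.designations.index))
    return Genotype(calls=calls)
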