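# Methods

`strexpert` re-creates, at desk scale, the analysis chain of a rules-based
("expert system") STR genotyping instrument: raw multi-channel
capillary-electrophoresis fluorescence traces go in; sized, binned, and
quality-flagged allele calls come out, together with the validation
statistics a developmental-validation study reports. Because no instrument
data ship with the package, a physically motivated trace simulator defines
the test bed; this note records the model, its parameters, and the design
choices that were genuinely open.

## Trace model (simulator)

A run is a scan-indexed RFU table with one column per dye (three locus dyes
plus one internal-lane-standard dye in the bundled panel). For each
surviving allele copy set the simulator renders a Gaussian peak:

* **Mobility warp.** Fragment size s (bases) maps to scan position through a
  strictly increasing cubic, scan(s) = c0 + c1·s + c2·s² + c3·s³, default
  (200, 10, 1e-4, 1e-7). The default is deliberately near-linear so that an
  affine-in-size peak-width law and the cubic warp can jointly reproduce
  realistic resolution behaviour.
* **Peak width.** σ in scans is affine in size, σ(s) = max(1.2, −0.57 +
  0.01526·s). The floor keeps the shortest ILS fragments (60–100 bases)
  sampled by several scans. With the default warp this yields single-peak
  resolution R ≈ 1.6 near 140 bases falling to R ≈ 0.36 near 500 bases
  (see Resolution below).
* **Height.** height = height_scale · template_mass · copies ·
  exp(−degradation_rate · s) · imbalance, with height_scale = 6 RFU/pg,
  degradation_rate = 0.0015/base, and copies = 2 for a homozygote.
* **Heterozygote imbalance.** Each allele draws a lognormal multiplier
  exp(d·Z), Z ~ N(0,1), d = imbalance_dispersion = 0.27. The implied
  peak-height ratio is PHR = exp(−d√2·|Z|) with mean
  2·exp(c²/2)·Φ(−c) ≈ 0.76 for c = d√2 — the middle of the 0.7–0.8 band
  typical of low-DNA-content samples. The mean is continuous and strictly
  decreasing in d.
* **Stutter.** One artifact peak per surviving allele at one repeat unit
  below the parent. The stutter ratio is Normal, truncated at 0:
  mean 0.07, SD 0.015 for tetranucleotide loci; mean 0.02, SD 0.008 for
  pentanucleotide loci. Penta loci are included in real panels precisely
  because their stutter is very low, and at a 5-base repeat the stutter
  peak lands exactly in the adjacent allele bin, so modelling their stutter
  at tetranucleotide levels would manufacture spurious extra-allele flags.
  Forward (n+1) stutter is not modelled.
* **Dropout.** Each allele copy set survives independently with probability
  1 − p, p = 1 / (1 + (m/m50)^k) — logistic in log template mass — with
  m50 = 72 pg and k = 3. At the 500-pg default, p ≈ 0.3 %, giving mostly
  full profiles with occasional single-locus dropouts; at one tenth the
  default mass, p ≈ 75 %, giving sparse partial profiles with fewer than 10
  CODIS loci. m50 ≤ 0 disables dropout (the oracle regime).
* **Crosstalk, baseline, noise, saturation.** Pure dye signals are mixed
  through a square spectral matrix (default: 3 % adjacent-channel bleed),
  a slow two-cycle sinusoidal baseline (20 RFU) and white noise (SD 4 RFU)
  are added, and the result is clipped at 30,000 RFU.

All randomness flows from a single seed. The generator stream is consumed
in a fixed order — dropout uniforms for every allele slot first, then
imbalance, stutter, baseline phases, noise — so the stream does not depend
on which alleles survive. Two runs differing only in template mass
therefore share dropout uniforms, making the surviving-allele set (and so
the called-locus count) deterministically non-decreasing in mass for a
fixed seed. This common-random-numbers construction is what the sensitivity
monotonicity tests rely on.

The ladder run renders every ladder fragment of every locus at a fixed
1,200-RFU nominal height; the ILS (1,000 RFU) is present in every run.
`sample_genotype` draws genotypes per locus under Hardy–Weinberg, uniform
over ladder alleles unless a frequency table is supplied.

### What the simulator does not emulate

PCR kinetics, inhibition, mixtures of contributors, forward stutter,
minus-A artifacts, dye blobs and spikes, pull-up beyond linear crosstalk,
and inter-instrument variation. Tests passing against simulated traces
demonstrate that the analysis logic is self-consistent and correctly
recovers a known truth under the stated noise model — not that the system
would validate on real casework data.

## Analysis chain

1. **Baseline.** Per channel, a rolling 10th-percentile filter (window 201
   scans ≈ 20× a typical FWHM) estimates and subtracts the baseline. The
   estimator is robust to sparse peaks but carries a small slope-dependent
   offset on steeply drifting baselines; this offset is well below the
   analytical threshold and cancels in peak-height measurements, which are
   taken relative to the corrected local baseline.
2. **Color correction.** The known spectral matrix is inverted per scan
   (exact linear solve; singular matrices are rejected). Blind spectral
   estimation is out of scope.
3. **Peak detection.** Local maxima above the analytical threshold with
   FWHM ≥ 2 scans. Sub-scan apexes use log-parabolic (Gaussian)
   interpolation of the three samples around the maximum — exact for a
   noiseless Gaussian — falling back to an ordinary parabola when a sample
   is non-positive. Plateau maxima use the plateau midpoint; a plateau
   longer than 3 scans at the saturation ceiling marks the peak saturated.
   FWHM comes from interpolated half-height crossings.
4. **ILS evaluation.** Detected ILS-channel peaks are matched to the
   expected fragment sizes: an affine guess anchored on the outermost
   prominent peaks predicts fragment scans; each fragment greedily takes
   the nearest unused peak within 25 % of the local inter-fragment gap,
   monotonically; a cubic refit must leave every residual ≤ 0.25 bases.
   Any unmatched fragment, non-monotone assignment, or oversized residual
   fails the run with a named reason — failure is a status, not an
   exception, and no sizing is attempted on a failed ILS.
5. **Size calibration.** Default: least-squares cubic fitted in the
   size→scan direction and inverted by monotone root finding. Fitting in
   this direction makes the calibration exact when the true mobility is
   cubic (the inverse of a cubic is not a polynomial, so the conventional
   scan→size fit cannot be exact even on noise-free data). Residuals are
   reported per fragment in bases via the local slope. Classic Local
   Southern (two overlapping three-point reciprocal fits, averaged) is
   provided as an alternative. Sizes are carried as floats and reported to
   0.01 base; scans are 0-based.
6. **Bin calibration.** From a sized ladder run, every expected fragment
   must match a peak within the bin half-width (0.5 bases); observed sizes
   become bin centers. Missing or unexpected above-threshold fragments fail
   the ladder with the fragment named.
7. **Allele assignment.** A sample peak in a locus's dye channel and size
   span takes the designation of the bin containing its size, otherwise
   off-ladder (OL). Microvariant designations (e.g. 9.3) are opaque labels
   with explicit sizes; no arithmetic is done on them.
8. **Rules.** Fired in a fixed order: (i) height below the analytical
   threshold; (ii) stutter — a call one repeat unit (±0.5 bases) below a
   taller unflagged same-locus call at a height ratio ≤ the locus stutter
   threshold; (iii) PHR — for exactly two survivors, min/max height below
   the PHR threshold flags the weaker call (flagging the weaker rather than
   both is our choice); more than two survivors flags all for review.
   Flags annotate, never delete: flagged calls appear in the allele table
   and the plot but are excluded from the CODIS CMF export. A locus with
   at least one unflagged call is "called"; with only flagged calls,
   "flagged_only"; with none, "dropout". A profile is full / partial / fail
   as all / some / none of the panel loci are called, and carries the count
   of called CODIS core loci plus a ≥10-CODIS-loci searchability
   annotation.

### Thresholds

The rule thresholds are configuration, not published constants: analytical
threshold 100 RFU, PHR threshold 0.5, stutter threshold 0.15 (0.10 for
penta loci), bin half-width 0.5 bases. All live in the panel file and are
overridable. Amelogenin participates in profile completeness and in the
PHR rule, but is excluded from PHR statistics aggregation because X/Y
imbalance is sex-dependent rather than a measure of amplification balance.

## Validation metrics

* **Precision** — sample SD (n−1) of each ladder fragment's calibrated
  size across repeated injections; acceptance requires every fragment
  below 0.16 bases. Twenty default-noise injections give a maximum SD
  around 0.02 bases; the SD collapses to numerical zero as noise → 0.
* **Resolution** — R = Δsize / mean baseline width for a peak pair, with
  baseline width W_b = 2·FWHM/√(2 ln 2) = 4σ for a Gaussian; a lone peak is
  scored against a hypothetical equal-width twin one base away, R = 1/W_b.
  This baseline-width convention is our documented stand-in for the
  instrument literature's formula, which is not reproduced here; the
  simulator's width law is calibrated so R runs from ≈1.6 at 140 bases to
  ≈0.36 at 500 bases, comfortably above the 0.2 single-base-resolution
  floor everywhere in the 100–500-base range.
* **PHR statistics** — per-locus mean and SD over loci with a surviving
  heterozygous pair.
* **Concordance** — every reference allele designation is assessed; a
  matching unflagged call is concordant, a missing one is a dropout and
  counts discordant; an unflagged call absent from the reference is a
  drop-in, tallied outside the assessed denominator. A homozygous
  reference locus contributes one assessed designation. Percentages are
  reported to three decimals (e.g. 8091/8094 → 99.963 %).
* **Reproducibility** — a grid of per-sample status codes (Y full, Y*
  partial, F fail) tabulates to full/partial/fail counts; profiles =
  full + partial. The bundled 24×4 demonstration grid tabulates to
  91/4/1 → 95 profiles.
* **Sensitivity** — end-to-end Monte Carlo over a template-mass ladder
  (default 25–1000 pg), reporting mean called loci and category fractions
  per mass. The series is capped below detector saturation: above ~1 ng,
  homozygous peaks clip, acquire the saturated flag, and are excluded like
  any flagged call, so the called-locus count is only monotone in mass in
  the sub-saturation regime a dilution study actually probes.

## Problem sizes

Default study sizes are chosen to be statistically meaningful at desk
scale: 20 ladder injections for precision, 145 fragments in the 100–500
range for resolution, 50 samples for PHR aggregation, 100 random genotypes
for the noise-free oracle equivalence check, and 8–10 replicates per mass
for sensitivity. Each simulated run is ~6,500 scans × 4 channels.

## File formats

* **ABIF (.fsa)** — minimal big-endian v1.01 dialect: DATA 1..n as clipped
  int16 channels, DyeN/SMPL name strings, and two custom string tags (run
  kind, panel id). Read inverts write exactly on quantized traces;
  Biopython's ABIF parser reads the dialect (used as an independent oracle
  in the tests).
* **CODIS CMF XML** — a documented subset modelled on CMF 3.2
  (specimen / locus / allele elements), validated against a bundled XSD;
  fail-category profiles produce a zero-locus document with a status
  attribute. Full CODIS schema compliance is out of scope.
* **Panel config** — JSON or YAML; the bundled PowerPlex-16-style fixture
  defines 16 loci on three dyes, a 20-fragment 60–600-base ILS on the
  fourth, and exactly 210 ladder fragments (the public ladder composition
  padded by five fragments, as documented in the fixture itself; nominal
  sizes are idealized, not vendor lot values).
* **Allele table** — RFC-4180 CSV with sample, locus, allele, size,
  height, flags; contains every call including flagged ones.

## Known limitations

The ILS matcher anchors on the outermost prominent peaks, so a tall
spurious peak outside the ILS span could mislead it; spurs between
fragments are handled. Commercial expert systems do not publish their
conditioning internals, so this chain is a documented, self-contained
design rather than a reconstruction of any vendor's.
Concordance counting conventions (homozygote = one assessed designation)
are stated here because published tallies rarely state theirs. Simulated
validation numbers characterize this implementation under this noise
model only.
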