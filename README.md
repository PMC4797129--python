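# strexpert

Expert-system STR electropherogram analysis at desk scale: a synthetic
capillary-electrophoresis trace simulator plus the full rules-based
genotyping chain — signal conditioning, internal-lane-standard sizing,
allelic-ladder-calibrated allele calling, quality flagging — and the
developmental-validation metrics used to qualify such systems.

**Who it is for.** Forensic-genetics and bioinformatics developers who want
to prototype, test, or teach STR allele-calling logic without instrument
data. Everything runs from a seed: traces, ladders, genotypes, and the
validation studies are fully reproducible.

## The problem and the model

Short tandem repeat (STR) profiling separates PCR-amplified fragments by
capillary electrophoresis; the raw output is a scan-indexed fluorescence
trace per dye. Turning that into a CODIS-ready genotype takes a chain of
steps, each with failure modes an automated ("expert") system must handle
without a human analyst:

1. **Condition** the trace: set the baseline to zero (rolling-percentile
   estimate) and undo spectral crosstalk between dyes (per-scan linear
   solve against the known mixing matrix).
2. **Size** the peaks: match the internal lane standard (ILS) against its
   expected fragments under strict criteria, fit a monotone scan→size
   calibration (least-squares cubic, or Local Southern), and convert every
   peak apex to bases.
3. **Call** alleles: calibrate per-allele bins from an allelic-ladder run,
   assign designations by bin membership (off-ladder otherwise), then fire
   the quality rules in order — analytical threshold (peak height),
   stutter filter (a peak one repeat unit below a parent at ≤ the stutter
   ratio), and heterozygote peak-height ratio PHR = min(h)/max(h).
   Flags annotate rather than delete: flagged peaks stay in the allele
   table and plots but never enter the CODIS CMF XML export.
4. **Validate**: sizing precision (per-fragment SD across injections,
   acceptance < 0.16 bases), resolution R = Δsize / baseline width
   (single-base resolution needs R > 0.2 across 100–500 bases), per-locus
   PHR statistics, allele concordance against reference genotypes, and a
   template-mass sensitivity curve.

The bundled demonstration panel is PowerPlex-16-style: 16 loci (13 CODIS
core + two pentanucleotide loci + Amelogenin) on three dye channels, a
20-fragment 60–600-base ILS on the fourth, and an allelic ladder totalling
exactly 210 fragments. The simulator renders Gaussian peaks on a cubic
mobility warp with heterozygote imbalance, n−1 stutter, exponential
size-dependent degradation, logistic-in-log-mass allele dropout, spectral
crosstalk, baseline drift, noise, and detector saturation. See
`docs/methods.md` for the model and every default.

## Worked example

```bash
python examples/simulate_and_call.py
```

simulates a ladder and one 500-pg sample, analyzes both end to end, and
prints (abridged):

```
profile category: full  (CODIS loci called: 13)
    locus      truth     called  flagged-as-artifact
  D3S1358      17/19      17/19  16(stutter_filtered), 18(stutter_filtered)
     TH01       6/10       6/10  5(stutter_filtered), 9(stutter_filtered)
   D18S51       8/23       8/23  22(stutter_filtered)
     AMEL        X/Y          Y  X(phr_imbalance)
      ...
concordance vs truth: 30/31 alleles = 96.774%
```

Every locus is called and matches the simulated truth; the stutter rule
has caught the one-repeat-below artifact peaks, and one Amelogenin allele
drew an extreme height imbalance and was flagged for review — so it is
excluded from the CODIS export and counted against concordance, which is
exactly what an expert system should do with it. `examples/
validation_metrics.py` prints the headline validation numbers
(precision max SD ≈ 0.02 bases over 210 fragments; R from ≈2.0 at 106
bases to ≈0.38 at 479 bases; 8091/8094 = 99.963 %; the 24×4
reproducibility grid → 91 full / 4 partial / 1 fail), and
`examples/sensitivity_study.py` shows full profiles at high template mass
degrading to sparse partials below ~100 pg.

There is also a thin CLI:

```bash
strexpert simulate --out sim/ --seed 1 --n-samples 4   # .fsa files + truth.csv
strexpert analyze --ladder sim/ladder.fsa --out results/ sim/sample_*.fsa
strexpert validate --out reports/ --seed 1             # validation suite
strexpert demo                                          # end-to-end example
```

`analyze` writes the four expert-system outputs per sample: the allele
table CSV (all calls, flags included), a CODIS CMF-subset XML (passing
calls only), an electropherogram PNG with flagged peaks boxed in red, and
reads/writes ABIF `.fsa` traces throughout.

## Layout

```
src/strexpert/      panel, simulate, signal, sizing, calling, pipeline,
                    metrics, validation, io_formats, cli (+ bundled panel,
                    CMF schema subset, and status-grid fixtures in data/)
tests/              unit, property, and system-level pytest suite
examples/           narrative scripts, one per capability
scripts/            acceptance.py (validation statistics recomputation)
docs/methods.md     model, assumptions, parameters, design decisions
```
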