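"""Simulation-based validation suite: one call runs every study and writes
CSV tables plus PNG summary plots (per-fragment precision bars, resolution
vs size, per-locus PHR bars, sensitivity curve)."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from . import metrics
from .panel import PanelDefinition
from .pipeline import analyze_sample, calibrate_from_ladder
from .simulate import SimulationParams, sample_genotype, simulate_ladder_run, \
    simulate_sample

__all__ = ["run_validation"]

#: default template-mass series for the sensitivity study, pg; capped below
#: detector saturation (above ~1 ng homozygous peaks clip and get flagged)
SENSITIVITY_MASSES = (25.0, 50.0, 100.0, 150.0, 250.0, 500.0, 1000.0)


def _save_fig(fig: Figure, path: Path) -> None:
    FigureCanvasAgg(fig).print_png(str(path))


def run_validation(panel: PanelDefinition, outdir: Path, seed: int = 0,
                   n_ladders: int = 20, n_samples: int = 20,
                   n_reps: int = 10,
                   masses: tuple[float, ...] = SENSITIVITY_MASSES) -> dict:
    """Run precision, resolution, PHR, concordance, and sensitivity studies.

    Returns a JSON-serializable summary; detailed tables and plots land in
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(4)]
    base = SimulationParams()

    # Precision: repeated ladder injections at default noise
    prec = metrics.precision_study(panel, n_runs=n_ladders, seed=seeds[0])
    prec_df = prec.to_frame()
    prec_df.to_csv(outdir / "precision.csv", index=False)
    fig = Figure(figsize=(12, 3.5))
    ax = fig.subplots()
    ax.bar(range(len(prec_df)), prec_df["sd_bases"], width=0.9)
    ax.axhline(prec.bound, color="red", ls="--", lw=1,
               label=f"acceptance bound {prec.bound:g}")
    ax.set_xlabel("ladder fragment")
    ax.set_ylabel("size SD (bases)")
    ax.legend()
    _save_fig(fig, outdir / "precision.png")

    # Resolution: noise-free sweep across the sizing range
    res = metrics.resolution_sweep(panel)
    res_df = res.to_frame()
    res_df.to_csv(outdir / "resolution.csv", index=False)
    fig = Figure(figsize=(7, 4))
    ax = fig.subplots()
    ax.plot(res_df["size_bases"], res_df["R"], "o-", ms=3)
    ax.axhline(0.2, color="red", ls="--", lw=1, label="single-base bound 0.2")
    ax.set_xlabel("fragment size (bases)")
    ax.set_ylabel("R")
    ax.legend()
    _save_fig(fig, outdir / "resolution.png")

    # PHR + concordance over simulated samples at default template mass
    ladder = simulate_ladder_run(panel, replace(base, seed=seeds[1]))
    bins = calibrate_from_ladder(ladder, panel)
    geno_rng = np.random.default_rng(seeds[2])
    sample_seeds = [int(s.generate_state(1)[0] % 2**31)
                    for s in np.random.SeedSequence(seeds[3]).spawn(n_samples)]
    profiles, tally = [], None
    for i in range(n_samples):
        genotype = sample_genotype(panel, seed=geno_rng)
        trace = simulate_sample(genotype, panel,
                                replace(base, seed=sample_seeds[i]),
                                sample_id=f"val_{i:03d}")
        result = analyze_sample(trace, bins, panel)
        profiles.append(result.profile)
        t = metrics.concordance(result.profile, genotype)
        tally = t if tally is None else tally + t
    phr_df = metrics.phr_report(profiles)
    phr_df.to_csv(outdir / "phr.csv", index=False)
    if len(phr_df):
        fig = Figure(figsize=(9, 4))
        ax = fig.subplots()
        ax.bar(phr_df["locus"], phr_df["mean_phr"],
               yerr=phr_df["sd_phr"].fillna(0), capsize=3)
        ax.set_ylabel("mean PHR")
        ax.set_ylim(0, 1.05)
        ax.tick_params(axis="x", rotation=60)
        _save_fig(fig, outdir / "phr.png")

    # Sensitivity: mass series, end-to-end Monte Carlo
    sens = metrics.sensitivity_curve(list(masses), n_reps, panel, base,
                                     seed=seeds[3])
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    fig = Figure(figsize=(7, 4))
    ax = fig.subplots()
    ax.plot(sens["template_mass_pg"], sens["mean_called_loci"], "o-")
    ax.set_xscale("log")
    ax.set_xlabel("template mass (pg)")
    ax.set_ylabel("mean called loci")
    ax2 = ax.twinx()
    ax2.plot(sens["template_mass_pg"], sens["frac_full"], "s--",
             color="tab:green", label="full fraction")
    ax2.set_ylabel("full-profile fraction")
    _save_fig(fig, outdir / "sensitivity.png")

    return {
        "precision_max_sd_bases": prec.max_sd,
        "precision_pass": bool(prec.passed),
        "resolution_min_r": res.min_r,
        "phr_overall_mean": (float(np.average(phr_df["mean_phr"],
                                              weights=phr_df["n"]))
                             if len(phr_df) else None),
        "concordance_percent": tally.percent_concordant if tally else None,
        "concordance_assessed": tally.n_assessed if tally else 0,
        "sensitivity_full_fraction_at_max_mass": float(sens["frac_full"].iloc[-1]),
    }
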