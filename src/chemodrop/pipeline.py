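"""End-to-end in-silico chemotaxis-sorting experiments and stats-only analysis.

A scenario run executes the device stages in order, for a control condition
(no chemoeffector) and an exposed condition (gradient on):

  gradient -> chemotactic sorting -> hydraulic dilution at the droplet
  generator -> Poisson encapsulation -> incubation/trace synthesis ->
  segmentation + classification + fluorescence gating -> occupancy tallies
  -> lambda estimates, dual-label deconvolution, enrichment factor.

Everything is driven by one ``RunConfig`` and one root seed, split per stage
through ``numpy.random.SeedSequence`` so a fixed config reproduces every
number bit-identically and individual stages can be re-run.

``analyze_counts`` is the stats-only entry point: it reproduces the lambda
and enrichment arithmetic directly from a tally table, no simulation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .gradient import (
    ChannelGeometry,
    FlowConfig,
    FLUORESCEIN_D_CM2_S,
    GradientField,
    solve_steady_gradient,
)
from .occupancy import (
    EnrichmentResult,
    LambdaEstimate,
    OccupancyCount,
    deconvolve_dual_label,
    empty_fraction,
    enrichment_factor,
    estimate_lambda,
    round_sig,
    single_cell_given_growth,
)
from .synth import SpeciesParams, TraceParams, encapsulate, simulate_sorting, synth_trace
from .traces import Trace, classify_segments, fluorescence_gate, segment_trace, tally_segments

__all__ = [
    "RunConfig",
    "ConditionResult",
    "RunResult",
    "scenario_config",
    "run_scenario",
    "analyze_counts",
    "reference_targets",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterisation of one in-silico sorting + cultivation run."""

    species: list[SpeciesParams]
    densities_cfu_per_ml: list[float]
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    flow: FlowConfig = field(default_factory=FlowConfig)
    diffusivity_cm2_s: float = FLUORESCEIN_D_CM2_S
    inlet_concentrations: tuple[float, float, float] = (0.0, 0.0, 1.0)
    q_media_ul_min: float = 0.3
    volume_nl: float = 13.0
    n_droplets: int = 500
    n_cells: int = 3000
    trace: TraceParams = field(default_factory=TraceParams)
    conf: float = 0.95
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.densities_cfu_per_ml):
            raise ValueError("one density per species required")
        if self.n_droplets <= 0 or self.n_cells <= 0:
            raise ValueError("n_droplets and n_cells must be positive")
        if self.q_media_ul_min < 0:
            raise ValueError("media flow must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = [dataclasses.asdict(s) for s in self.species]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesParams(**s) for s in raw.pop("species")]
        for key, typ in (
            ("geometry", ChannelGeometry),
            ("flow", FlowConfig),
            ("trace", TraceParams),
        ):
            if key in raw:
                raw[key] = typ(**raw[key])
        if "inlet_concentrations" in raw:
            raw["inlet_concentrations"] = tuple(raw["inlet_concentrations"])
        return cls(species=species, **raw)


@dataclass
class ConditionResult:
    """Per-condition outcome with full provenance back to its tally."""

    condition: str
    sorting_fractions: dict[str, float]
    generator_densities: dict[str, float]
    counts: OccupancyCount
    lambda_growth: LambdaEstimate
    lambda_ref: LambdaEstimate | None = None
    lambda_target: LambdaEstimate | None = None


@dataclass
class RunResult:
    conditions: dict[str, ConditionResult]
    enrichment: EnrichmentResult | None
    enrichment_ci: tuple[float, float] | None
    provenance: dict

    def to_dict(self) -> dict:
        def est(e: LambdaEstimate | None) -> dict | None:
            if e is None:
                return None
            return {
                "lambda_hat": e.lambda_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "occupied_fraction": e.occupied_fraction,
                "n_total": e.n_total,
            }

        out: dict = {"conditions": {}, "provenance": self.provenance}
        for name, c in self.conditions.items():
            out["conditions"][name] = {
                "sorting_fractions": c.sorting_fractions,
                "generator_densities_cfu_per_ml": c.generator_densities,
                "counts": {
                    "n_total": c.counts.n_total,
                    "n_growth": c.counts.n_growth,
                    "n_fluor": c.counts.n_fluor,
                    "n_growth_nonfluor": c.counts.n_growth_nonfluor,
                },
                "lambda_growth": est(c.lambda_growth),
                "lambda_ref": est(c.lambda_ref),
                "lambda_target": est(c.lambda_target),
            }
        if self.enrichment is not None:
            out["enrichment"] = dataclasses.asdict(self.enrichment)
            out["enrichment_ci"] = list(self.enrichment_ci)
        return out


def _generator_density(
    d_inlet: float, collected_fraction: float, flow: FlowConfig, q_media: float
) -> float:
    """Cell density at the droplet generator after sorting and media dilution.

    Cells enter through the middle inlet at ``d_inlet``; a fraction of them is
    routed to the collection outlet, whose stream (total minus waste flow)
    is then merged with culture media at the T-junction.
    """
    q_collect = flow.q_total - flow.q_waste_outlet
    if q_collect <= 0:
        raise ValueError("no collection flow: waste outlet swallows everything")
    return d_inlet * flow.q_middle * collected_fraction / (q_collect + q_media)


def _run_condition(
    config: RunConfig,
    condition: str,
    inlet_concentrations: tuple[float, float, float],
    seeds: list[int],
    outdir: Path | None,
) -> ConditionResult:
    t0 = time.perf_counter()
    gradient = solve_steady_gradient(
        config.geometry,
        config.flow,
        config.diffusivity_cm2_s,
        inlet_concentrations=inlet_concentrations,
    )
    sorting = simulate_sorting(gradient, config.species, config.n_cells, seed=seeds[0])
    fractions = {name: r.fraction for name, r in sorting.items()}
    densities = {
        sp.name: _generator_density(d, fractions[sp.name], config.flow, config.q_media_ul_min)
        for sp, d in zip(config.species, config.densities_cfu_per_ml)
    }
    droplets = encapsulate(
        config.species,
        [densities[sp.name] for sp in config.species],
        config.volume_nl,
        config.n_droplets,
        seed=seeds[1],
    )
    synth = synth_trace(droplets, config.trace, seed=seeds[2])
    bright = Trace(synth.bright, synth.sample_rate)
    fluor = Trace(synth.fluor, synth.sample_rate)
    segments = segment_trace(bright)
    cls = classify_segments(segments)
    dual = any(sp.labelled for sp in config.species)
    if dual:
        flags = fluorescence_gate(cls.segments, fluor)
        counts = tally_segments(cls.segments, flags)
    else:
        counts = tally_segments(cls.segments)
    lam_growth = estimate_lambda(counts, "n_growth", config.conf)
    lam_ref = lam_target = None
    if dual:
        lam_ref, lam_target = deconvolve_dual_label(counts, config.conf)
    logger.info(
        "condition=%s seeds=%s n_segments=%d n_growth=%d lambda=%.4f elapsed=%.2fs",
        condition,
        seeds,
        len(segments),
        counts.n_growth,
        lam_growth.lambda_hat,
        time.perf_counter() - t0,
    )
    if outdir is not None:
        cdir = outdir / condition
        cdir.mkdir(parents=True, exist_ok=True)
        cio.write_field_csv(cdir / "gradient_field.csv", gradient)
        cio.write_droplets_csv(
            cdir / "droplets.csv", droplets, [sp.name for sp in config.species]
        )
        cio.write_trace_csv(cdir / "trace.csv", bright, fluor)
        cio.write_segments_csv(cdir / "segments.csv", cls.segments)
        cio.write_plate_manifest_csv(cdir / "plate_manifest.csv", cls.segments)
    return ConditionResult(
        condition=condition,
        sorting_fractions=fractions,
        generator_densities=densities,
        counts=counts,
        lambda_growth=lam_growth,
        lambda_ref=lam_ref,
        lambda_target=lam_target,
    )


def _conservative_factor_ci(
    t_b: LambdaEstimate, r_b: LambdaEstimate, t_a: LambdaEstimate, r_a: LambdaEstimate
) -> tuple[float, float]:
    def safe_div(a: float, b: float) -> float:
        return a / b if b > 0 else float("inf")

    lo = safe_div(safe_div(t_a.ci_low, r_a.ci_high), safe_div(t_b.ci_high, r_b.ci_low))
    hi = safe_div(safe_div(t_a.ci_high, r_a.ci_low), safe_div(t_b.ci_low, r_b.ci_high))
    if not np.isfinite(hi):
        hi = float("inf")
    return (max(lo, 0.0), hi)


def run_scenario(config: RunConfig, exposed_gradient: bool = True) -> RunResult:
    """Run control and exposed conditions and compute the enrichment factor.

    ``exposed_gradient=False`` makes the exposed condition a second
    zero-gradient run (the null control: the factor should then sit at 1
    within confidence limits).
    """
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s) for s in ss.generate_state(6) % (2**31)]
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        echo = config.to_dict()
        (outdir / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))

    zero = (0.0, 0.0, 0.0)
    exposed_inlets = config.inlet_concentrations if exposed_gradient else zero
    try:
        control = _run_condition(config, "control", zero, stage_seeds[:3], outdir)
        exposed = _run_condition(config, "exposed", exposed_inlets, stage_seeds[3:], outdir)
    except Exception as exc:  # annotate with stage context for debuggability
        raise RuntimeError(f"scenario failed ({exc}); config={config.to_dict()}") from exc

    enrich = enrich_ci = None
    if all(
        e is not None and e.lambda_hat > 0
        for e in (control.lambda_target, control.lambda_ref, exposed.lambda_target, exposed.lambda_ref)
    ):
        enrich = enrichment_factor(
            (control.lambda_target.lambda_hat, control.lambda_ref.lambda_hat),
            (exposed.lambda_target.lambda_hat, exposed.lambda_ref.lambda_hat),
        )
        enrich_ci = _conservative_factor_ci(
            control.lambda_target, control.lambda_ref, exposed.lambda_target, exposed.lambda_ref
        )

    result = RunResult(
        conditions={"control": control, "exposed": exposed},
        enrichment=enrich,
        enrichment_ci=enrich_ci,
        provenance={
            "seed": config.seed,
            "stage_seeds": stage_seeds,
            "exposed_gradient": exposed_gradient,
            "n_cells": config.n_cells,
            "n_droplets": config.n_droplets,
        },
    )
    if outdir is not None:
        cio.write_results_json(outdir / "results.json", result.to_dict())
    return result


# ---------------------------------------------------------------------------
# bundled scenarios


def scenario_config(name: str, seed: int = 0, output_dir: str | None = None) -> tuple[RunConfig, bool]:
    """Bundled scenario configs; returns (config, exposed_gradient).

    * ``rp437_vs_rp1616`` — chemotactic wild type against its non-chemotactic
      cheZ-deletion mutant (modelled as the labelled reference), aspartate-like
      gradient, 13 nL droplets.
    * ``cnb1_mixture`` — non-labelled chemotactic target in a 1:10 mixture
      with an RFP-tagged reference that barely responds to the aromatic
      chemoeffector; waste flow raised to 0.30 uL/min to trim the reference.
    * ``null_control`` — the mixture with no gradient in either run.
    """
    # waste flow at 0.30 uL/min puts the splitting streamline above the cell
    # stream, so passive cells are mostly discarded and collection demands
    # active up-gradient migration — the stringent-sorting setting
    stringent = FlowConfig(q_side_each=0.25, q_middle=0.025, q_waste_outlet=0.30)
    if name == "rp437_vs_rp1616":
        cfg = RunConfig(
            species=[
                SpeciesParams(name="RP437", chemotactic_sensitivity=1.0, labelled=False),
                SpeciesParams(name="RP1616", chemotactic_sensitivity=0.0, labelled=True),
            ],
            densities_cfu_per_ml=[3.2e5, 3.2e5],
            flow=stringent,
            volume_nl=13.0,
            n_droplets=800,
            seed=seed,
            output_dir=output_dir,
        )
        return cfg, True
    if name in ("cnb1_mixture", "null_control"):
        cfg = RunConfig(
            species=[
                SpeciesParams(name="CNB-1", chemotactic_sensitivity=1.0, labelled=False),
                SpeciesParams(name="RP437-RFP", chemotactic_sensitivity=0.1, labelled=True),
            ],
            densities_cfu_per_ml=[6.0e5, 1.3e6],
            flow=stringent,
            volume_nl=5.5,
            n_droplets=800,
            seed=seed,
            output_dir=output_dir,
        )
        return cfg, name == "cnb1_mixture"
    raise ValueError(f"unknown scenario {name!r}; pick one of {sorted(SCENARIOS)}")


SCENARIOS = ("rp437_vs_rp1616", "cnb1_mixture", "null_control")


# ---------------------------------------------------------------------------
# stats-only entry point


def analyze_counts(counts: "pd.DataFrame | str | Path", conf: float = 0.95) -> dict:
    """Lambda estimates, ratios and enrichment factors from a tally table.

    The table needs columns ``condition, n_total, n_growth`` and optionally
    ``n_fluor, n_growth_nonfluor`` (dual-label rows).  The first dual-label
    row is taken as the baseline; an enrichment factor is reported for every
    later dual-label row against it.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = cio.read_counts_csv(counts)
    results: dict = {"conditions": {}, "enrichment": {}}
    ratios: list[tuple[str, LambdaEstimate, LambdaEstimate]] = []
    for _, row in counts.iterrows():
        cond = str(row["condition"])
        has_dual = (
            "n_fluor" in row.index
            and "n_growth_nonfluor" in row.index
            and pd.notna(row["n_fluor"])
            and pd.notna(row["n_growth_nonfluor"])
        )
        oc = OccupancyCount(
            n_total=int(row["n_total"]),
            n_growth=int(row["n_growth"]),
            n_fluor=int(row["n_fluor"]) if has_dual else None,
            n_growth_nonfluor=int(row["n_growth_nonfluor"]) if has_dual else None,
        )
        entry: dict = {}
        lam = estimate_lambda(oc, "n_growth", conf)
        entry["lambda_growth"] = {
            "lambda_hat": lam.lambda_hat,
            "ci_low": lam.ci_low,
            "ci_high": lam.ci_high,
        }
        if has_dual:
            ref, target = deconvolve_dual_label(oc, conf)
            entry["lambda_ref"] = ref.lambda_hat
            entry["lambda_target"] = target.lambda_hat
            if ref.lambda_hat > 0:
                entry["ratio_target_ref"] = target.lambda_hat / ref.lambda_hat
            ratios.append((cond, target, ref))
        results["conditions"][cond] = entry
    if len(ratios) >= 2:
        base_cond, base_t, base_r = ratios[0]
        for cond, t, r in ratios[1:]:
            res = enrichment_factor(
                (base_t.lambda_hat, base_r.lambda_hat), (t.lambda_hat, r.lambda_hat)
            )
            results["enrichment"][f"{cond}_vs_{base_cond}"] = res.enrichment_factor
    return results


# ---------------------------------------------------------------------------
# reference quantities


def reference_targets(seed: int = 0) -> dict:
    """Recompute the study's printed summary statistics from its printed fractions.

    Every value is produced by running the package's estimators on tallies
    equivalent to the printed droplet fractions (denominator 1000); nothing
    is hard-coded beyond those input fractions.  ``seed`` is accepted for
    interface uniformity; these quantities are deterministic.
    """
    del seed
    n = 1000

    def lam_of(k: int) -> LambdaEstimate:
        return estimate_lambda(OccupancyCount(n_total=n, n_growth=k))

    out: dict = {}
    # pure-culture chemotaxis: growth fraction 90.0% and 1.5%
    out["t1"] = {"value": round(lam_of(900).lambda_hat, 2), "n": n}
    out["t2"] = {"value": round_sig(lam_of(15).lambda_hat, 2), "n": n}

    # mixture, pre-exposure: 8.0% fluorescent, 3.6% growth-only-nonfluorescent
    before = OccupancyCount(n_total=n, n_growth=80 + 36, n_fluor=80, n_growth_nonfluor=36)
    ref_b, target_b = deconvolve_dual_label(before)
    out["t3"] = {"value": round(target_b.lambda_hat / ref_b.lambda_hat, 2), "n": n}

    # mixture, post-exposure: 1.7% fluorescent, 27.1% total growth
    after = OccupancyCount(n_total=n, n_growth=271, n_fluor=17, n_growth_nonfluor=271 - 17)
    ref_a, target_a = deconvolve_dual_label(after)
    out["t5"] = {"value": round_sig(ref_a.lambda_hat, 2), "n": n}
    out["t6"] = {"value": round(target_a.lambda_hat, 3), "n": n}

    enrich = enrichment_factor(
        (target_b.lambda_hat, ref_b.lambda_hat), (target_a.lambda_hat, ref_a.lambda_hat)
    )
    out["t7"] = {"value": enrich.enrichment_factor, "n": n}

    # single-cell design point at lambda = 0.1
    out["t8"] = {"value": round(100.0 * single_cell_given_growth(0.1)), "n": 1}
    out["t9"] = {"value": 100.0 * empty_fraction(0.1), "n": 1}
    return out
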