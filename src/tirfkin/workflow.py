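"""End-to-end orchestration: simulate/load -> image pipeline -> pulses ->
partitions -> statistics, with a run manifest for reproducibility.

Two entry points mirror the two assay modes:

* :func:`run_endpoint` — single-snapshot colocalization: detect spots in the
  DNA and protein snapshots and score the fraction of DNA templates with a
  protein spot within the match radius.
* :func:`run_timelapse` — the full residence-lifetime pipeline, from movie
  (real or simulated) to survival curves and off-rates.

All statistics are reproducible from the pulse CSV alone:
:func:`compute_statistics` consumes pulses, so a skip-imaging re-run on a
saved pulse table yields identical numbers to the image-path run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    ImageStack,
    SpotMap,
    ThresholdPolicy,
    Trace,
    apply_drift_correction,
    detect_dna_spots,
    estimate_drift,
    extract_traces,
    traces_to_frame,
)
from .kinetics import (
    RateEstimate,
    SurvivalCurve,
    TestResult,
    estimate_offrate,
    km_estimate,
    logrank_test,
)
from .pulses import (
    BinarizationPolicy,
    Pulse,
    pulses_from_frame,
    pulses_from_trace,
    pulses_to_frame,
)
from .residence import (
    ColocalizationResult,
    ResidencePartition,
    arrival_proportions,
    endpoint_colocalization,
    occupancy_fraction,
    partition_residences,
    partitions_to_frame,
    residences_per_spot,
)
from .schedule import AcquisitionSchedule
from .simulate import (
    DriftSpec,
    GroundTruth,
    SimulationParams,
    SpeciesKinetics,
    read_movie,
    render_movie,
    simulate_pulse_trains,
)

__all__ = ["RunConfig", "TimelapseResult", "run_endpoint", "run_timelapse",
           "compute_statistics", "pipeline_pulses"]


@dataclass
class RunConfig:
    """Every knob of the pipeline in one serializable object.

    Either ``simulation`` (generate the movie) or ``input_dir`` (read TIFFs
    written by :func:`tirfkin.simulate.write_movie`) must be set.
    """

    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    simulation: SimulationParams | None = None
    input_dir: str | None = None
    dna_channel: str = "647"
    focal_channel: str = "488"
    partner_channel: str = "561"
    drift_method: str = "auto"
    threshold_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    size_range: tuple[float, float] = (2, 30)
    min_persistency: float = 0.5
    link_radius: float = 2.0
    aperture_radius: float = 3.0
    bg_annulus: tuple[float, float] = (5.0, 8.0)
    binarization: BinarizationPolicy = field(default_factory=BinarizationPolicy)
    co_arrival_window: float = 5.0
    match_radius: float = 2.0
    short_cut: float = 120.0
    long_cut: float = 300.0
    seed: int = 0
    outdir: str | None = None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "schedule": self.schedule.to_dict(),
            "dna_channel": self.dna_channel,
            "focal_channel": self.focal_channel,
            "partner_channel": self.partner_channel,
            "drift_method": self.drift_method,
            "threshold_policy": dataclasses.asdict(self.threshold_policy),
            "size_range": list(self.size_range),
            "min_persistency": self.min_persistency,
            "link_radius": self.link_radius,
            "aperture_radius": self.aperture_radius,
            "bg_annulus": list(self.bg_annulus),
            "binarization": dataclasses.asdict(self.binarization),
            "co_arrival_window": self.co_arrival_window,
            "match_radius": self.match_radius,
            "short_cut": self.short_cut,
            "long_cut": self.long_cut,
            "seed": self.seed,
            "input_dir": self.input_dir,
            "outdir": self.outdir,
        }
        if self.simulation is not None:
            s = self.simulation
            d["simulation"] = {
                "n_spots": s.n_spots,
                "field_size": list(s.field_size),
                "pixel_size": s.pixel_size,
                "spot_min_separation": s.spot_min_separation,
                "kinetics": {
                    ch: dataclasses.asdict(k) for ch, k in s.kinetics.items()
                },
                "psf_sigma": s.psf_sigma,
                "spot_amplitude": s.spot_amplitude,
                "dna_amplitude": s.dna_amplitude,
                "background_mean": s.background_mean,
                "noise_model": s.noise_model,
                "gaussian_noise_sigma": s.gaussian_noise_sigma,
                "drift": {
                    "velocity": list(s.drift.velocity),
                    "wobble_amplitude": s.drift.wobble_amplitude,
                    "wobble_period": s.drift.wobble_period,
                },
                "initial_occupancy": s.initial_occupancy,
                "edge_margin": s.edge_margin,
                "seed": s.seed,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = None
        if d.get("simulation"):
            s = d["simulation"]
            sim = SimulationParams(
                n_spots=int(s["n_spots"]),
                field_size=tuple(s["field_size"]),
                pixel_size=float(s["pixel_size"]),
                spot_min_separation=float(s["spot_min_separation"]),
                kinetics={
                    ch: SpeciesKinetics(**k) for ch, k in s["kinetics"].items()
                },
                psf_sigma=float(s["psf_sigma"]),
                spot_amplitude=float(s["spot_amplitude"]),
                dna_amplitude=s.get("dna_amplitude"),
                background_mean=float(s["background_mean"]),
                noise_model=s["noise_model"],
                gaussian_noise_sigma=float(s["gaussian_noise_sigma"]),
                drift=DriftSpec(
                    velocity=tuple(s["drift"]["velocity"]),
                    wobble_amplitude=float(s["drift"]["wobble_amplitude"]),
                    wobble_period=float(s["drift"]["wobble_period"]),
                ),
                initial_occupancy=float(s["initial_occupancy"]),
                edge_margin=float(s["edge_margin"]),
                seed=int(s["seed"]),
            )
        return cls(
            schedule=AcquisitionSchedule.from_dict(d["schedule"]),
            simulation=sim,
            input_dir=d.get("input_dir"),
            dna_channel=d.get("dna_channel", "647"),
            focal_channel=d.get("focal_channel", "488"),
            partner_channel=d.get("partner_channel", "561"),
            drift_method=d.get("drift_method", "auto"),
            threshold_policy=ThresholdPolicy(**d.get("threshold_policy", {})),
            size_range=tuple(d.get("size_range", (2, 30))),
            min_persistency=float(d.get("min_persistency", 0.5)),
            link_radius=float(d.get("link_radius", 2.0)),
            aperture_radius=float(d.get("aperture_radius", 3.0)),
            bg_annulus=tuple(d.get("bg_annulus", (5.0, 8.0))),
            binarization=BinarizationPolicy(**d.get("binarization", {})),
            co_arrival_window=float(d.get("co_arrival_window", 5.0)),
            match_radius=float(d.get("match_radius", 2.0)),
            short_cut=float(d.get("short_cut", 120.0)),
            long_cut=float(d.get("long_cut", 300.0)),
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TimelapseResult:
    """Everything the time-lapse pipeline produces for one run."""

    spots: SpotMap
    traces: dict[str, list[Trace]]
    pulses: dict[str, list[Pulse]]
    partitions: list[ResidencePartition]
    rates: dict[str, RateEstimate | None]
    survival: dict[str, SurvivalCurve | None]
    logrank: TestResult | None
    summary: dict
    truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# stages

def _obtain_stacks(
    config: RunConfig,
) -> tuple[dict[str, ImageStack], GroundTruth | None]:
    if config.simulation is not None:
        truth = simulate_pulse_trains(config.simulation, config.schedule)
        raw = render_movie(truth, config.simulation, config.schedule)
        px = config.simulation.pixel_size
        stacks = {
            ch: ImageStack(ch, arr, config.schedule.frame_times(ch), px)
            for ch, arr in raw.items()
        }
        return stacks, truth
    if config.input_dir is None:
        raise ValueError("config must provide simulation params or an input_dir")
    raw, schedule, px = read_movie(config.input_dir)
    stacks = {
        ch: ImageStack(ch, arr, schedule.frame_times(ch), px)
        for ch, arr in raw.items()
    }
    return stacks, None


def pipeline_pulses(
    config: RunConfig,
) -> tuple[SpotMap, dict[str, list[Trace]], dict[str, list[Pulse]], GroundTruth | None]:
    """Movie -> drift-corrected stacks -> spots -> traces -> pulses."""
    stacks, truth = _obtain_stacks(config)
    if config.dna_channel not in stacks:
        raise ValueError(f"missing DNA channel {config.dna_channel!r}")
    drift = estimate_drift(stacks[config.dna_channel], method=config.drift_method)
    corrected = {ch: apply_drift_correction(st, drift) for ch, st in stacks.items()}
    spots = detect_dna_spots(
        corrected[config.dna_channel],
        threshold_policy=config.threshold_policy,
        size_range=config.size_range,
        min_persistency=config.min_persistency,
        link_radius=config.link_radius,
    )
    traces: dict[str, list[Trace]] = {}
    pulses: dict[str, list[Pulse]] = {}
    for ch, st in corrected.items():
        if ch == config.dna_channel:
            continue
        trs = extract_traces(
            st, spots, aperture_radius=config.aperture_radius,
            bg_annulus=config.bg_annulus,
        )
        traces[ch] = trs
        ch_pulses: list[Pulse] = []
        for tr in trs:
            if not tr.valid:
                continue
            ch_pulses.extend(pulses_from_trace(tr, config.binarization))
        pulses[ch] = ch_pulses
    return spots, traces, pulses, truth


def compute_statistics(
    pulses: dict[str, list[Pulse]], config: RunConfig, n_spots: int
) -> tuple[
    list[ResidencePartition],
    dict[str, RateEstimate | None],
    dict[str, SurvivalCurve | None],
    TestResult | None,
    dict,
]:
    """All kinetic statistics from pulse trains alone (no images needed)."""
    focal = pulses.get(config.focal_channel, [])
    partner = pulses.get(config.partner_channel, [])
    partitions = partition_residences(
        focal, partner, co_arrival_window=config.co_arrival_window
    )

    def _km(parts: list[ResidencePartition]) -> SurvivalCurve | None:
        if not parts:
            return None
        return km_estimate(
            np.array([p.focal.duration for p in parts]),
            np.array([p.focal.right_censored for p in parts]),
        )

    tern = [p for p in partitions if p.ever_ternary]
    nont = [p for p in partitions if not p.ever_ternary]
    survival = {
        "focal_all": _km(partitions),
        "ternary": _km(tern),
        "non_ternary": _km(nont),
    }

    def _rate(pool: str) -> RateEstimate | None:
        try:
            return estimate_offrate(partitions, pool)
        except ValueError:
            return None

    rates = {"ternary": _rate("ternary"), "non_ternary": _rate("non_ternary")}

    lr: TestResult | None = None
    if tern and nont:
        try:
            lr = logrank_test(
                np.array([p.focal.duration for p in tern]),
                np.array([p.focal.right_censored for p in tern]),
                np.array([p.focal.duration for p in nont]),
                np.array([p.focal.right_censored for p in nont]),
            )
        except ValueError:
            lr = None

    summary: dict = {
        "n_spots": n_spots,
        "n_focal_pulses": len(focal),
        "n_partner_pulses": len(partner),
        "n_ternary": len(tern),
        "n_non_ternary": len(nont),
    }
    if focal and n_spots > 0:
        summary["residences_per_spot"] = residences_per_spot(focal, n_spots)
    if tern:
        summary["occupancy_fraction"] = occupancy_fraction(partitions)
        summary["arrival_proportions"] = arrival_proportions(partitions)
    durs = np.array([p.duration for p in focal])
    if len(durs):
        from .kinetics import short_long_proportions

        p_short, p_long = short_long_proportions(
            durs, config.short_cut, config.long_cut
        )
        summary["p_short"] = p_short
        summary["p_long"] = p_long
    for pool, r in rates.items():
        if r is not None:
            summary[f"k_{pool}_per_h"] = r.k
            summary[f"n_off_{pool}"] = r.n_off
    for name, curve in survival.items():
        if curve is not None:
            summary[f"median_{name}_s"] = (
                curve.median if curve.median_defined else None
            )
            summary[f"n_censored_{name}"] = curve.n_censored
    if lr is not None:
        summary["logrank_statistic"] = lr.statistic
        summary["logrank_p"] = lr.p_value
    return partitions, rates, survival, lr, summary


def _export_survival(curve: SurvivalCurve, path: Path) -> None:
    pd.DataFrame(
        {
            "t": curve.times,
            "S": curve.survival,
            "lo": curve.ci_lower,
            "hi": curve.ci_upper,
            "at_risk": curve.at_risk,
        }
    ).to_csv(path, index=False)


def _write_outputs(config: RunConfig, result: TimelapseResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.spots.table.to_csv(outdir / "spots.csv", index=False)
    traces_to_frame(
        [t for ts in result.traces.values() for t in ts]
    ).to_csv(outdir / "traces.csv", index=False)
    pulses_to_frame(
        [p for ps in result.pulses.values() for p in ps]
    ).to_csv(outdir / "pulses.csv", index=False)
    partitions_to_frame(result.partitions).to_csv(
        outdir / "partitions.csv", index=False
    )
    for name, curve in result.survival.items():
        if curve is not None:
            _export_survival(curve, outdir / f"survival_{name}.csv")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True, default=float)
    )
    manifest = {"tirfkin_version": __version__, "config": config.to_dict()}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# entry points

def run_timelapse(config: RunConfig) -> TimelapseResult:
    """Execute the full residence-lifetime pipeline for one run."""
    spots, traces, pulses, truth = pipeline_pulses(config)
    partitions, rates, survival, lr, summary = compute_statistics(
        pulses, config, len(spots)
    )
    result = TimelapseResult(
        spots=spots,
        traces=traces,
        pulses=pulses,
        partitions=partitions,
        rates=rates,
        survival=survival,
        logrank=lr,
        summary=summary,
        truth=truth,
    )
    if config.outdir is not None:
        _write_outputs(config, result)
    return result


def run_stats(pulse_csv: str | Path, config: RunConfig, n_spots: int) -> dict:
    """Skip-imaging mode: statistics straight from a saved pulse table."""
    df = pd.read_csv(pulse_csv)
    df["channel"] = df["channel"].astype(str)
    pulses: dict[str, list[Pulse]] = {}
    for ch, grp in df.groupby("channel"):
        pulses[str(ch)] = pulses_from_frame(grp)
    _, _, _, _, summary = compute_statistics(pulses, config, n_spots)
    return summary


def run_endpoint(
    config: RunConfig, n_fields: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Single-snapshot colocalization over one or more fields of view.

    In simulation mode each field draws fresh spot positions and occupancy
    (``initial_occupancy`` of the simulation params) and renders a single
    frame per channel; spot detection runs in single-frame mode (the
    persistency filter is vacuous) and each protein channel is scored
    against the DNA map.  Returns a per-field table and a summary with
    across-field mean +/- s.d. per channel.
    """
    if config.simulation is None:
        raise ValueError("endpoint mode currently requires simulation params")
    rows = []
    base = config.simulation
    snap_schedule = AcquisitionSchedule(
        total_duration=1.0,
        channel_intervals={ch: 1.0 for ch in config.schedule.channels},
    )
    for f in range(n_fields):
        params = dataclasses.replace(
            base,
            seed=int(np.random.SeedSequence([config.seed, f]).generate_state(1)[0] % (2**31)),
            kinetics={
                ch: SpeciesKinetics(k_on=0.0, k_off=0.0, k_bleach=0.0)
                for ch in base.kinetics
            },
        )
        truth = simulate_pulse_trains(params, snap_schedule)
        stacks = render_movie(truth, params, snap_schedule)
        dna = ImageStack(
            config.dna_channel,
            stacks[config.dna_channel][:1],
            np.array([0.0]),
            params.pixel_size,
        )
        dna_map = detect_dna_spots(
            dna,
            threshold_policy=config.threshold_policy,
            size_range=config.size_range,
            min_persistency=config.min_persistency,
            link_radius=config.link_radius,
        )
        for ch in stacks:
            if ch == config.dna_channel:
                continue
            qry = detect_dna_spots(
                ImageStack(ch, stacks[ch][:1], np.array([0.0]), params.pixel_size),
                threshold_policy=config.threshold_policy,
                size_range=config.size_range,
                min_persistency=config.min_persistency,
                link_radius=config.link_radius,
            )
            res = endpoint_colocalization(dna_map, qry, config.match_radius)
            rows.append(
                {
                    "field": f,
                    "channel": ch,
                    "n_reference": res.n_reference,
                    "n_colocalized": res.n_colocalized,
                    "fraction_pct": res.fraction,
                }
            )
    table = pd.DataFrame(rows)
    summary: dict = {}
    for ch, grp in table.groupby("channel"):
        vals = grp["fraction_pct"].dropna()
        summary[str(ch)] = {
            "mean_pct": float(vals.mean()) if len(vals) else None,
            "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "n_fields": int(len(grp)),
        }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "endpoint.csv", index=False)
        (outdir / "endpoint_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
    return table, summary
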