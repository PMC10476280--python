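"""Synthetic CoSMoS data with known binding/bleaching kinetics.

Ground truth is generated in two stages that mirror the physics:

1. ``simulate_pulse_trains`` runs a continuous-time two-state (bound/free)
   chain per spot and protein species.  OFF -> ON waiting times are
   exponential with rate ``k_on``; ON intervals end after an exponential
   waiting time with total rate ``k_off + k_bleach``, the cause drawn
   proportionally (competing risks).  Intervals still ON at the end of the
   acquisition are flagged as censored.
2. ``render_movie`` paints each ON molecule as a 2-D Gaussian PSF at its
   drift-displaced spot position onto a constant background, then applies
   shot noise, producing multi-page image stacks on the acquisition grid.

Because state is sampled in continuous time but observed only at frame
times, an ON interval shorter than one frame interval that straddles no
frame time is invisible by construction — this mimics the real detection
floor of interval imaging and is deliberately not corrected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .schedule import AcquisitionSchedule

__all__ = [
    "DriftSpec",
    "SpeciesKinetics",
    "SimulationParams",
    "GroundTruth",
    "simulate_pulse_trains",
    "render_movie",
    "export_ground_truth",
    "read_ground_truth",
    "simulate_staircase_traces",
    "write_movie",
    "read_movie",
    "DNA_CHANNEL",
]

#: conventional reference / DNA-marker channel label
DNA_CHANNEL = "647"

#: termination causes for a simulated ON interval
CAUSE_DETACH = "detachment"
CAUSE_BLEACH = "bleach"
CAUSE_END = "end-of-acquisition"

_TRUTH_COLUMNS = ["spot", "channel", "t_start", "t_end", "cause"]


@dataclass(frozen=True)
class DriftSpec:
    """Lateral stage drift as a smooth displacement field (px vs time).

    displacement(t) = velocity * t + amplitude * sin(2*pi*t / period)

    ``velocity`` is (dy, dx) in px/s; the sinusoidal wobble is optional
    (amplitude 0 disables it).  At t = 0 the displacement is (0, 0).
    """

    velocity: tuple[float, float] = (0.0, 0.0)
    wobble_amplitude: float = 0.0
    wobble_period: float = 600.0

    def displacement(self, t: float | np.ndarray) -> np.ndarray:
        """Displacement (dy, dx) in px at time(s) ``t`` (s); shape (..., 2)."""
        t = np.asarray(t, dtype=float)
        lin = np.stack([self.velocity[0] * t, self.velocity[1] * t], axis=-1)
        if self.wobble_amplitude != 0.0:
            w = self.wobble_amplitude * np.sin(2 * np.pi * t / self.wobble_period)
            lin = lin + np.stack([w, w], axis=-1)
        return lin


@dataclass(frozen=True)
class SpeciesKinetics:
    """First-order binding kinetics for one labeled species, in events/hour.

    ``k_on`` is the per-spot arrival rate from solution, ``k_off`` the true
    detachment rate, and ``k_bleach`` the photobleaching rate of the bound
    fluorophore (a competing risk that also terminates the visible pulse).
    """

    k_on: float
    k_off: float
    k_bleach: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_bleach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def k_loss(self) -> float:
        """Total ON-state exit rate, events/h."""
        return self.k_off + self.k_bleach


@dataclass(frozen=True)
class SimulationParams:
    """Everything the simulator needs besides the acquisition schedule.

    Defaults emulate the assay geometry this package targets: ~1,000
    surface-tethered DNA templates per 512 x 512 px field at 0.11 um/px,
    diffraction-limited PSF (sigma ~1.3 px), EMCCD-like shot noise.
    """

    n_spots: int = 1000
    field_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.11  # um/px
    spot_min_separation: float = 8.0  # px
    kinetics: dict[str, SpeciesKinetics] = field(
        default_factory=lambda: {
            "488": SpeciesKinetics(k_on=1.0, k_off=30.0, k_bleach=2.0),
            "561": SpeciesKinetics(k_on=1.0, k_off=20.0, k_bleach=2.0),
        }
    )
    psf_sigma: float = 1.3  # px
    spot_amplitude: float = 800.0  # photons per labeled molecule per frame
    dna_amplitude: float | None = None  # defaults to spot_amplitude
    background_mean: float = 200.0  # photons
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_noise_sigma: float = 10.0
    drift: DriftSpec = DriftSpec()
    initial_occupancy: float = 0.0
    edge_margin: float = 12.0  # px kept clear of the field border
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.spot_min_separation <= 0:
            raise ValueError("spot_min_separation must be positive")
        if not 0.0 <= self.initial_occupancy <= 1.0:
            raise ValueError("initial_occupancy must be in [0, 1]")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("noise_model must be 'poisson', 'gaussian' or 'none'")
        h, w = self.field_size
        usable = (h - 2 * self.edge_margin) * (w - 2 * self.edge_margin)
        # random sequential placement saturates near 0.7 spots per sep^2 of
        # usable area; stay at half that so dart-throwing converges quickly
        if self.n_spots > 0 and 0.35 * usable < self.n_spots * self.spot_min_separation**2:
            raise ValueError(
                "field cannot accommodate n_spots at the requested separation"
            )

    @property
    def effective_dna_amplitude(self) -> float:
        return self.spot_amplitude if self.dna_amplitude is None else self.dna_amplitude


@dataclass
class GroundTruth:
    """True spot positions and per-channel ON intervals.

    ``centroids`` is an (n_spots, 2) array of (row, col) pixel positions in
    the un-drifted frame of reference.  ``intervals`` has one row per ON
    interval: spot, channel, t_start, t_end (s, half-open) and cause of
    termination (detachment / bleach / end-of-acquisition).
    """

    centroids: np.ndarray
    intervals: pd.DataFrame
    total_duration: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        missing = [c for c in _TRUTH_COLUMNS if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"intervals missing columns: {missing}")
        iv = self.intervals
        if len(iv):
            if (iv["t_start"] < 0).any() or (iv["t_end"] > self.total_duration + 1e-9).any():
                raise ValueError("intervals outside the acquisition window")
            if (iv["t_end"] <= iv["t_start"]).any():
                raise ValueError("empty or inverted interval")

    def intervals_for(self, spot: int, channel: str) -> pd.DataFrame:
        iv = self.intervals
        return iv[(iv["spot"] == spot) & (iv["channel"] == channel)]


# ---------------------------------------------------------------------------
# spot placement

def _place_spots(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement of immobile spots with a hard minimum spacing."""
    h, w = params.field_size
    m = params.edge_margin
    sep2 = params.spot_min_separation**2
    placed: list[np.ndarray] = []
    # grid acceleration: bin side = min separation
    cell = params.spot_min_separation
    grid: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    max_attempts = 200 * max(params.n_spots, 1)
    while len(placed) < params.n_spots:
        if attempts >= max_attempts:
            raise RuntimeError("could not place spots at the requested separation")
        attempts += 1
        p = np.array([rng.uniform(m, h - m), rng.uniform(m, w - m)])
        gy, gx = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for idx in grid.get((gy + dy, gx + dx), ()):
                    if np.sum((placed[idx] - p) ** 2) < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gy, gx), []).append(len(placed))
            placed.append(p)
    return np.array(placed).reshape(-1, 2)


# ---------------------------------------------------------------------------
# kinetic simulation

def _simulate_one_train(
    kin: SpeciesKinetics,
    total: float,
    start_on: bool,
    rng: np.random.Generator,
) -> list[tuple[float, float, str]]:
    """Alternating OFF/ON intervals for one spot; returns ON intervals only."""
    k_on = kin.k_on / 3600.0  # /s
    k_loss = kin.k_loss / 3600.0
    p_bleach = kin.k_bleach / kin.k_loss if kin.k_loss > 0 else 0.0
    t = 0.0
    on = start_on
    out: list[tuple[float, float, str]] = []
    while t < total:
        if on:
            if k_loss == 0.0:
                out.append((t, total, CAUSE_END))
                break
            dwell = rng.exponential(1.0 / k_loss)
            if t + dwell >= total:
                out.append((t, total, CAUSE_END))
                break
            cause = CAUSE_BLEACH if rng.random() < p_bleach else CAUSE_DETACH
            out.append((t, t + dwell, cause))
            t += dwell
            on = False
        else:
            if k_on == 0.0:
                break
            t += rng.exponential(1.0 / k_on)
            on = True
    return out


def simulate_pulse_trains(
    params: SimulationParams, schedule: AcquisitionSchedule
) -> GroundTruth:
    """Draw ground-truth ON intervals for every spot and protein species.

    Reproducible: a fixed ``params.seed`` yields identical output.  The DNA
    reference channel carries no kinetics — templates are permanently
    present — so intervals are generated only for channels present in
    ``params.kinetics``.
    """
    for ch in params.kinetics:
        if ch not in schedule.channel_intervals:
            raise ValueError(f"kinetics given for channel {ch!r} not in the schedule")
    if all(schedule.n_frames(ch) == 0 for ch in schedule.channels):
        raise ValueError("schedule has no frames")

    rng = np.random.default_rng(params.seed)
    centroids = _place_spots(params, rng)
    rows: list[tuple[int, str, float, float, str]] = []
    total = schedule.total_duration
    for spot in range(params.n_spots):
        for ch, kin in params.kinetics.items():
            start_on = rng.random() < params.initial_occupancy
            for t0, t1, cause in _simulate_one_train(kin, total, start_on, rng):
                rows.append((spot, ch, t0, t1, cause))
    intervals = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return GroundTruth(centroids=centroids, intervals=intervals, total_duration=total)


# ---------------------------------------------------------------------------
# rendering

def _paint_gaussian(
    frame: np.ndarray, cy: float, cx: float, sigma: float, amplitude: float
) -> None:
    """Add an integrated-intensity-``amplitude`` Gaussian in place (windowed)."""
    h, w = frame.shape
    r = int(math.ceil(4 * sigma)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=float) - cy
    xx = np.arange(x0, x1, dtype=float) - cx
    g = np.exp(-0.5 * (yy[:, None] ** 2 + xx[None, :] ** 2) / sigma**2)
    frame[y0:y1, x0:x1] += amplitude / (2 * np.pi * sigma**2) * g


def _on_at(intervals: pd.DataFrame, t: float, total_duration: float) -> np.ndarray:
    """Spot ids whose ON interval covers time ``t`` (half-open [start, end)).

    Intervals censored at the acquisition end are closed on the right so the
    final frame still shows the molecule.
    """
    start = intervals["t_start"].to_numpy()
    end = intervals["t_end"].to_numpy()
    m = (start <= t) & ((t < end) | ((end >= total_duration) & (t <= end)))
    return intervals.loc[m, "spot"].to_numpy()


def render_movie(
    truth: GroundTruth,
    params: SimulationParams,
    schedule: AcquisitionSchedule,
    n_fluorophores: int = 1,
) -> dict[str, np.ndarray]:
    """Render per-channel image stacks (frames x H x W, float photons).

    The DNA channel shows every template in every frame; protein channels
    show a PSF only while the molecule is ON at that frame time.  Spots are
    displaced by the programmed drift; shot noise is applied last.
    ``n_fluorophores > 1`` multiplies each molecule's brightness (used for
    stoichiometry/step-count scenarios at the movie level).
    """
    h, w = params.field_size
    if truth.centroids.shape[0] != params.n_spots:
        raise ValueError("truth inconsistent with params (spot count)")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC0FFEE]))
    stacks: dict[str, np.ndarray] = {}
    for ch in schedule.channels:
        times = schedule.frame_times(ch)
        stack = np.full((len(times), h, w), float(params.background_mean))
        is_dna = ch not in params.kinetics
        amp = params.effective_dna_amplitude if is_dna else params.spot_amplitude
        amp = amp * (1 if is_dna else n_fluorophores)
        ch_iv = truth.intervals[truth.intervals["channel"] == ch]
        for i, t in enumerate(times):
            dy, dx = params.drift.displacement(t)
            spots = (
                np.arange(params.n_spots)
                if is_dna
                else _on_at(ch_iv, t, truth.total_duration)
            )
            for s in spots:
                cy, cx = truth.centroids[s]
                cy, cx = cy + dy, cx + dx
                if not (0 <= cy < h and 0 <= cx < w):
                    raise ValueError(
                        f"spot {s} drifted outside the field at t={t:.1f} s"
                    )
                _paint_gaussian(stack[i], cy, cx, params.psf_sigma, amp)
        if params.noise_model == "poisson":
            stack = rng.poisson(stack).astype(float)
        elif params.noise_model == "gaussian":
            stack = stack + rng.normal(0.0, params.gaussian_noise_sigma, stack.shape)
        stacks[ch] = stack
    return stacks


# ---------------------------------------------------------------------------
# staircase (stoichiometry) traces

def simulate_staircase_traces(
    n_traces: int,
    n_fluorophores: int,
    k_bleach: float,
    schedule_interval: float = 5.0,
    total_duration: float = 2700.0,
    amplitude: float = 1.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity staircases from ``n_fluorophores`` independently bleaching dyes.

    Each fluorophore contributes ``amplitude`` until its own exponential
    bleaching time (rate ``k_bleach`` in events/h); Gaussian noise of sd
    ``noise_sigma`` is added.  Returns ``(traces, true_steps)`` where
    ``true_steps[i]`` counts bleaching events that fall inside the recorded
    window (distinct frames; near-simultaneous bleaches can merge).
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(int(np.floor(total_duration / schedule_interval + 1e-9)) + 1)
    times = times * schedule_interval
    traces = np.empty((n_traces, len(times)))
    true_steps = np.empty(n_traces, dtype=int)
    rate = k_bleach / 3600.0
    for i in range(n_traces):
        bleach_t = (
            rng.exponential(1.0 / rate, n_fluorophores)
            if rate > 0
            else np.full(n_fluorophores, np.inf)
        )
        level = (times[None, :] < bleach_t[:, None]).sum(axis=0).astype(float)
        true_steps[i] = int(np.sum(bleach_t < total_duration))
        traces[i] = level * amplitude + rng.normal(0.0, noise_sigma, len(times))
    return traces, true_steps


# ---------------------------------------------------------------------------
# serialization

def export_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ON intervals (and spot centroids alongside) as plain CSV.

    ``<path>`` receives the interval table; centroids go to
    ``<path stem>_spots.csv`` next to it so acceptance joins need no pickle.
    """
    path = Path(path)
    truth.intervals.to_csv(path, index=False)
    spots = pd.DataFrame(truth.centroids, columns=["row", "col"])
    spots.insert(0, "spot", np.arange(len(spots)))
    spots["total_duration"] = truth.total_duration
    spots.to_csv(path.with_name(path.stem + "_spots.csv"), index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Inverse of :func:`export_ground_truth`."""
    path = Path(path)
    intervals = pd.read_csv(path)
    if len(intervals) == 0:
        intervals = pd.DataFrame(columns=_TRUTH_COLUMNS)
    intervals["channel"] = intervals["channel"].astype(str)
    spots = pd.read_csv(path.with_name(path.stem + "_spots.csv"))
    centroids = spots[["row", "col"]].to_numpy()
    total = float(spots["total_duration"].iloc[0]) if len(spots) else float(
        intervals["t_end"].max() if len(intervals) else 0.0
    )
    return GroundTruth(centroids=centroids, intervals=intervals, total_duration=total)


def write_movie(
    stacks: dict[str, np.ndarray],
    schedule: AcquisitionSchedule,
    params: SimulationParams,
    outdir: str | Path,
) -> None:
    """Write one multi-page TIFF per channel plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch, stack in stacks.items():
        tifffile.imwrite(outdir / f"channel_{ch}.tif", stack.astype(np.float32))
    sidecar = {
        "schedule": schedule.to_dict(),
        "pixel_size": params.pixel_size,
        "channels": list(stacks),
    }
    (outdir / "acquisition.json").write_text(json.dumps(sidecar, indent=2))


def read_movie(indir: str | Path) -> tuple[dict[str, np.ndarray], AcquisitionSchedule, float]:
    """Read stacks + schedule written by :func:`write_movie`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "acquisition.json").read_text())
    schedule = AcquisitionSchedule.from_dict(sidecar["schedule"])
    stacks = {
        ch: tifffile.imread(indir / f"channel_{ch}.tif").astype(float)
        for ch in sidecar["channels"]
    }
    for ch, stack in stacks.items():
        if stack.ndim == 2:  # single-page stacks come back squeezed
            stacks[ch] = stack[None, ...]
    return stacks, schedule, float(sidecar["pixel_size"])
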