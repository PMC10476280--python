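"""Image pipeline: drift correction, DNA-spot detection, trace extraction.

Turns raw multi-channel stacks into per-spot, background-subtracted,
z-normalized intensity traces.  The DNA-marker channel anchors everything:
drift is estimated on it (templates are immobile and always lit), its
thresholded spots define the spot map, and protein-channel intensities are
then read out at those fixed positions on the fast time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "DriftModel",
    "SpotMap",
    "Trace",
    "ThresholdPolicy",
    "estimate_drift",
    "apply_drift_correction",
    "detect_dna_spots",
    "extract_traces",
    "traces_to_frame",
]


@dataclass
class ImageStack:
    """An ordered stack of same-shape frames for one channel."""

    channel: str
    frames: np.ndarray  # (n_frames, H, W)
    frame_times: np.ndarray  # s
    pixel_size: float = 0.11  # um/px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frame count does not match frame_times")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DriftModel:
    """Per-reference-time (dy, dx) displacement of the image content, px.

    Displacement at the first reference time is (0, 0) by construction;
    between reference times the model interpolates linearly, and holds the
    boundary values outside the sampled window.
    """

    times: np.ndarray
    dy: np.ndarray
    dx: np.ndarray
    method: str = "phase_correlation"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float) - float(self.dy[0])
        self.dx = np.asarray(self.dx, dtype=float) - float(self.dx[0])
        if not (np.isfinite(self.dy).all() and np.isfinite(self.dx).all()):
            raise ValueError("drift displacements must be finite")

    def displacement(self, t: float | np.ndarray) -> np.ndarray:
        """Interpolated (dy, dx) at time(s) t; shape (..., 2)."""
        t = np.asarray(t, dtype=float)
        return np.stack(
            [np.interp(t, self.times, self.dy), np.interp(t, self.times, self.dx)],
            axis=-1,
        )

    @property
    def max_displacement(self) -> float:
        return float(np.max(np.hypot(self.dy, self.dx)))


@dataclass
class SpotMap:
    """Detected immobile template locations, one row per spot.

    Columns: ``spot`` (id), ``row``/``col`` (centroid, px, drift-corrected
    frame of reference), ``area`` (px), ``persistency`` (fraction of
    reference-channel frames in which the spot was detected).
    """

    table: pd.DataFrame
    field_shape: tuple[int, int] | None = None

    _COLUMNS = ["spot", "row", "col", "area", "persistency"]

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"SpotMap table missing columns: {missing}")
        if self.table["spot"].duplicated().any():
            raise ValueError("duplicate spot ids")
        if len(self.table) and not self.table["persistency"].between(0, 1).all():
            raise ValueError("persistency must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["row", "col"]].to_numpy(dtype=float).reshape(-1, 2)

    @property
    def ids(self) -> np.ndarray:
        return self.table["spot"].to_numpy()


@dataclass
class Trace:
    """Per-spot, per-channel intensity time series.

    ``z`` is the background-subtracted series centered and scaled by a
    single robust (median, MAD) pair estimated from the whole series, so a
    binarization threshold in z-units means "MADs above baseline".
    """

    spot: int
    channel: str
    frame_times: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    z: np.ndarray
    valid: bool = True  # False when the background annulus leaves the field

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        if not (len(self.raw) == len(self.background) == len(self.z) == n):
            raise ValueError("trace arrays must share the frame grid")


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the global DNA binarization threshold is computed.

    ``mad``: median + k * scaled-MAD of the pooled raw frame pixels (robust
    to sparse bright spots, and reflects the per-frame noise the
    binarization actually sees).  ``quantile``: a fixed pixel quantile.
    ``absolute``: a user-supplied intensity value.
    """

    kind: str = "mad"
    k: float = 4.0
    quantile: float = 0.99
    absolute: float | None = None

    def threshold(self, reference_image: np.ndarray) -> float:
        if self.kind == "absolute":
            if self.absolute is None:
                raise ValueError("absolute policy requires a value")
            return float(self.absolute)
        if self.kind == "quantile":
            return float(np.quantile(reference_image, self.quantile))
        if self.kind == "mad":
            med = np.median(reference_image)
            mad = 1.4826 * np.median(np.abs(reference_image - med))
            return float(med + self.k * mad)
        raise ValueError(f"unknown threshold policy {self.kind!r}")


# ---------------------------------------------------------------------------
# drift

def estimate_drift(
    stack: ImageStack,
    method: str = "auto",
    upsample_factor: int = 50,
    auto_threshold: float = 5.0,
) -> DriftModel:
    """Estimate lateral drift of every frame relative to the first.

    Sub-pixel displacements come from upsampled FFT cross-correlation
    against frame 0.  ``translation_fit`` replaces the raw per-frame
    estimates with a least-squares linear (constant-velocity) fit — the
    smooth model of choice when drift is severe and per-frame estimates
    noisy; ``auto`` switches to it once the raw cumulative displacement
    exceeds ``auto_threshold`` px.
    """
    if method not in ("phase_correlation", "translation_fit", "auto"):
        raise ValueError(f"unknown drift method {method!r}")
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to estimate drift")
    ref = stack.frames[0]
    if np.ptp(ref) == 0:
        warnings.warn("constant reference frame; assuming zero drift", stacklevel=2)
        z = np.zeros(stack.n_frames)
        return DriftModel(stack.frame_times, z, z.copy(), method="degenerate")
    dy = np.zeros(stack.n_frames)
    dx = np.zeros(stack.n_frames)
    for i in range(1, stack.n_frames):
        shift, _, _ = phase_cross_correlation(
            ref, stack.frames[i], upsample_factor=upsample_factor, normalization=None
        )
        # returned shift registers the moving frame onto the reference, so
        # the content displacement is its negative
        dy[i], dx[i] = -shift[0], -shift[1]
    used = method
    if method == "auto":
        used = (
            "translation_fit"
            if float(np.max(np.hypot(dy, dx))) > auto_threshold
            else "phase_correlation"
        )
    if used == "translation_fit":
        t = stack.frame_times
        A = np.stack([t - t[0], np.ones_like(t)], axis=1)
        dy = A @ np.linalg.lstsq(A, dy, rcond=None)[0]
        dx = A @ np.linalg.lstsq(A, dx, rcond=None)[0]
    return DriftModel(stack.frame_times, dy, dx, method=used)


def apply_drift_correction(stack: ImageStack, drift: DriftModel) -> ImageStack:
    """Resample every frame back by its drift displacement (linear interp).

    Pixels carried in from outside the field are filled with the frame's
    median (a background estimate).
    """
    h, w = stack.shape
    if drift.max_displacement > max(h, w):
        raise ValueError("drift displacement exceeds the field size")
    disp = drift.displacement(stack.frame_times)
    out = np.empty_like(stack.frames)
    for i in range(stack.n_frames):
        dyi, dxi = disp[i]
        if dyi == 0.0 and dxi == 0.0:
            out[i] = stack.frames[i]
            continue
        out[i] = ndimage.shift(
            stack.frames[i],
            shift=(-dyi, -dxi),
            order=1,
            mode="constant",
            cval=float(np.median(stack.frames[i])),
        )
    return ImageStack(stack.channel, out, stack.frame_times, stack.pixel_size)


# ---------------------------------------------------------------------------
# spot detection

def _frame_candidates(
    frame: np.ndarray, thr: float, size_range: tuple[float, float]
) -> list[tuple[float, float, float]]:
    lbl = label(frame > thr)
    # weight centroids by background-subtracted intensity
    bg = float(np.median(frame))
    weights = np.clip(frame - bg, 0.0, None)
    out = []
    for p in regionprops(lbl, intensity_image=weights):
        if size_range[0] <= p.area <= size_range[1]:
            cy, cx = p.centroid_weighted
            out.append((cy, cx, float(p.area)))
    return out


def detect_dna_spots(
    dna_stack: ImageStack,
    threshold_policy: ThresholdPolicy | None = None,
    size_range: tuple[float, float] = (2, 30),
    min_persistency: float = 0.5,
    link_radius: float = 2.0,
) -> SpotMap:
    """Identify immobile DNA-template spots in the (drift-corrected) stack.

    Every frame is binarized at one global threshold computed from the
    temporal-median image, connected components within ``size_range`` become
    candidates, candidates are linked across frames by proximity
    (``link_radius``; templates are immobile after drift correction), and
    tracks detected in fewer than ``min_persistency`` of frames are dropped.
    With a single frame the persistency filter is vacuous (endpoint mode).
    """
    if dna_stack.n_frames == 0:
        raise ValueError("empty stack")
    policy = threshold_policy or ThresholdPolicy()
    # pool raw pixels (subsampled frames for large stacks) so the threshold
    # sees the same noise the per-frame binarization does
    step = max(1, dna_stack.n_frames * dna_stack.frames[0].size // 4_000_000)
    thr = policy.threshold(dna_stack.frames[::step])

    # tracks: running lists of per-frame detections
    track_pos: list[list[tuple[float, float]]] = []
    track_area: list[list[float]] = []
    for frame in dna_stack.frames:
        cands = _frame_candidates(frame, thr, size_range)
        if not cands:
            continue
        pts = np.array([(c[0], c[1]) for c in cands])
        if track_pos:
            centers = np.array([np.mean(p, axis=0) for p in track_pos])
            tree = cKDTree(centers)
            dist, idx = tree.query(pts, distance_upper_bound=link_radius)
        else:
            dist = np.full(len(pts), np.inf)
            idx = np.zeros(len(pts), dtype=int)
        claimed: set[int] = set()
        for j, (cy, cx, area) in enumerate(cands):
            if np.isfinite(dist[j]) and idx[j] not in claimed:
                track_pos[idx[j]].append((cy, cx))
                track_area[idx[j]].append(area)
                claimed.add(int(idx[j]))
            else:
                track_pos.append([(cy, cx)])
                track_area.append([area])

    rows = []
    n_frames = dna_stack.n_frames
    for positions, areas in zip(track_pos, track_area):
        persistency = len(positions) / n_frames
        if n_frames > 1 and persistency < min_persistency:
            continue
        cy, cx = np.mean(positions, axis=0)
        rows.append((cy, cx, float(np.mean(areas)), persistency))
    table = pd.DataFrame(rows, columns=["row", "col", "area", "persistency"])
    table = table.sort_values(["row", "col"]).reset_index(drop=True)
    table.insert(0, "spot", np.arange(len(table)))
    return SpotMap(table, field_shape=dna_stack.shape)


# ---------------------------------------------------------------------------
# trace extraction

def _robust_scale(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _clipped_baseline(
    sub: np.ndarray, clip: float = 3.0, n_iter: int = 3
) -> tuple[float, float, np.ndarray]:
    """Baseline center/scale by one-sided sigma clipping.

    Bound intervals only push intensity up, so frames above
    center + ``clip``*scale are iteratively excluded before re-estimating the
    median/MAD.  This keeps the baseline honest for traces that are ON for a
    substantial fraction of frames (a plain median/MAD baseline degrades
    beyond ~30% duty cycle).  Clipping stops if it would leave fewer than
    max(8, 25%) of the frames.  Returns (center, scale, kept_mask).
    """
    keep = np.ones(len(sub), dtype=bool)
    center = float(np.median(sub))
    scale = _robust_scale(sub)
    floor = max(8, int(0.25 * len(sub)))
    for _ in range(n_iter):
        if scale <= 0:
            break
        new = sub <= center + clip * scale
        if new.sum() < floor or np.array_equal(new, keep):
            break
        keep = new
        center = float(np.median(sub[keep]))
        scale = _robust_scale(sub[keep])
    return center, scale, keep


def extract_traces(
    stack: ImageStack,
    spots: SpotMap,
    aperture_radius: float = 3.0,
    bg_annulus: tuple[float, float] = (5.0, 8.0),
) -> list[Trace]:
    """Read out per-spot intensity series and z-normalize them.

    raw = mean over a disc of ``aperture_radius`` at the spot centroid;
    background = median over the ``bg_annulus`` (pixels inside any other
    spot's aperture are excluded); z = (raw - background - center)/scale with
    center = median and scale = 1.4826*MAD of the background-subtracted
    series after one-sided sigma clipping of above-baseline frames (so traces
    that are ON for a large fraction of frames keep an honest baseline).  The
    scale is floored at a noise estimate from temporal first differences
    between baseline frames so a constant trace maps to z = 0, and z is
    invariant to affine rescaling of the raw intensities.

    Spots whose annulus leaves the field are returned flagged
    ``valid=False`` and should be excluded from downstream statistics.
    """
    r_in, r_out = bg_annulus
    if not (0 < aperture_radius <= r_in < r_out):
        raise ValueError("require 0 < aperture_radius <= r_in < r_out")
    h, w = stack.shape
    yy, xx = np.mgrid[0:h, 0:w]
    flat = stack.frames.reshape(stack.n_frames, -1)

    # pixels claimed by any spot's aperture (for annulus exclusion)
    claimed = np.zeros((h, w), dtype=bool)
    cents = spots.centroids
    for cy, cx in cents:
        claimed |= (yy - cy) ** 2 + (xx - cx) ** 2 <= aperture_radius**2

    traces: list[Trace] = []
    for sid, (cy, cx) in zip(spots.ids, cents):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= aperture_radius**2
        valid = (
            cy - r_out >= -0.5
            and cx - r_out >= -0.5
            and cy + r_out <= h - 0.5
            and cx + r_out <= w - 0.5
        )
        ann = (d2 > r_in**2) & (d2 <= r_out**2)
        own = d2 <= aperture_radius**2
        ann &= ~(claimed & ~own)
        if not ann.any() or not disc.any():
            valid = False
            ann = disc  # degenerate fallback, trace flagged anyway
        raw = flat[:, disc.ravel()].mean(axis=1)
        bg = np.median(flat[:, ann.ravel()], axis=1)
        sub = raw - bg
        center, scale, keep = _clipped_baseline(sub)
        if stack.n_frames > 1:
            # noise floor from first differences between consecutive baseline
            # frames (ON-level differences would inflate it)
            pair = keep[1:] & keep[:-1]
            d = np.diff(sub)
            d = d[pair] if pair.sum() >= 4 else d
            noise = _robust_scale(d) / np.sqrt(2.0)
        else:
            noise = 0.0
        scale = max(scale, noise, 1e-12)
        z = (sub - center) / scale
        traces.append(
            Trace(int(sid), stack.channel, stack.frame_times, raw, bg, z, valid=valid)
        )
    return traces


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Long-format table (one row per spot-frame) for CSV export."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "spot": tr.spot,
                    "channel": tr.channel,
                    "t": tr.frame_times,
                    "raw": tr.raw,
                    "background": tr.background,
                    "z": tr.z,
                    "valid": tr.valid,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["spot", "channel", "t", "raw", "background", "z", "valid"]
        )
    return pd.concat(parts, ignore_index=True)
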