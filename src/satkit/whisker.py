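"""Whisker-movement quantification from video.

Gross whisker-field movement is summarized per frame by motion energy: a
bank of complex Gabor filters spanning spatial orientations, spatial
frequencies, and temporal frequencies is convolved with the x,y,t frame
stack, and the mean activation energy across the bank gives a motion-energy
time series.  The trace is baseline-normalized by subtracting the mean of
the low-20th-percentile values of the 1.2 s pre-stimulus period; the
whisking threshold is mean + 3 SD of the normalized pre-stimulus samples;
whisking bouts are maximal supra-threshold runs lasting at least 0.5 s.

A synthetic video generator renders a bright curvilinear filament whose tip
follows a prescribed deflection profile, providing ground truth for
end-to-end tests without any recorded video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

FRAME_RATE_HZ = 30.0
PRE_WINDOW_S = 1.2
MIN_BOUT_S = 0.5
WHISKING_WINDOW_S = (1.0, 2.0)  # post-onset window for percent-whisking


@dataclass
class MotionTrace:
    values: np.ndarray
    frame_rate_hz: float = FRAME_RATE_HZ
    stim_onset_frame: int = 0
    stim_duration_frames: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MotionTrace values must be one-dimensional")


@dataclass(frozen=True)
class Bout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, lo: float, hi: float) -> float:
        return max(0.0, min(self.end_s, hi) - max(self.start_s, lo))


@dataclass
class BoutSet:
    bouts: list[Bout]
    threshold: float

    def __iter__(self):
        return iter(self.bouts)

    def __len__(self):
        return len(self.bouts)


@dataclass
class WhiskerTrack:
    """Per-frame whisker-tip coordinates (pixels, or mm if scaled)."""

    x: np.ndarray
    y: np.ndarray
    frame_rate_hz: float = FRAME_RATE_HZ
    stim_onset_frame: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")


# --------------------------------------------------------------------------
# filter bank and motion energy
# --------------------------------------------------------------------------

def default_gabor_bank(
    orientations: int = 4,
    spatial_freqs: tuple[float, ...] = (0.05, 0.1, 0.2),
    temporal_freqs: tuple[float, ...] = (0.1, 0.25),
    temporal_len: int = 9,
    temporal_sigma: float = 2.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Separable spatiotemporal Gabor bank.

    Each element pairs a complex 2-D spatial Gabor (from skimage) with a
    complex temporal Gabor (Gaussian-windowed exponential, made zero-mean
    so the bank is temporally bandpass: a static scene yields zero energy
    and any frame-to-frame change yields positive energy).  Spatial
    frequencies are in cycles/pixel, temporal frequencies in cycles/frame.
    The default 4 orientations x 3 spatial x 2 temporal frequencies give a
    small standard 24-filter bank.
    """
    t = np.arange(temporal_len) - (temporal_len - 1) / 2.0
    bank = []
    for i in range(orientations):
        theta = i * math.pi / orientations
        for sf in spatial_freqs:
            spatial = gabor_kernel(frequency=sf, theta=theta)
            for tf in temporal_freqs:
                temporal = np.exp(-(t**2) / (2 * temporal_sigma**2)) * np.exp(
                    2j * math.pi * tf * t
                )
                temporal -= temporal.mean()  # zero DC: blind to static content
                temporal /= np.abs(temporal).sum()
                bank.append((spatial, temporal))
    return bank


def motion_energy(
    frames: np.ndarray,
    bank: list[tuple[np.ndarray, np.ndarray]] | None = None,
    frame_rate_hz: float = FRAME_RATE_HZ,
    stim_onset_frame: int = 0,
    stim_duration_frames: int = 0,
) -> MotionTrace:
    """Per-frame motion energy of a grayscale frame stack (T, H, W).

    For each bank filter the stack is convolved with the spatial kernel and
    then with the temporal kernel; squared magnitudes are averaged over
    pixels and across the bank.  Returns the raw (unnormalized) trace.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    if frames.shape[0] < 2:
        raise ValueError("motion energy needs at least 2 frames")
    if bank is None:
        bank = default_gabor_bank()

    trace = np.zeros(frames.shape[0])
    # group by spatial kernel so each spatial convolution is done once
    by_spatial: dict[int, tuple[np.ndarray, list[np.ndarray]]] = {}
    for spatial, temporal in bank:
        key = id(spatial)
        by_spatial.setdefault(key, (spatial, []))[1].append(temporal)
    for spatial, temporals in by_spatial.values():
        resp = fftconvolve(frames.astype(complex), spatial[None, :, :], mode="same")
        for temporal in temporals:
            st = fftconvolve(resp, temporal[:, None, None], mode="same")
            trace += np.mean(np.abs(st) ** 2, axis=(1, 2))
    trace /= len(bank)
    return MotionTrace(
        values=trace,
        frame_rate_hz=frame_rate_hz,
        stim_onset_frame=stim_onset_frame,
        stim_duration_frames=stim_duration_frames,
        normalized=False,
    )


# --------------------------------------------------------------------------
# normalization, threshold, bouts
# --------------------------------------------------------------------------

def _pre_window(trace: MotionTrace, pre_window_s: float) -> np.ndarray:
    n_pre = int(round(pre_window_s * trace.frame_rate_hz))
    if trace.stim_onset_frame < n_pre:
        raise ValueError(
            f"need {pre_window_s} s ({n_pre} frames) of pre-stimulus data, "
            f"stimulus onset is at frame {trace.stim_onset_frame}"
        )
    return trace.values[trace.stim_onset_frame - n_pre : trace.stim_onset_frame]


def normalize_trace(trace: MotionTrace, pre_window_s: float = PRE_WINDOW_S) -> MotionTrace:
    """Baseline-subtract a motion-energy trace.

    The baseline is the mean of the pre-stimulus samples at or below their
    20th percentile (the quiescent floor of the pre-stimulus period); it is
    subtracted from every sample.  Shift-invariant: adding a constant to
    the raw trace leaves the normalized trace unchanged.
    """
    pre = _pre_window(trace, pre_window_s)
    cut = np.percentile(pre, 20)
    baseline = float(np.mean(pre[pre <= cut]))
    out = replace(trace)
    out.values = trace.values - baseline
    out.normalized = True
    return out


def whisking_threshold(trace: MotionTrace, pre_window_s: float = PRE_WINDOW_S) -> float:
    """Whisking threshold: mean + 3 SD of the normalized pre-stimulus samples."""
    if not trace.normalized:
        raise ValueError("whisking_threshold expects a normalized trace")
    pre = _pre_window(trace, pre_window_s)
    return float(np.mean(pre) + 3.0 * np.std(pre))


def detect_bouts(
    trace: MotionTrace,
    threshold: float,
    min_duration_s: float = MIN_BOUT_S,
) -> BoutSet:
    """Maximal supra-threshold runs lasting at least ``min_duration_s``.

    Bout boundaries are at sample resolution: a run of k frames has
    duration k / frame_rate.  Runs shorter than the minimum are dropped.
    """
    above = np.asarray(trace.values) > threshold
    fps = trace.frame_rate_hz
    bouts: list[Bout] = []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # end exclusive
    for s, e in zip(starts, ends):
        duration = (e - s) / fps
        if duration >= min_duration_s - 1e-12:
            bouts.append(Bout(start_s=s / fps, end_s=e / fps))
    return BoutSet(bouts=bouts, threshold=threshold)


def percent_whisking(
    trials: list[MotionTrace],
    window_s: tuple[float, float] = WHISKING_WINDOW_S,
    min_duration_s: float = MIN_BOUT_S,
    pre_window_s: float = PRE_WINDOW_S,
) -> float:
    """Percentage of trials with whisking in the post-stimulus window.

    A trial counts as whisking if at least one detected bout overlaps the
    window (``window_s`` seconds after stimulus onset) by at least the
    minimum bout duration.  Traces are normalized and thresholded per trial
    if not already normalized.
    """
    if not trials:
        raise ValueError("percent_whisking needs at least one trial")
    n_whisk = 0
    for trace in trials:
        if not trace.normalized:
            trace = normalize_trace(trace, pre_window_s)
        thr = whisking_threshold(trace, pre_window_s)
        bouts = detect_bouts(trace, thr, min_duration_s)
        onset_s = trace.stim_onset_frame / trace.frame_rate_hz
        lo, hi = onset_s + window_s[0], onset_s + window_s[1]
        if any(b.overlap_s(lo, hi) >= min_duration_s - 1e-12 for b in bouts):
            n_whisk += 1
    return 100.0 * n_whisk / len(trials)


# --------------------------------------------------------------------------
# tip displacement
# --------------------------------------------------------------------------

def displacement_and_area(
    track: WhiskerTrack,
    stim_window_s: tuple[float, float],
    pre_window_s: float = PRE_WINDOW_S,
) -> tuple[np.ndarray, float]:
    """Tip displacement trace and its area under the curve.

    Displacement is the per-frame Euclidean distance of the tip from its
    pre-stimulus rest position (mean position over the pre-stimulus
    window); the area is the trapezoidal integral of displacement over the
    stimulus window, in coordinate-units x seconds.  Gaps (NaNs) are hard
    errors — no interpolation.
    """
    if np.any(np.isnan(track.x)) or np.any(np.isnan(track.y)):
        raise ValueError("track contains gaps (NaN coordinates)")
    fps = track.frame_rate_hz
    n_pre = int(round(pre_window_s * fps))
    if track.stim_onset_frame < n_pre:
        raise ValueError("insufficient pre-stimulus frames for rest position")
    rest_x = np.mean(track.x[track.stim_onset_frame - n_pre : track.stim_onset_frame])
    rest_y = np.mean(track.y[track.stim_onset_frame - n_pre : track.stim_onset_frame])
    disp = np.hypot(track.x - rest_x, track.y - rest_y)

    lo_f = track.stim_onset_frame + int(round(stim_window_s[0] * fps))
    hi_f = track.stim_onset_frame + int(round(stim_window_s[1] * fps))
    if lo_f < 0 or hi_f >= disp.size or hi_f <= lo_f:
        raise ValueError("stimulus window outside the tracked range")
    area = float(np.trapezoid(disp[lo_f : hi_f + 1], dx=1.0 / fps))
    return disp, area


# --------------------------------------------------------------------------
# synthetic video
# --------------------------------------------------------------------------

def synth_whisker_video(
    n_frames: int = 120,
    shape: tuple[int, int] = (48, 48),
    deflection_px: np.ndarray | None = None,
    base: tuple[float, float] = (6.0, 24.0),
    length_px: float = 36.0,
    curvature: float = 4.0,
    noise_sigma: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, WhiskerTrack]:
    """Render a bright curved filament on a dark background.

    The filament is a quadratic arc from ``base`` toward +x whose tip is
    displaced vertically by ``deflection_px[t]`` each frame; pixel
    intensities get i.i.d. Gaussian noise.  Returns the (T, H, W) float
    stack and the ground-truth tip track.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if deflection_px is None:
        deflection_px = np.zeros(n_frames)
    deflection_px = np.asarray(deflection_px, dtype=float)
    if deflection_px.size != n_frames:
        raise ValueError("deflection profile length must equal n_frames")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    s = np.linspace(0.0, 1.0, 64)
    frames = np.empty((n_frames, h, w))
    tip_x = np.empty(n_frames)
    tip_y = np.empty(n_frames)
    for t in range(n_frames):
        d = deflection_px[t]
        px = base[0] + s * length_px
        py = base[1] + curvature * s**2 + d * s**2
        tip_x[t] = px[-1]
        tip_y[t] = py[-1]
        img = np.zeros((h, w))
        for cx, cy in zip(px, py):
            img += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.8**2))
        img = np.clip(img, 0.0, 1.0)
        frames[t] = img + rng.normal(0.0, noise_sigma, size=(h, w))
    track = WhiskerTrack(x=tip_x, y=tip_y)
    return frames, track
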