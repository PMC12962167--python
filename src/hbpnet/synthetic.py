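"""Seeded simulator of pulse traces and rPPG-like facial video.

Real rPPG benchmarks pair facial video with a contact pulse reference.  The
simulator emulates the measurement physics at desk scale so the full
pipeline — labels, training, inference, evaluation — runs end to end with
no downloads: a skin-toned rectangle whose green channel (and, at half
amplitude, red) is modulated by a pulse waveform of known heart rate, with
configurable rigid motion, illumination drift and sensor noise.  Blood
absorbs green light most strongly, so the green mean *dips* at each
systolic peak, exactly the cue a video model must learn.

Three motion levels (static / slow / fast walking-like sway) and
illumination drift mirror the structure of motion-and-lighting benchmark
protocols; the generator is an emulation of such conditions, not a
reproduction of any dataset.  Everything is deterministic under the spec's
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulse import HbpMap, PeakSequence, PulseTrace, hbp_from_peaks
from .video import ClipSet, FrameSequence, crop_face_roi, resize_normalize, \
    segment_clips

__all__ = ["SyntheticSpec", "SyntheticRecording", "generate_pulse",
           "render_video", "make_recording", "make_dataset"]

#: displacement random-walk scale (px/frame) per motion level
MOTION_SCALES = {"static": 0.0, "slow": 0.5, "fast": 2.0}

#: illumination gain drift amplitude per lighting level
ILLUMINATION_DRIFT = {"weak": 0.02, "strong": 0.05, "natural": 0.10}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of one simulated recording."""

    duration_s: float = 30.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (32, 32)          # (H, W)
    hr_trajectory: tuple = ("constant", 72.0)       # | ("ramp", b0, b1)
                                                    # | ("walk", b0, step_sd)
    pulse_amplitude: float = 0.01    # fractional green-channel modulation
    base_color: tuple[float, float, float] = (0.78, 0.60, 0.48)
    roi: tuple[int, int, int, int] | None = None    # (x, y, w, h); default centered
    motion: str = "static"           # static | slow | fast
    illumination: str = "weak"       # weak | strong | natural
    illumination_drift: float | None = None   # overrides the level's default
    noise_sd: float = 0.005
    pulse_fs: float = 50.0
    pulse_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.pulse_fs <= 0 or self.duration_s <= 0:
            raise ValueError("rates and duration must be positive")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse amplitude must be >= 0")
        if self.motion not in MOTION_SCALES:
            raise ValueError(f"motion must be one of {sorted(MOTION_SCALES)}")
        if self.illumination not in ILLUMINATION_DRIFT:
            raise ValueError(
                f"illumination must be one of {sorted(ILLUMINATION_DRIFT)}")
        for b in self._trajectory_endpoints():
            if not (40.0 <= b <= 180.0):
                raise ValueError(
                    f"heart-rate trajectory must stay in [40, 180], got {b}")

    def _trajectory_endpoints(self) -> tuple[float, ...]:
        kind = self.hr_trajectory[0]
        if kind == "constant":
            return (float(self.hr_trajectory[1]),)
        if kind == "ramp":
            return (float(self.hr_trajectory[1]), float(self.hr_trajectory[2]))
        if kind == "walk":
            return (float(self.hr_trajectory[1]),)
        raise ValueError(f"unknown trajectory {kind!r}")

    def default_roi(self) -> tuple[int, int, int, int]:
        if self.roi is not None:
            return self.roi
        H, W = self.frame_size
        w, h = W // 2, H // 2
        return ((W - w) // 2, (H - h) // 2, w, h)


@dataclass(frozen=True)
class SyntheticRecording:
    """Frames plus the ground truth that produced them."""

    frames: FrameSequence
    pulse: PulseTrace
    peak_times: np.ndarray           # seconds
    hr_bpm_per_s: np.ndarray         # instantaneous HR sampled once per second
    spec: SyntheticSpec
    roi_clipped_frames: int = 0

    @property
    def mean_hr_bpm(self) -> float:
        return float(np.mean(self.hr_bpm_per_s))

    def peak_frames(self) -> np.ndarray:
        """True peak positions as frame indices of the video."""
        idx = np.round(self.peak_times * self.frames.fps).astype(int)
        T = self.frames.shape[0]
        return idx[(idx >= 0) & (idx < T)]


def _hr_at(spec: SyntheticSpec, t: float, rng: np.random.Generator,
           walk_state: list[float]) -> float:
    kind = spec.hr_trajectory[0]
    if kind == "constant":
        return float(spec.hr_trajectory[1])
    if kind == "ramp":
        b0, b1 = float(spec.hr_trajectory[1]), float(spec.hr_trajectory[2])
        frac = min(max(t / spec.duration_s, 0.0), 1.0)
        return b0 + (b1 - b0) * frac
    # bounded random walk, one step per beat
    step = float(spec.hr_trajectory[2]) if len(spec.hr_trajectory) > 2 else 2.0
    walk_state[0] = float(np.clip(walk_state[0] + rng.normal(0.0, step),
                                  40.0, 180.0))
    return walk_state[0]


def generate_pulse(spec: SyntheticSpec) -> tuple[PulseTrace, np.ndarray]:
    """Pulse waveform plus exact peak times for the spec's HR trajectory.

    Beat times integrate the instantaneous rate (next beat 60/bpm(t) seconds
    after the previous).  Each period is an asymmetric raised cosine —
    a slow decay over 70% of the interval followed by a sharp 30% upstroke
    into the next peak — giving one unambiguous maximum per beat.
    """
    rng = np.random.default_rng(spec.seed)
    walk_state = [float(spec.hr_trajectory[1])]
    # one spin-up beat before t=0 so the waveform is defined from the start
    beats = [-60.0 / _hr_at(spec, 0.0, rng, walk_state)]
    t = 0.05  # first visible peak shortly after start
    while t < spec.duration_s + 2.0:
        beats.append(t)
        t += 60.0 / _hr_at(spec, t, rng, walk_state)
    beats_arr = np.asarray(beats)

    n = int(round(spec.duration_s * spec.pulse_fs)) + 1
    times = np.arange(n) / spec.pulse_fs
    seg = np.searchsorted(beats_arr, times, side="right") - 1
    seg = np.clip(seg, 0, len(beats_arr) - 2)
    t0 = beats_arr[seg]
    period = beats_arr[seg + 1] - t0
    phase = (times - t0) / period
    rise = phase >= 0.7
    wave = np.where(rise,
                    0.5 - 0.5 * np.cos(np.pi * (phase - 0.7) / 0.3),
                    0.5 + 0.5 * np.cos(np.pi * phase / 0.7))
    if spec.pulse_noise_sd > 0:
        wave = wave + rng.normal(0.0, spec.pulse_noise_sd, wave.shape)
    visible = beats_arr[(beats_arr >= 0) & (beats_arr <= spec.duration_s)]
    return PulseTrace(wave, spec.pulse_fs), visible


def render_video(spec: SyntheticSpec,
                 pulse: PulseTrace | None = None,
                 peak_times: np.ndarray | None = None) -> SyntheticRecording:
    """Render the rPPG-like video for a spec (generating the pulse if needed)."""
    if pulse is None or peak_times is None:
        pulse, peak_times = generate_pulse(spec)
    if pulse.duration < spec.duration_s - 1.0 / spec.fps:
        raise ValueError("pulse trace shorter than the requested video")
    rng = np.random.default_rng(spec.seed + 1)  # independent of pulse noise
    T = int(round(spec.duration_s * spec.fps))
    H, W = spec.frame_size
    x0, y0, rw, rh = spec.default_roi()

    frame_times = np.arange(T) / spec.fps
    pulse_at_frame = np.interp(frame_times, pulse.times, pulse.samples)
    lo, hi = pulse_at_frame.min(), pulse_at_frame.max()
    norm = ((pulse_at_frame - lo) / (hi - lo)) if hi > lo else \
        np.zeros_like(pulse_at_frame)

    # rigid random-walk translation of the skin patch
    scale = MOTION_SCALES[spec.motion]
    if scale > 0:
        disp = np.cumsum(rng.normal(0.0, scale, size=(T, 2)), axis=0)
    else:
        disp = np.zeros((T, 2))
    # slow multiplicative illumination drift (one full cycle per recording)
    drift_amp = (spec.illumination_drift if spec.illumination_drift is not None
                 else ILLUMINATION_DRIFT[spec.illumination])
    gain = 1.0 + drift_amp * np.sin(2 * np.pi * frame_times
                                    / max(spec.duration_s, 1e-9)
                                    + rng.uniform(0, 2 * np.pi))

    base = np.asarray(spec.base_color, dtype=np.float32)
    frames = np.empty((T, H, W, 3), dtype=np.float32)
    background = 0.5 * base  # darker surround
    clipped = 0
    for t in range(T):
        img = np.broadcast_to(background, (H, W, 3)).copy()
        dx, dy = int(round(disp[t, 0])), int(round(disp[t, 1]))
        x, y = x0 + dx, y0 + dy
        cx0, cy0 = max(x, 0), max(y, 0)
        cx1, cy1 = min(x + rw, W), min(y + rh, H)
        if (cx1 - cx0, cy1 - cy0) != (rw, rh):
            clipped += 1
        if cx1 > cx0 and cy1 > cy0:
            skin = base.copy()
            mod = spec.pulse_amplitude * norm[t]
            skin[1] *= (1.0 - mod)          # green dips at the systolic peak
            skin[0] *= (1.0 - 0.5 * mod)    # red at half amplitude
            img[cy0:cy1, cx0:cx1, :] = skin
        frames[t] = img * gain[t]
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape).astype(np.float32)
    frames = np.clip(frames, 0.0, 1.0)

    # instantaneous HR once per second, from consecutive peak spacing
    sec_grid = np.arange(int(np.floor(spec.duration_s)))
    if len(peak_times) >= 2:
        ibis = np.diff(peak_times)
        mid = 0.5 * (peak_times[:-1] + peak_times[1:])
        hr_per_s = 60.0 / np.interp(sec_grid, mid, ibis)
    else:
        hr_per_s = np.full(sec_grid.shape, np.nan)
    return SyntheticRecording(FrameSequence(frames, spec.fps), pulse,
                              np.asarray(peak_times), hr_per_s, spec, clipped)


def make_recording(spec: SyntheticSpec) -> SyntheticRecording:
    """Generate pulse and render video in one call."""
    return render_video(spec)


def make_dataset(specs: list[SyntheticSpec], clip_T: int, mode: str = "train",
                 out_size: tuple[int, int] | None = None):
    """Render recordings into labeled clip sets plus a manifest.

    Each recording is cropped to its known skin region (detection bypassed),
    resized to ``out_size`` (default: the spec frame size), segmented into
    clips, and labeled by slicing the recording-level heartbeat-probability
    map built from the true peaks.

    Returns ``(clip_sets, recordings, manifest)`` where the manifest is one
    row per clip: recording id, clip index, start frame, true mean HR over
    the clip span.
    """
    clip_sets: list[ClipSet] = []
    recordings: list[SyntheticRecording] = []
    rows = []
    for rec_id, spec in enumerate(specs):
        rec = make_recording(spec)
        roi = spec.default_roi()
        cropped = crop_face_roi(rec.frames, box=roi)
        size = out_size if out_size is not None else spec.frame_size
        resized = resize_normalize(cropped, *size)
        clips = segment_clips(resized, clip_T, mode)

        peaks = rec.peak_frames()
        T_total = resized.shape[0]
        full_map = hbp_from_peaks(PeakSequence(peaks, spec.fps), T_total,
                                  fps=spec.fps)
        labels = [HbpMap(full_map.values[s:s + clip_T], spec.fps)
                  for s in clips.start_frames]
        clips.labels = labels
        clip_sets.append(clips)
        recordings.append(rec)
        for ci, s in enumerate(clips.start_frames):
            lo_s, hi_s = s / spec.fps, (s + clip_T) / spec.fps
            in_span = (rec.peak_times >= lo_s) & (rec.peak_times <= hi_s)
            pts = rec.peak_times[in_span]
            hr = 60.0 / float(np.mean(np.diff(pts))) if len(pts) >= 2 \
                else rec.mean_hr_bpm
            rows.append(dict(recording=rec_id, clip=ci, start_frame=s,
                             true_hr_bpm=hr, motion=spec.motion,
                             illumination=spec.illumination, seed=spec.seed))
    manifest = pd.DataFrame(rows)
    return clip_sets, recordings, manifest
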