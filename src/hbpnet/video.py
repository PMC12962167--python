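"""Video preprocessing: face ROI cropping, resizing, clip segmentation, overlays.

Raw facial video becomes the network input ``X`` (a C,T,H,W clip of values in
[0, 1]) through a fixed pipeline: crop to the face box found on the first
frame, resize to the working resolution, scale pixel values to [0, 1], and
cut the sequence into fixed-length clips (overlapping for training,
non-overlapping for testing).  The reverse direction — rendering attention
maps back onto frames as temporal-difference overlays — lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .pulse import HbpMap

__all__ = [
    "FrameSequence",
    "ClipTensor",
    "ClipSet",
    "crop_face_roi",
    "resize_normalize",
    "segment_clips",
    "attention_overlay",
]

#: A face detector maps one RGB frame (H, W, 3) to a box (x, y, w, h) or None.
FaceDetector = Callable[[np.ndarray], "tuple[int, int, int, int] | None"]


@dataclass(frozen=True)
class FrameSequence:
    """T x H x W x 3 RGB frames with values in [0, 1]."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if frames.size and (frames.min() < 0 or frames.max() > 1):
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class ClipTensor:
    """A C x T x H x W network input clip (RGB channel order)."""

    data: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError(f"clip must be (C, T, H, W), got {data.shape}")
        if data.size and (data.min() < 0 or data.max() > 1):
            raise ValueError("clip values must lie in [0, 1]")

    @property
    def T(self) -> int:
        return self.data.shape[1]


@dataclass
class ClipSet:
    """Ordered clips cut from one source, with their start offsets and labels."""

    clips: list[ClipTensor]
    start_frames: list[int]
    labels: list[HbpMap] | None = None

    def __post_init__(self) -> None:
        if sorted(self.start_frames) != list(self.start_frames):
            raise ValueError("clip start offsets must ascend")
        if self.labels is not None:
            if len(self.labels) != len(self.clips):
                raise ValueError("one label per clip required")
            for clip, lab in zip(self.clips, self.labels):
                if len(lab) != clip.T:
                    raise ValueError("label length must equal clip length")

    def __len__(self) -> int:
        return len(self.clips)


def crop_face_roi(frames: FrameSequence,
                  detector: FaceDetector | None = None,
                  box: "tuple[int, int, int, int] | None" = None) -> FrameSequence:
    """Crop every frame to the face box of the first frame.

    The box is held fixed across the clip; recordings with a known region of
    interest (synthetic data, pre-annotated video) bypass detection by
    passing ``box`` directly.
    """
    if box is None:
        if detector is None:
            raise ValueError("either a detector or an explicit box is required")
        box = detector(frames.frames[0])
        if box is None:
            raise ValueError("no face found in frame 0 and no explicit box given")
    x, y, w, h = (int(v) for v in box)
    T, H, W, _ = frames.shape
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"box {box} does not fit inside {H}x{W} frames")
    return FrameSequence(frames.frames[:, y:y + h, x:x + w, :], frames.fps)


def resize_normalize(frames: FrameSequence | np.ndarray, H: int, W: int,
                     fps: float | None = None) -> FrameSequence:
    """Resize frames to H x W (bilinear) and scale pixel values into [0, 1].

    Accepts a :class:`FrameSequence` (already in [0, 1]) or a raw uint8 array
    in [0, 255], which is scaled by 1/255 first.
    """
    if H < 8 or W < 8:
        raise ValueError("target size must be at least 8x8")
    if isinstance(frames, FrameSequence):
        arr = frames.frames
        fps = frames.fps
    else:
        arr = np.asarray(frames)
        if fps is None:
            raise ValueError("fps required when passing a raw array")
        if arr.dtype == np.uint8:
            arr = arr.astype(np.float32) / 255.0
    T = arr.shape[0]
    if arr.shape[1:3] == (H, W):
        out = arr.astype(np.float32)
    else:
        shrinking = H < arr.shape[1] or W < arr.shape[2]
        out = _sk_resize(arr, (T, H, W, 3), order=1, mode="edge",
                         anti_aliasing=shrinking, preserve_range=True)
    return FrameSequence(np.clip(out, 0.0, 1.0).astype(np.float32), fps)


def segment_clips(frames: FrameSequence, T: int, mode: str = "train") -> ClipSet:
    """Cut the sequence into length-T clips.

    Training uses 50% overlap (stride ``T // 2``), testing no overlap
    (stride ``T``).  Trailing frames that do not fill a clip are dropped.
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    n = frames.shape[0]
    if n < T:
        raise ValueError(f"source of {n} frames is shorter than clip length {T}")
    stride = T // 2 if mode == "train" else T
    starts = list(range(0, n - T + 1, stride))
    clips = [ClipTensor(np.transpose(frames.frames[s:s + T], (3, 0, 1, 2)),
                        frames.fps) for s in starts]
    return ClipSet(clips, starts)


def attention_overlay(maps: np.ndarray, frames: FrameSequence,
                      mu: float = 1.0) -> FrameSequence:
    """Render attention as temporal-difference overlays on the frames.

    ``Image_t = (Map_{t+1} - Map_t) * mu + Frame_t`` for interior times; the
    first and last frames pass through unchanged so the output length equals
    the input length.  Single-channel maps are broadcast over RGB; results
    are clamped to [0, 1] for rendering.
    """
    m = np.asarray(maps, dtype=np.float32)
    T, H, W, _ = frames.shape
    if m.ndim == 3:
        m = m[..., None]
    if m.shape[:3] != (T, H, W) or m.shape[3] not in (1, 3):
        raise ValueError(
            f"maps of shape {maps.shape} do not match frames {frames.shape}")
    out = frames.frames.copy()
    diff = (m[2:] - m[1:-1]) * mu  # forward difference at t = 1 .. T-2
    out[1:-1] = np.clip(out[1:-1] + diff, 0.0, 1.0)
    return FrameSequence(out, frames.fps)
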