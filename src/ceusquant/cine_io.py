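"""Reading and writing cine loops as multi-page TIFF stacks.

All downstream analysis assumes an 8-bit grayscale representation, so the
loader funnels every input — grayscale or RGB, any bit depth — through
:func:`to_grayscale_8bit` before a :class:`CineLoop` is constructed.
Multi-page TIFF (one page per frame) is the canonical interchange format:
it is lossless, universally readable, and round-trips bit-exactly.

The frame rate is caller-supplied metadata, never parsed from the file:
CEUS exports report it inconsistently (the same study may acquire at
10 Hz and archive clips resampled at 20 Hz), so no default is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

# ITU-R BT.601 luma weights for RGB -> gray collapse
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class CineLoop:
    """An ordered stack of 2-D 8-bit frames with a frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols), dtype uint8
        Pixel intensities in [0, 255].
    frame_rate_hz : float
        Acquisition frame rate in frames per second; must be positive.
    origin_time_s : float, default 0
        Time of frame 0 relative to contrast injection, in seconds.
        Zero when unknown; positive when the recording started after
        the injection.
    """

    frames: np.ndarray
    frame_rate_hz: float
    origin_time_s: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError(
                f"frames must be a (n_frames, rows, cols) stack with >= 1 frame, "
                f"got shape {frames.shape}"
            )
        if frames.dtype != np.uint8:
            if frames.min() < 0 or frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            frames = frames.astype(np.uint8)
        if not self.frame_rate_hz > 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        """Clip duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate_hz

    def times_s(self) -> np.ndarray:
        """Per-frame acquisition times relative to injection, in seconds."""
        return self.origin_time_s + np.arange(self.n_frames) / self.frame_rate_hz


def to_grayscale_8bit(frames: np.ndarray) -> np.ndarray:
    """Coerce a frame stack to single-channel 8-bit grayscale.

    RGB input (trailing axis of size 3) is collapsed with BT.601 luma
    weights (0.299, 0.587, 0.114), rounded half-up and clipped to
    [0, 255].  Single-channel input already within [0, 255] is returned
    unchanged (cast to uint8); single-channel input with values outside
    that range is linearly rescaled from its own min–max range onto
    [0, 255].  Constant out-of-range input degenerates to all zeros.

    Parameters
    ----------
    frames : ndarray
        Either (..., rows, cols) single-channel, or (..., rows, cols, c)
        with a trailing channel axis of size 1 or 3.

    Returns
    -------
    ndarray of uint8 with the channel axis removed.
    """
    arr = np.asarray(frames)
    if arr.ndim >= 3 and arr.shape[-1] in (1, 3) and arr.ndim != 3:
        # trailing channel axis on a stack (4-D) — collapse it
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            luma = np.tensordot(arr.astype(np.float64), _BT601, axes=([-1], [0]))
            return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)
    elif arr.ndim == 3 and arr.shape[-1] == 3:
        # a single RGB frame
        luma = np.tensordot(arr.astype(np.float64), _BT601, axes=([-1], [0]))
        return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)
    elif arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]

    if arr.ndim not in (2, 3):
        raise ValueError(
            f"expected single-channel frames or a trailing channel axis of "
            f"size 1 or 3, got shape {arr.shape}"
        )

    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if lo >= 0 and hi <= 255:
        return np.floor(arr + 0.5).astype(np.uint8)
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def load_cine(
    path: str | Path, frame_rate_hz: float, origin_time_s: float = 0.0
) -> CineLoop:
    """Read a multi-page TIFF into a :class:`CineLoop`.

    Frames appear in page order; RGB pages are converted per frame via
    :func:`to_grayscale_8bit`.

    Raises
    ------
    FileNotFoundError / OSError
        Missing or unreadable file (the message names the path).
    ValueError
        Zero pages, or a non-positive frame rate.
    """
    path = Path(path)
    if not frame_rate_hz > 0:
        raise ValueError(f"frame_rate_hz must be positive, got {frame_rate_hz}")
    if not path.exists():
        raise FileNotFoundError(f"cine file not found: {path}")
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # corrupt / non-TIFF
        raise OSError(f"could not read TIFF cine {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.size == 0:
        raise ValueError(f"cine {path} contains no frames")
    if stack.ndim == 2:  # single page
        stack = stack[None]
    frames = to_grayscale_8bit(stack)
    if frames.ndim == 2:
        frames = frames[None]
    return CineLoop(frames=frames, frame_rate_hz=frame_rate_hz, origin_time_s=origin_time_s)


def save_cine(cine: CineLoop, path: str | Path) -> None:
    """Write a :class:`CineLoop` as an 8-bit grayscale multi-page TIFF.

    ``load_cine(path, fps)`` on the written file reproduces the frames
    bit-exactly.
    """
    path = Path(path)
    try:
        tifffile.imwrite(path, cine.frames, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"could not write TIFF cine {path}: {exc}") from exc
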