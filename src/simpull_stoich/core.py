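"""Shared containers for two-channel SiMPull acquisitions.

Coordinates are 0-based ``(row, col)`` with pixel centers at integer
coordinates. Movies are frame-major stacks in camera counts.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

GREEN = "green"
FARRED = "farred"
CHANNELS = (GREEN, FARRED)

#: class sets used for step labels, per channel
FARRED_CLASSES = ("rejected", "1-step", "2-step", "3-and-higher")
GREEN_CLASSES = ("rejected", "1-step")
REJECTED = "rejected"


def classes_for(channel: str) -> tuple[str, ...]:
    if channel == GREEN:
        return GREEN_CLASSES
    if channel == FARRED:
        return FARRED_CLASSES
    raise ValueError(f"unknown channel {channel!r}")


@dataclass
class TirfMovie:
    """A single-channel TIRF frame stack.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Camera counts.
    channel : str
        ``"green"`` or ``"farred"``.
    frame_rate : float
        Frames per second.
    pixel_size : float
        Nanometers per pixel (used for the density cap on spot detection).
    """

    frames: np.ndarray
    channel: str = GREEN
    frame_rate: float = 20.0
    pixel_size: float = 108.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def write(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def read(cls, path: str | Path, channel: str = GREEN,
             frame_rate: float = 20.0, pixel_size: float = 108.0) -> "TirfMovie":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, channel=channel, frame_rate=frame_rate,
                   pixel_size=pixel_size)


@dataclass
class IntensityTrace:
    """Background-corrected integrated counts for one spot, one value per frame."""

    values: np.ndarray
    spot_id: int = -1
    channel: str = GREEN
    ok: bool = True  # False when the spot sits too close to the border

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


def derive_seed(seed: int, *tokens) -> int:
    """Derive a reproducible child seed (< 2**31) from a global seed.

    Stage/substream seeds are spawned via ``numpy.random.SeedSequence`` so
    independent pipeline stages can also be re-run standalone.
    """
    entropy = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tokens]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))
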