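"""Core data containers shared across the pipeline.

A :class:`TimeLapseStack` holds the two Incucyte-style channels
(phase contrast + green fluorescence) as (T, H, W) arrays with the
acquisition times in hours.  A :class:`SegMask` is one frame's binary
spheroid mask together with its provenance, so downstream statistics
can always say whether they were computed on network output, on the
classical baseline or on simulation ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

MASK_SOURCES = ("pnet", "baseline", "ground_truth")


@dataclass
class TimeLapseStack:
    """Multi-channel time-lapse stack with timestamps.

    phase, green : (T, H, W) arrays (16-bit in files, any float in memory)
    times_h      : acquisition time of each frame, hours from t=0
    meta         : free-form metadata (pixel size, frame interval, subject)
    """

    phase: np.ndarray
    green: np.ndarray
    times_h: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phase = np.asarray(self.phase)
        self.green = np.asarray(self.green)
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.phase.shape != self.green.shape:
            raise ValueError("phase and green channels must share a shape")
        if self.phase.ndim != 3:
            raise ValueError("expected (T, H, W) stacks")
        if len(self.times_h) != self.phase.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.times_h) < 0):
            raise ValueError("timestamps must be ascending")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.phase.shape[1:]


@dataclass
class SegMask:
    """Binary spheroid mask for a single frame."""

    pixels: np.ndarray
    frame_index: int = 0
    source: str = "ground_truth"
    empty_warning: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask pixels must be binary (0/1)")
        if self.source not in MASK_SOURCES:
            raise ValueError(f"source must be one of {MASK_SOURCES}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return self.area == 0


def write_stack(path: str | Path, stack: TimeLapseStack) -> None:
    """Write a stack as a multi-page TIFF, channel-interleaved per frame.

    Page order is (frame0 phase, frame0 green, frame1 phase, ...); the
    timestamps are stored in the ImageDescription as JSON.
    """
    import json

    path = Path(path)
    pages = np.empty((2 * stack.n_frames,) + stack.frame_shape, dtype=np.uint16)
    pages[0::2] = np.clip(stack.phase, 0, 65535).astype(np.uint16)
    pages[1::2] = np.clip(stack.green, 0, 65535).astype(np.uint16)
    desc = json.dumps({"times_h": list(stack.times_h), "meta": stack.meta})
    tifffile.imwrite(path, pages, description=desc)


def read_stack(path: str | Path) -> TimeLapseStack:
    import json

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    info = json.loads(desc) if desc else {"times_h": None, "meta": {}}
    phase = pages[0::2].astype(np.float32)
    green = pages[1::2].astype(np.float32)
    times = info.get("times_h")
    if times is None:
        times = np.arange(phase.shape[0], dtype=float)
    return TimeLapseStack(phase=phase, green=green, times_h=np.asarray(times),
                          meta=info.get("meta", {}))


def write_masks(path: str | Path, masks: list[SegMask]) -> None:
    pages = np.stack([m.pixels for m in masks]).astype(np.uint8)
    tifffile.imwrite(Path(path), pages)


def read_masks(path: str | Path, source: str = "ground_truth") -> list[SegMask]:
    pages = tifffile.imread(Path(path))
    if pages.ndim == 2:
        pages = pages[None]
    return [SegMask(pixels=(p > 0).astype(np.uint8), frame_index=i, source=source)
            for i, p in enumerate(pages)]
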