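"""Lead-on gating and fixed-window framing of continuous recordings.

A recording is only meaningful while the driver's hands are on the
electrodes; a per-sample lead-on mask (hardware detector, emulated here)
gates the stream into maximal contact runs.  Each run is partitioned into
5 s analysis frames advancing by 1 s (4 s overlap), so a first decision is
available five seconds after contact and is renewed every second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EcgStream", "Frame", "contact_runs", "make_frames", "frame_stream"]

FRAME_S = 5.0
STEP_S = 1.0


@dataclass
class EcgStream:
    """Raw continuous signal + sampling rate + lead-on mask."""

    samples: np.ndarray
    fs: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.ones(self.samples.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size != self.samples.size:
            raise ValueError("mask length must equal samples length")


@dataclass
class Frame:
    """One 5 s analysis window, entirely inside a single contact run."""

    samples: np.ndarray
    start_s: float
    fs: float
    stream: EcgStream | None = field(default=None, repr=False)

    @property
    def end_s(self) -> float:
        return self.start_s + self.samples.size / self.fs


def contact_runs(stream: EcgStream) -> list[tuple[int, int]]:
    """Maximal half-open sample intervals [start, end) where the mask is true."""
    m = stream.mask
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [m.size]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if m[a]]


def make_frames(run: tuple[int, int], stream: EcgStream,
                frame_s: float = FRAME_S, step_s: float = STEP_S) -> list[Frame]:
    """Partition one contact run into fixed frames.

    Frames are anchored at the run start and advance by ``step_s``; trailing
    partial windows are dropped.  Runs shorter than one frame yield nothing.
    """
    start, end = run
    fs = stream.fs
    flen = int(round(frame_s * fs))
    step = int(round(step_s * fs))
    if flen <= 0 or step <= 0:
        raise ValueError("frame and step lengths must be positive")
    frames = []
    for i0 in range(start, end - flen + 1, step):
        frames.append(Frame(samples=stream.samples[i0:i0 + flen],
                            start_s=i0 / fs, fs=fs, stream=stream))
    return frames


def frame_stream(stream: EcgStream, frame_s: float = FRAME_S,
                 step_s: float = STEP_S) -> list[Frame]:
    """All frames of all contact runs, in chronological order."""
    out: list[Frame] = []
    for run in contact_runs(stream):
        out.extend(make_frames(run, stream, frame_s, step_s))
    return out
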