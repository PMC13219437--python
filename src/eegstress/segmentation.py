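"""Fixed-duration windowing of multichannel EEG recordings.

Two schemes are supported: non-overlapping windows that tile a prefix of the
recording, and overlapping (sliding) windows that advance by a fixed step.
Trailing partial windows are always discarded — a 480 s recording cut into
10 s non-overlapping windows yields exactly 48 segments per channel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MONTAGE = ("AF7", "AF8", "TP7", "TP8")


@dataclass(frozen=True)
class EEGRecording:
    """One subject's multichannel signal.

    ``samples`` is a channels x time float array; every channel has the same
    length and contains no non-finite values.
    """

    subject_id: str
    channel_names: tuple[str, ...]
    fs: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{samples.shape[0]} sample rows for "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(samples).all():
            raise ValueError(f"non-finite samples in recording {self.subject_id!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SegmentationScheme:
    """Windowing parameters.

    mode
        ``"non_overlapping"``: consecutive disjoint windows of ``window_s``
        seconds.  ``"overlapping"``: windows of ``window_s`` seconds whose
        starts advance by ``step_s`` seconds (``window_s == step_s``
        degenerates to the non-overlapping scheme).
    """

    mode: str = "non_overlapping"
    window_s: float = 10.0
    step_s: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("non_overlapping", "overlapping"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if self.mode == "overlapping" and self.window_s < self.step_s:
            raise ValueError("overlapping mode requires window_s >= step_s")

    @property
    def effective_step_s(self) -> float:
        return self.window_s if self.mode == "non_overlapping" else self.step_s


@dataclass(frozen=True)
class Segment:
    """One windowed slice of one channel."""

    subject_id: str
    channel: str
    start_s: float
    fs: float
    samples: np.ndarray = field(repr=False)


def count_segments(duration_s: float, scheme: SegmentationScheme) -> int:
    """Closed-form number of windows per channel for a given duration.

    Non-overlapping: floor(duration / window).  Overlapping:
    floor((duration - window) / step) + 1 when the recording is at least one
    window long, else 0.
    """
    if duration_s < scheme.window_s:
        return 0
    step = scheme.effective_step_s
    # small epsilon guards float representation of exact multiples
    return int(math.floor((duration_s - scheme.window_s) / step + 1e-9)) + 1


def segment_recording(rec: EEGRecording, scheme: SegmentationScheme) -> list[Segment]:
    """Cut every channel of ``rec`` into windows under ``scheme``.

    Returns segments ordered channel-major, then by start time. A recording
    shorter than one window yields an empty list and a logged warning rather
    than an error.
    """
    window_n = int(round(scheme.window_s * rec.fs))
    step_n = int(round(scheme.effective_step_s * rec.fs))
    if window_n < 1 or step_n < 1:
        raise ValueError("window and step must span at least one sample")
    n = rec.n_samples
    if n < window_n:
        logger.warning(
            "recording %s (%.1f s) shorter than window (%.1f s); no segments",
            rec.subject_id, rec.duration_s, scheme.window_s,
        )
        return []
    starts = range(0, n - window_n + 1, step_n)
    out: list[Segment] = []
    for ch_idx, ch in enumerate(rec.channel_names):
        row = rec.samples[ch_idx]
        for s0 in starts:
            out.append(
                Segment(
                    subject_id=rec.subject_id,
                    channel=ch,
                    start_s=s0 / rec.fs,
                    fs=rec.fs,
                    samples=row[s0 : s0 + window_n],
                )
            )
    return out
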