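"""Sliding-window segmentation of annotated recordings.

Recordings are cut into fixed-length, overlapping windows (default 250 ms /
256 samples at 1024 Hz, stepped by 125 ms / 128 samples) and each window is
assigned a single gesture label.  Two labelling policies exist: ``pure``
drops any window that straddles a class transition (clean exemplars for
training) and ``majority`` keeps every window with its modal per-sample
label (contiguous streams for whole-recording prediction traces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .synthetic import Recording

DEFAULT_WINDOW_MS = 250.0
DEFAULT_STEP_MS = 125.0


@dataclass
class Segment:
    """One fixed-length window across all channels."""

    samples: np.ndarray        # (n_channels, window_samples)
    window_index: int
    start_sample: int          # 0-based; span is [start, start + window)
    label: Optional[int] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-d (channels x window)")

    @property
    def window_samples(self) -> int:
        return self.samples.shape[1]


def window_params(fs: float, window_ms: float, step_ms: float):
    """Convert window/step durations to sample counts.

    (1024 Hz, 250 ms, 125 ms) -> (256, 128).  A step longer than the window
    is permitted (gapped windows) but warned about.
    """
    if fs <= 0 or window_ms <= 0 or step_ms <= 0:
        raise ValueError("fs, window_ms and step_ms must all be positive")
    window_samples = int(round(fs * window_ms / 1000.0))
    step_samples = int(round(fs * step_ms / 1000.0))
    if step_samples > window_samples:
        warnings.warn("step exceeds window length: windows will not overlap "
                      "and samples will be skipped", stacklevel=2)
    return window_samples, step_samples


def n_segments(length: int, window_samples: int, step_samples: int) -> int:
    if length < window_samples:
        return 0
    return (length - window_samples) // step_samples + 1


def segment_recording(recording: Recording, window_samples: int = 256,
                      step_samples: int = 128) -> List[Segment]:
    """Cut a recording into overlapping windows (labels assigned separately).

    Window k covers samples [k*step, k*step + window); trailing samples that
    do not fill a whole window are discarded.
    """
    if window_samples <= 0 or step_samples <= 0:
        raise ValueError("window_samples and step_samples must be positive")
    L = recording.n_samples
    segments = []
    for k in range(n_segments(L, window_samples, step_samples)):
        start = k * step_samples
        segments.append(Segment(
            samples=recording.channels[:, start:start + window_samples],
            window_index=k,
            start_sample=start,
            subject_id=recording.subject.subject_id,
        ))
    return segments


def trim_transition_margin(label_track: np.ndarray, fs: float,
                           margin_s: float) -> np.ndarray:
    """Invalidate samples within ``margin_s`` of every label transition.

    Returns a copy of the track with 0 (the invalid marker) around each
    class boundary; ``assign_labels`` drops any window touching an invalid
    sample.  Excludes the effort ramps at gesture on/offsets from training
    data, keeping only steady-state windows.
    """
    lab = np.asarray(label_track).copy()
    if margin_s < 0:
        raise ValueError("margin_s must be non-negative")
    m = int(round(margin_s * fs))
    if m == 0:
        return lab
    changes = np.where(np.diff(np.asarray(label_track)) != 0)[0]
    for c in changes:
        lab[max(0, c - m + 1):c + 1 + m] = 0
    return lab


def assign_labels(segments: Sequence[Segment], label_track: np.ndarray,
                  policy: str = "pure") -> List[Segment]:
    """Assign one class label per window from the per-sample label track.

    ``pure``: windows containing more than one distinct label are dropped.
    ``majority``: the modal per-sample label wins; ties break toward the
    label whose first occurrence in the window is earliest.  Windows
    touching invalidated samples (label 0, see ``trim_transition_margin``)
    are dropped under both policies.
    """
    if policy not in ("pure", "majority"):
        raise ValueError("policy must be 'pure' or 'majority'")
    label_track = np.asarray(label_track)
    out = []
    for seg in segments:
        span = label_track[seg.start_sample:seg.start_sample + seg.window_samples]
        if len(span) < seg.window_samples:
            raise ValueError(f"label track does not cover window {seg.window_index}")
        if np.any(span == 0):
            continue
        values, counts = np.unique(span, return_counts=True)
        if policy == "pure":
            if len(values) > 1:
                continue
            label = int(values[0])
        else:
            top = counts.max()
            tied = values[counts == top]
            if len(tied) == 1:
                label = int(tied[0])
            else:
                # earliest-starting label among the tied ones
                firsts = {int(v): int(np.argmax(span == v)) for v in tied}
                label = min(firsts, key=firsts.get)
        seg = Segment(samples=seg.samples, window_index=seg.window_index,
                      start_sample=seg.start_sample, label=label,
                      subject_id=seg.subject_id)
        out.append(seg)
    return out


def segment_and_label(recording: Recording, window_samples: int = 256,
                      step_samples: int = 128, policy: str = "pure",
                      event_margin_s: float = 0.0) -> List[Segment]:
    """Convenience: segment a recording and label the windows in one call."""
    segs = segment_recording(recording, window_samples, step_samples)
    track = trim_transition_margin(recording.labels, recording.fs,
                                   event_margin_s)
    return assign_labels(segs, track, policy=policy)
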