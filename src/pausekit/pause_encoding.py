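"""Binary pause-sequence encoding, segmentation, statistics and plots.

The pause sequence is the pipeline's core feature: one 0/1 label per
0.03 s frame (1 = voiced, 0 = non-voiced), used directly as classifier
input after being cut into fixed-length 4 s segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SEGMENT_DURATION = 4.0

__all__ = [
    "PauseSequence",
    "SegmentSet",
    "PauseStats",
    "encode",
    "segment",
    "pause_stats",
    "plot_comparison",
    "write_sequence_csv",
    "read_sequence_csv",
]


@dataclass
class PauseSequence:
    """Ordered voiced (1) / non-voiced (0) frame labels at a fixed frame step."""

    labels: np.ndarray
    frame_duration: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValueError("pause sequence must be nonempty")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("pause labels must be 0 or 1")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")

    @property
    def duration(self) -> float:
        return self.labels.size * self.frame_duration

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class SegmentSet:
    """Fixed-length segments of a pause sequence, in temporal order."""

    segments: np.ndarray  # (n_segments, segment_frames)
    segment_frames: int
    frame_duration: float
    subject_id: str = ""
    label: int | None = None
    dropped_frames: int = 0

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.int64)
        if self.segments.ndim != 2 or self.segments.shape[1] != self.segment_frames:
            raise ValueError("segments must be (n, segment_frames)")

    def __len__(self) -> int:
        return self.segments.shape[0]


@dataclass
class PauseStats:
    """Run-length pause summary of one sequence."""

    pause_count: int
    mean_pause_duration: float  # seconds; 0 when there are no pauses
    pause_time_fraction: float
    voiced_fraction: float


def encode(decisions: np.ndarray, frame_duration: float, subject_id: str = "") -> PauseSequence:
    """Package per-frame VAD labels as a pause sequence (identity + metadata)."""
    return PauseSequence(np.asarray(decisions), frame_duration, subject_id)


def segment(seq: PauseSequence, segment_duration: float = DEFAULT_SEGMENT_DURATION) -> SegmentSet:
    """Cut a pause sequence into consecutive fixed-length segments.

    ``segment_frames = floor(segment_duration / frame_duration)`` (133
    for 4 s at 0.03 s frames); the trailing remainder shorter than one
    segment is dropped.
    """
    if segment_duration < seq.frame_duration:
        raise ValueError("segment_duration must be at least one frame long")
    seg_frames = int(segment_duration / seq.frame_duration)
    n_seg = len(seq) // seg_frames
    if n_seg == 0:
        raise ValueError(
            f"sequence of {len(seq)} frames is shorter than one segment ({seg_frames} frames)"
        )
    used = n_seg * seg_frames
    return SegmentSet(
        segments=seq.labels[:used].reshape(n_seg, seg_frames),
        segment_frames=seg_frames,
        frame_duration=seq.frame_duration,
        subject_id=seq.subject_id,
        dropped_frames=len(seq) - used,
    )


def pause_stats(seq: PauseSequence) -> PauseStats:
    """Count maximal runs of non-voiced frames and summarize pause time."""
    x = seq.labels
    is_pause = x == 0
    # a pause starts where 0 follows a 1 or the sequence start
    starts = is_pause & np.r_[True, x[:-1] == 1]
    pause_count = int(starts.sum())
    n_pause_frames = int(is_pause.sum())
    pause_fraction = n_pause_frames / x.size
    mean_dur = (n_pause_frames * seq.frame_duration / pause_count) if pause_count else 0.0
    return PauseStats(
        pause_count=pause_count,
        mean_pause_duration=mean_dur,
        pause_time_fraction=pause_fraction,
        voiced_fraction=1.0 - pause_fraction,
    )


def plot_comparison(
    sequences: list[PauseSequence],
    groups: list[int] | None = None,
    out_path: str | Path = "pause_comparison.png",
    group_names: dict[int, str] | None = None,
) -> Path:
    """Raster plot of voiced/non-voiced frames over time, grouped by label.

    Voiced frames are drawn as blue markers, non-voiced as red, one row
    per sequence; sequences sharing a group label are stacked in the
    same panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not sequences:
        raise ValueError("need at least one sequence to plot")
    if groups is None:
        groups = [0] * len(sequences)
    group_names = group_names or {0: "non-AD", 1: "AD"}
    uniq = sorted(set(groups))
    fig, axes = plt.subplots(len(uniq), 1, figsize=(10, 2 + 1.2 * len(sequences)), squeeze=False)
    for ax, g in zip(axes.ravel(), uniq):
        row = 0
        for s, grp in zip(sequences, groups):
            if grp != g:
                continue
            t = np.arange(len(s)) * s.frame_duration
            voiced = s.labels == 1
            ax.plot(t[voiced], np.full(voiced.sum(), row), "*", color="tab:blue", ms=3)
            ax.plot(t[~voiced], np.full((~voiced).sum(), row), "*", color="tab:red", ms=3)
            row += 1
        ax.set_title(group_names.get(g, str(g)))
        ax.set_ylabel("recording")
        ax.set_yticks(range(row))
    axes.ravel()[-1].set_xlabel("time (s)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path


def write_sequence_csv(path: str | Path, seq: PauseSequence) -> None:
    """One row per frame: ``frame_index,t_start,label``."""
    idx = np.arange(len(seq))
    pd.DataFrame(
        {"frame_index": idx, "t_start": idx * seq.frame_duration, "label": seq.labels}
    ).to_csv(path, index=False)


def read_sequence_csv(path: str | Path, subject_id: str = "") -> PauseSequence:
    df = pd.read_csv(path)
    if len(df) > 1:
        dt = float(df["t_start"].iloc[1] - df["t_start"].iloc[0])
    else:
        dt = 0.03
    return PauseSequence(df["label"].to_numpy(), dt, subject_id)
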