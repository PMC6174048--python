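"""Blink events, blink frequency, long-blink counts and PERCLOS.

A classified frame stream is reduced to the standard ocular drowsiness
indicators: every maximal run of CLOSED frames is one blink event; PERCLOS
is the fraction of frames closed within a time window; long blinks are
events at or above a duration cut (default 0.5 s, the conventional
microsleep-proximal threshold).  Frame intervals are half-open and
0-based throughout; events belong to the window containing their start
frame so no event is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .imaging import EyeState


@dataclass(frozen=True)
class StateSequence:
    """Per-frame eye states at a fixed frame rate."""

    states: tuple[EyeState, ...]
    fps: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if len(self.states) == 0:
            raise ParameterError("state sequence must be nonempty")
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def duration_s(self) -> float:
        return len(self.states) / self.fps

    def closed_mask(self) -> np.ndarray:
        return np.array([s is EyeState.CLOSED for s in self.states])


@dataclass(frozen=True)
class BlinkEvent:
    """One closed-eye episode over frames [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ParameterError("blink event must span at least one frame")


@dataclass(frozen=True)
class WindowMetrics:
    window_start_s: float
    window_end_s: float
    perclos: float
    blink_freq_per_min: float
    long_blink_count: int
    mean_blink_duration_s: float


def _runs(states: tuple[EyeState, ...]) -> list[tuple[EyeState, int, int]]:
    """(state, start, end) for each maximal run, half-open intervals."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] is not states[start]:
            runs.append((states[start], start, i))
            start = i
    return runs


def debounce_states(seq: StateSequence, min_run_frames: int = 2) -> StateSequence:
    """Absorb runs shorter than ``min_run_frames`` into the preceding run.

    Suppresses single-frame classifier flicker.  The first run is kept
    regardless of length (there is nothing before it to absorb into);
    ``min_run_frames=1`` is the identity.
    """
    if min_run_frames < 1:
        raise ParameterError("min_run_frames must be >= 1")
    merged: list[list] = []  # [state, length]
    for state, start, end in _runs(seq.states):
        length = end - start
        if not merged:
            merged.append([state, length])
        elif length < min_run_frames or state is merged[-1][0]:
            # absorbed runs take the preceding run's state
            merged[-1][1] += length
        else:
            merged.append([state, length])
    states: list[EyeState] = []
    for state, length in merged:
        states.extend([state] * length)
    return StateSequence(tuple(states), seq.fps, seq.start_time)


def extract_blinks(seq: StateSequence) -> list[BlinkEvent]:
    """One event per maximal CLOSED run, including runs touching the ends."""
    return [
        BlinkEvent(start, end, (end - start) / seq.fps)
        for state, start, end in _runs(seq.states)
        if state is EyeState.CLOSED
    ]


def blink_frequency(
    events: list[BlinkEvent], window_start_s: float, window_end_s: float,
    fps: float,
) -> float:
    """Events starting inside [start, end), scaled to events per minute."""
    if window_end_s <= window_start_s:
        raise ParameterError("window must have positive length")
    count = sum(
        1 for e in events
        if window_start_s <= e.start_frame / fps < window_end_s
    )
    return count * 60.0 / (window_end_s - window_start_s)


def count_long_blinks(
    events: list[BlinkEvent], long_threshold_s: float = 0.5
) -> int:
    """Blinks with duration >= threshold (boundary inclusive)."""
    if long_threshold_s <= 0:
        raise ParameterError("long_threshold_s must be > 0")
    return sum(1 for e in events if e.duration_s >= long_threshold_s)


def perclos(
    seq: StateSequence, window_start_s: float, window_end_s: float
) -> float:
    """Fraction of frames classified CLOSED within [start, end)."""
    if window_end_s <= window_start_s:
        raise ParameterError("window must have positive length")
    f0 = round((window_start_s - seq.start_time) * seq.fps)
    f1 = round((window_end_s - seq.start_time) * seq.fps)
    if f0 < 0 or f1 > len(seq.states) or f1 <= f0:
        raise ParameterError("window must lie within the sequence")
    closed = seq.closed_mask()[f0:f1]
    return float(closed.mean())


def rolling_metrics(
    seq: StateSequence,
    window_s: float = 300.0,
    stride_s: float = 60.0,
    long_threshold_s: float = 0.5,
) -> list[WindowMetrics]:
    """Windowed indicators: PERCLOS, blink rate, long blinks, mean duration.

    Windows are [k*stride, k*stride + window) for every k such that the
    window lies fully inside the sequence; events are assigned to the
    window containing their start frame.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ParameterError("window_s and stride_s must be > 0")
    if window_s > seq.duration_s + 1e-9:
        raise ParameterError("window_s exceeds the sequence duration")
    events = extract_blinks(seq)
    out: list[WindowMetrics] = []
    k = 0
    while True:
        w0 = seq.start_time + k * stride_s
        w1 = w0 + window_s
        if w1 > seq.start_time + seq.duration_s + 1e-9:
            break
        w1 = min(w1, seq.start_time + seq.duration_s)
        in_win = [
            e for e in events
            if w0 <= seq.start_time + e.start_frame / seq.fps < w1
        ]
        mean_dur = (
            float(np.mean([e.duration_s for e in in_win])) if in_win else 0.0
        )
        out.append(
            WindowMetrics(
                window_start_s=w0,
                window_end_s=w1,
                perclos=perclos(seq, w0, w1),
                blink_freq_per_min=len(in_win) * 60.0 / (w1 - w0),
                long_blink_count=count_long_blinks(in_win, long_threshold_s)
                if in_win else 0,
                mean_blink_duration_s=mean_dur,
            )
        )
        k += 1
    return out


def plot_signal_trace(frames_df, ax=None, compound_scale: float = 3.0):
    """Plot upper/lower ratios and the scaled compound signal over time.

    ``frames_df`` is the per-frame feature log (needs ``frame_index``,
    ``upper_ratio``, ``lower_ratio``, ``compound`` columns).  The compound
    trace is multiplied by ``compound_scale`` (default 3) purely for
    display, so open/closed transitions stand out at the ratio scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    x = frames_df["frame_index"]
    ax.plot(x, frames_df["upper_ratio"], label="upper dark ratio")
    ax.plot(x, frames_df["lower_ratio"], label="lower dark ratio")
    ax.plot(
        x,
        compound_scale * frames_df["compound"].clip(upper=2.0),
        label=f"compound x{compound_scale:g} (clipped)",
        alpha=0.7,
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("ratio")
    ax.legend(loc="upper right", fontsize=8)
    return ax
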