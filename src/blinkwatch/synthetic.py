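"""Seeded generators for eye-region image sequences and feature datasets.

Real driver-monitoring footage is not redistributable, so the test bed is
synthetic: small near-frontal eye crops whose geometry reproduces the
contrast pattern the classifier relies on.  An OPEN crop places a dark
iris/pupil disc and a lash arc in the upper half on a light sclera; a
CLOSED crop covers the upper half with a light eyelid and drops a dark
lash band into the lower half.  Blink schedules follow a Poisson onset
process with truncated-normal durations, and a drowsiness level in [0, 1]
ramps up blink durations and long-blink probability.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .imaging import EyeState

#: Feature-benchmark centroids (upper_mean, lower_mean): an alert window is
#: dominated by open frames (dark mass up top), a drowsy window by closed
#: frames (dark lash mass below).  Calibrated once and frozen.
ALERT_CENTROID = (0.32, 0.04)
DROWSY_CENTROID = (0.10, 0.12)
#: Default Gaussian noise on benchmark features, in ratio units.
FEATURE_NOISE_SD = 0.05


@dataclass(frozen=True)
class EyeImageParams:
    """Geometry and photometry of a rendered eye crop."""

    width: int = 64
    height: int = 32
    pupil_radius_frac: float = 0.35   # of height
    iris_gray: int = 40
    sclera_gray: int = 220
    eyelid_gray: int = 200
    lash_gray: int = 60
    noise_sd: float = 8.0             # intensity units
    illumination_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ParameterError("width and height must be >= 8")
        for name in ("iris_gray", "sclera_gray", "eyelid_gray", "lash_gray"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ParameterError(f"{name} must be in [0, 255], got {v}")
        if self.iris_gray >= self.sclera_gray:
            raise ParameterError("iris_gray must be darker than sclera_gray")
        if self.lash_gray >= self.eyelid_gray:
            raise ParameterError("lash_gray must be darker than eyelid_gray")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 < self.pupil_radius_frac <= 1:
            raise ParameterError("pupil_radius_frac must be in (0, 1]")
        if self.illumination_gain <= 0:
            raise ParameterError("illumination_gain must be > 0")


@dataclass(frozen=True)
class BlinkSchedule:
    """Stochastic blink process driving a synthetic session."""

    fps: float = 10.0
    duration_s: float = 60.0
    blink_rate_per_min: float = 12.0
    blink_duration_mean_s: float = 0.25
    blink_duration_sd_s: float = 0.08
    long_blink_prob: float = 0.05
    long_blink_duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ParameterError("fps and duration_s must be > 0")
        if min(self.blink_rate_per_min, self.blink_duration_mean_s,
               self.blink_duration_sd_s, self.long_blink_prob,
               self.long_blink_duration_s) < 0:
            raise ParameterError("rates, durations and probabilities must be >= 0")
        if self.long_blink_prob > 1:
            raise ParameterError("long_blink_prob must be <= 1")

    @property
    def n_frames(self) -> int:
        return round(self.fps * self.duration_s)


@dataclass(frozen=True)
class TrueBlink:
    """Ground-truth closed-eye episode, frames [start, end)."""

    start_frame: int
    end_frame: int
    duration_s: float


@dataclass
class SyntheticSession:
    frames: list[np.ndarray]
    true_states: list[EyeState]
    true_blinks: list[TrueBlink]
    drowsiness_profile: list[float]
    fps: float = 10.0
    params: EyeImageParams = field(default_factory=EyeImageParams)


def generate_eye_image(
    state: EyeState, params: EyeImageParams = EyeImageParams(), seed: int = 0
) -> np.ndarray:
    """Render one eye crop in the given state.

    OPEN: dark disc centered in the upper half plus a lash arc above it.
    CLOSED: light eyelid over the upper half, dark lash band in the lower
    half (the lid folds the lashes downward).  Zero-mean Gaussian noise
    with sd ``noise_sd`` is added after an overall ``illumination_gain``,
    then the result is clipped to [0, 255].
    """
    if not isinstance(state, EyeState):
        raise ParameterError(f"state must be an EyeState, got {state!r}")
    h, w = params.height, params.width
    img = np.full((h, w), float(params.sclera_gray))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    if state is EyeState.OPEN:
        # iris/pupil disc in the upper half
        cy, cx = 0.30 * h, 0.5 * w
        r = params.pupil_radius_frac * h
        disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
        img[disc] = params.iris_gray
        # lash arc: shallow parabola hugging the top of the disc
        arc_row = np.rint(
            0.06 * h + 0.10 * h * ((cols[0] - cx) / (0.5 * w)) ** 2
        ).astype(int)
        for c in range(w):
            rr = arc_row[c]
            if 0 <= rr < h:
                img[rr, c] = params.lash_gray
    else:
        img[: h // 2, :] = params.eyelid_gray
        # closed-lid lash band, 3 rows thick so cleanup keeps it
        band0 = int(0.58 * h)
        img[band0 : band0 + 3, :] = params.lash_gray
    img *= params.illumination_gain
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.rint(img).clip(0, 255).astype(np.uint8)


def _blinks_from_states(states: list[EyeState], fps: float) -> list[TrueBlink]:
    """Maximal CLOSED runs, as ground-truth blink events."""
    blinks: list[TrueBlink] = []
    start = None
    for i, s in enumerate(states):
        if s is EyeState.CLOSED and start is None:
            start = i
        elif s is EyeState.OPEN and start is not None:
            blinks.append(TrueBlink(start, i, (i - start) / fps))
            start = None
    if start is not None:
        n = len(states)
        blinks.append(TrueBlink(start, n, (n - start) / fps))
    return blinks


def draw_blink_onsets(
    rng: np.random.Generator, rate_per_min: float, duration_s: float
) -> list[float]:
    """Poisson-process onset times (exponential inter-arrivals), seconds.

    The onset *count* is Poisson at the scheduled rate; note that after
    durations are attached, overlapping blinks merge, so the realized
    event count in a state sequence is slightly below the onset count.
    """
    onsets: list[float] = []
    rate_per_s = rate_per_min / 60.0
    if rate_per_s <= 0:
        return onsets
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= duration_s:
            return onsets
        onsets.append(t)


def generate_state_sequence(
    schedule: BlinkSchedule, drowsiness_level: float = 0.0
) -> tuple[list[EyeState], list[TrueBlink]]:
    """Draw the per-frame OPEN/CLOSED ground truth for a schedule.

    Blink onsets come from a Poisson process at ``blink_rate_per_min``;
    each blink's duration is truncated-normal (at least one frame), and
    with probability ``long_blink_prob`` the blink is stretched to at
    least ``long_blink_duration_s``.  ``drowsiness_level`` in [0, 1]
    ramps the duration mean by a factor ``1 + 2*level`` and adds
    ``0.35 * level`` to the long-blink probability (clipped at 1); the
    random draws themselves do not depend on the level, so for a fixed
    seed the closed-frame set grows monotonically with the level.
    Overlapping blinks merge into one closed run.
    """
    if not 0.0 <= drowsiness_level <= 1.0:
        raise ParameterError("drowsiness_level must be in [0, 1]")
    rng = np.random.default_rng(schedule.seed)
    n = schedule.n_frames
    closed = np.zeros(n, dtype=bool)
    mean_eff = schedule.blink_duration_mean_s * (1.0 + 2.0 * drowsiness_level)
    long_prob_eff = min(1.0, schedule.long_blink_prob + 0.35 * drowsiness_level)
    for t in draw_blink_onsets(
        rng, schedule.blink_rate_per_min, schedule.duration_s
    ):
        z = rng.standard_normal()
        u = rng.uniform()
        dur = mean_eff + schedule.blink_duration_sd_s * z
        if u < long_prob_eff:
            dur = max(dur, schedule.long_blink_duration_s)
        dur = max(dur, 1.0 / schedule.fps)  # at least one frame
        start = int(t * schedule.fps)
        end = min(n, max(start + 1, int(math.ceil((t + dur) * schedule.fps))))
        closed[start:end] = True
    states = [EyeState.CLOSED if c else EyeState.OPEN for c in closed]
    return states, _blinks_from_states(states, schedule.fps)


def _frame_seed(session_seed: int, frame_index: int) -> int:
    """Stable per-frame seed so any frame is reproducible in isolation."""
    ss = np.random.SeedSequence([int(session_seed), int(frame_index)])
    return int(ss.generate_state(1)[0])


def render_session(
    schedule: BlinkSchedule,
    params: EyeImageParams = EyeImageParams(),
    drowsiness_level: float = 0.0,
) -> SyntheticSession:
    """Render a full synthetic session with ground truth attached."""
    states, blinks = generate_state_sequence(schedule, drowsiness_level)
    frames = [
        generate_eye_image(s, params, seed=_frame_seed(schedule.seed, i))
        for i, s in enumerate(states)
    ]
    return SyntheticSession(
        frames=frames,
        true_states=states,
        true_blinks=blinks,
        drowsiness_profile=[drowsiness_level] * len(states),
        fps=schedule.fps,
        params=params,
    )


def export_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a session as PNG frames + ground_truth.csv + blinks.csv."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ndigits = max(4, len(str(len(session.frames) - 1)))
    for i, frame in enumerate(session.frames):
        Image.fromarray(frame, mode="L").save(out / f"frame_{i:0{ndigits}d}.png")
    with open(out / "ground_truth.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame_index", "true_state", "drowsiness_level"])
        for i, (s, d) in enumerate(
            zip(session.true_states, session.drowsiness_profile)
        ):
            wr.writerow([i, s.value, d])
    with open(out / "blinks.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["start_frame", "end_frame", "duration_s"])
        for b in session.true_blinks:
            wr.writerow([b.start_frame, b.end_frame, b.duration_s])
    return out


def generate_feature_dataset(
    n: int,
    noise_sd: float = FEATURE_NOISE_SD,
    seed: int = 0,
) -> np.ndarray:
    """Balanced labeled feature records ``(upper_mean, lower_mean, label)``.

    Half the records scatter around the alert centroid (label 0.0), half
    around the drowsy centroid (label 1.0), with isotropic Gaussian noise
    of sd ``noise_sd``; odd ``n`` gives the extra record to the alert
    class.  Rows are shuffled deterministically by ``seed``.  Returns an
    ``(n, 3)`` float array.
    """
    if n < 10:
        raise ParameterError(f"need n >= 10, got {n}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_drowsy = n // 2
    n_alert = n - n_drowsy
    alert = np.tile(ALERT_CENTROID, (n_alert, 1))
    drowsy = np.tile(DROWSY_CENTROID, (n_drowsy, 1))
    X = np.vstack([alert, drowsy])
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    y = np.concatenate([np.zeros(n_alert), np.ones(n_drowsy)])
    order = rng.permutation(n)
    return np.column_stack([X, y])[order]


def save_feature_dataset(data: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["upper_mean", "lower_mean", "label"])
        for row in data:
            wr.writerow([repr(float(row[0])), repr(float(row[1])), float(row[2])])
    return path


def load_feature_dataset(path: str | Path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["upper_mean", "lower_mean", "label"]
    if list(df.columns) != expected:
        raise ParameterError(f"feature CSV must have columns {expected}")
    return df.to_numpy(dtype=float)
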