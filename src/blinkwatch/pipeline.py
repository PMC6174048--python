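"""End-to-end orchestration: frames -> eye state -> metrics -> score.

A run consumes a directory of image frames at a declared frame rate,
locates the eye region (fixed ROI by default; cascade detection for full
frames), classifies each crop open/closed, reduces the state stream to
blink and PERCLOS metrics, and feeds each metric window's mean upper and
lower dark-pixel ratios to the drowsiness network.  Every stage writes a
CSV so stages can be rerun and inspected in isolation; a run is a pure
function of (config, inputs, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, imaging, metrics, mlp, synthetic
from .errors import ConfigError, InputError, PipelineError
from .imaging import EyeState

logger = logging.getLogger("blinkwatch")

FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    fps: float = 10.0
    fixed_roi: list[tuple[int, int, int, int]] | None = None
    cascade_path: str | None = None
    ratio_threshold: float = 1.0
    debounce_min_run: int = 2
    window_s: float = 300.0
    stride_s: float = 60.0
    long_blink_threshold_s: float = 0.5
    model_path: str = "train"       # "train" = fit a model on the fly
    seed: int = 0
    abort_missing_frac: float = 0.5
    train_n: int = 2000             # used only when model_path == "train"
    train_epochs: int = 300

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if (self.fixed_roi is None) == (self.cascade_path is None):
            raise ConfigError(
                "exactly one detector mode required: fixed_roi or cascade_path"
            )
        for name in ("ratio_threshold", "window_s", "stride_s",
                     "long_blink_threshold_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.debounce_min_run < 1:
            raise ConfigError("debounce_min_run must be >= 1")
        if not 0 < self.abort_missing_frac <= 1:
            raise ConfigError("abort_missing_frac must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if not isinstance(payload, dict):
            raise ConfigError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_roi" in payload and payload["fixed_roi"] is not None:
            payload["fixed_roi"] = [tuple(b) for b in payload["fixed_roi"]]
        return cls(**payload)


def load_frames(input_dir: str | Path, fps: float):
    """Yield (index, gray_image) in lexicographic filename order.

    Unreadable files are skipped with a warning; their index stays
    reserved so timestamps of later frames are unaffected.
    """
    from PIL import Image

    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise InputError(f"not a directory: {input_dir}")
    files = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in FRAME_EXTENSIONS
    )
    if not files:
        raise InputError(f"no image frames found in {input_dir}")
    for index, path in enumerate(files):
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:  # Pillow raises several types here
            logger.warning("skipping unreadable frame %s: %s", path.name, exc)
            continue
        if arr.ndim == 3:
            arr = imaging.to_grayscale(arr[..., :3])
        yield index, arr.astype(np.uint8)


def _make_detector(config: PipelineConfig):
    if config.fixed_roi is not None:
        boxes = [detection.BoundingBox(*b) for b in config.fixed_roi]
        return detection.fixed_roi_detector(boxes)
    cascade = detection.load_cascade_json(config.cascade_path)
    return lambda frame: detection.detect_objects(frame, cascade)


def _resolve_model(config: PipelineConfig) -> mlp.MLPParams:
    if config.model_path != "train":
        return mlp.load_model(config.model_path)
    data = synthetic.generate_feature_dataset(config.train_n, seed=config.seed)
    params, _ = mlp.train(
        data, mlp.TrainConfig(epochs=config.train_epochs, seed=config.seed)
    )
    return params


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns paths of the five artifacts."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detector = _make_detector(config)

    rows = []
    n_missing = 0
    for index, frame in load_frames(config.input_dir, config.fps):
        dets = detector(frame)
        if dets:
            box = dets[0].box
            crop = frame[box.y : box.y + box.h, box.x : box.x + box.w]
            res = imaging.analyze_frame(
                crop, ratio_threshold=config.ratio_threshold
            )
            rows.append({
                "frame_index": index,
                "timestamp_s": index / config.fps,
                "eye_x": box.x, "eye_y": box.y,
                "eye_w": box.w, "eye_h": box.h,
                "upper_ratio": res.features.upper_ratio,
                "lower_ratio": res.features.lower_ratio,
                "compound": res.features.compound,
                "state": res.state.value,
                "otsu_t": res.otsu_t if res.otsu_t is not None else -1,
                "detected": 1,
            })
        else:
            n_missing += 1
            rows.append({
                "frame_index": index,
                "timestamp_s": index / config.fps,
                "eye_x": -1, "eye_y": -1, "eye_w": 0, "eye_h": 0,
                "upper_ratio": float("nan"),
                "lower_ratio": float("nan"),
                "compound": float("nan"),
                "state": EyeState.CLOSED.value,  # fail-safe
                "otsu_t": -1,
                "detected": 0,
            })
    if not rows:
        raise PipelineError("no frames processed")
    if n_missing / len(rows) > config.abort_missing_frac:
        raise PipelineError(
            f"eye region missing in {n_missing}/{len(rows)} frames "
            f"(> {config.abort_missing_frac:.0%}); aborting"
        )
    frames_df = pd.DataFrame(rows)
    frames_csv = out_dir / "frames.csv"
    frames_df.to_csv(frames_csv, index=False)

    seq = metrics.StateSequence(
        tuple(EyeState(s) for s in frames_df["state"]), fps=config.fps
    )
    seq = metrics.debounce_states(seq, config.debounce_min_run)
    events = metrics.extract_blinks(seq)
    blinks_csv = out_dir / "blinks.csv"
    pd.DataFrame(
        [{"start_frame": e.start_frame, "end_frame": e.end_frame,
          "duration_s": e.duration_s} for e in events],
        columns=["start_frame", "end_frame", "duration_s"],
    ).to_csv(blinks_csv, index=False)

    windows = metrics.rolling_metrics(
        seq, window_s=config.window_s, stride_s=config.stride_s,
        long_threshold_s=config.long_blink_threshold_s,
    )
    metrics_csv = out_dir / "metrics.csv"
    pd.DataFrame(
        [dataclasses.asdict(w) for w in windows],
        columns=["window_start_s", "window_end_s", "perclos",
                 "blink_freq_per_min", "long_blink_count",
                 "mean_blink_duration_s"],
    ).to_csv(metrics_csv, index=False)

    model = _resolve_model(config)
    drows = []
    for w in windows:
        f0 = round(w.window_start_s * config.fps)
        f1 = round(w.window_end_s * config.fps)
        sub = frames_df.iloc[f0:f1]
        sub = sub[sub["detected"] == 1]
        mean_upper = float(sub["upper_ratio"].mean()) if len(sub) else 0.0
        mean_lower = float(sub["lower_ratio"].mean()) if len(sub) else 0.0
        score = float(mlp.forward(model, [mean_upper, mean_lower]))
        drows.append({
            "window_start_s": w.window_start_s,
            "window_end_s": w.window_end_s,
            "mean_upper": mean_upper,
            "mean_lower": mean_lower,
            "score": score,
        })
    drowsiness_csv = out_dir / "drowsiness.csv"
    pd.DataFrame(
        drows,
        columns=["window_start_s", "window_end_s", "mean_upper",
                 "mean_lower", "score"],
    ).to_csv(drowsiness_csv, index=False)

    from . import __version__

    run_json = out_dir / "run.json"
    run_json.write_text(json.dumps({
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_frames": len(frames_df),
        "n_missing": n_missing,
        "n_blinks": len(events),
        "n_windows": len(windows),
    }, indent=1, default=str))

    return {
        "frames": frames_csv,
        "blinks": blinks_csv,
        "metrics": metrics_csv,
        "drowsiness": drowsiness_csv,
        "run": run_json,
    }
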