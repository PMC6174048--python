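"""Cascade object detection over integral images.

Implements the evaluation half of the classic boosted-cascade detector:
integral images give any rectangle's pixel sum in four lookups; Haar-like
rectangle features score sliding windows; a window survives only if every
stage's summed feature contributions clear that stage's threshold, with
evaluation short-circuiting at the first failing stage.  Cascade
*training* is out of scope — cascades are loaded from JSON (native
format) or from the old-style OpenCV XML dialect, and a small hand-built
dark-disc cascade ships with the package for testing.

Feature scores are normalized by ``window_area * window_sd`` (the window
standard deviation comes from integral images of x and x**2), the
standard practice that makes thresholds robust to contrast changes.  When
no squared integral image is supplied, sd falls back to 1 so scores are
plain mean-normalized rectangle sums, convenient for hand-checked tests.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import BoundsError, ConfigError, FormatError, ParameterError


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based top-left corner, width/height in pixels."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ParameterError("box width and height must be >= 1")

    @property
    def area(self) -> int:
        return self.w * self.h


@dataclass(frozen=True)
class HaarFeature:
    """Weighted rectangles + a threshold deciding the stage contribution.

    ``rects`` are (x, y, w, h, weight) in coordinates of the cascade's
    base window.  If the feature's normalized score is below ``threshold``
    the feature contributes ``left_val`` to its stage sum, else
    ``right_val``.
    """

    rects: tuple[tuple[int, int, int, int, float], ...]
    threshold: float
    left_val: float
    right_val: float

    def __post_init__(self) -> None:
        if len(self.rects) < 2:
            raise FormatError("a Haar feature needs at least 2 rectangles")


@dataclass(frozen=True)
class CascadeStage:
    features: tuple[HaarFeature, ...]
    stage_threshold: float

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise FormatError("a stage needs at least one feature")


@dataclass(frozen=True)
class Cascade:
    window_w: int
    window_h: int
    stages: tuple[CascadeStage, ...]


def integral_image(img: np.ndarray) -> np.ndarray:
    """(H+1) x (W+1) cumulative-sum table with a zero-padded first row/col.

    ``table[i, j]`` holds the sum of all pixels strictly above and left of
    (i, j), so any rectangle sum needs four lookups.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ParameterError("empty image")
    table = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(img, axis=0, dtype=np.int64), axis=1, out=table[1:, 1:])
    return table


def rect_sum(ii: np.ndarray, box: BoundingBox) -> int:
    """Exact pixel sum inside ``box`` from the integral table."""
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
        raise BoundsError(f"box {box} outside {h}x{w} image")
    y0, y1 = box.y, box.y + box.h
    x0, x1 = box.x, box.x + box.w
    return int(ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0])


def _window_sd(ii: np.ndarray, ii_sq: np.ndarray, window: BoundingBox) -> float:
    n = window.area
    mean = rect_sum(ii, window) / n
    var = rect_sum(ii_sq, window) / n - mean * mean
    return math.sqrt(max(var, 0.0))


def _scaled_rect(
    rect: tuple[int, int, int, int, float],
    window: BoundingBox,
    sx: float,
    sy: float,
) -> BoundingBox:
    x, y, w, h, _ = rect
    return BoundingBox(
        x=window.x + round(x * sx),
        y=window.y + round(y * sy),
        w=max(1, round(w * sx)),
        h=max(1, round(h * sy)),
    )


def run_cascade(
    ii: np.ndarray,
    window: BoundingBox,
    cascade: Cascade,
    ii_sq: np.ndarray | None = None,
) -> bool:
    """Accept/reject one window; short-circuits at the first failed stage.

    An empty cascade accepts everything (vacuous conjunction).  Feature
    scores are mean-normalized: each rectangle contributes
    ``weight * (rect_sum - rect_area * window_mean)``, so any constant
    window scores exactly 0 at every scale; the sum is divided by
    ``window_area * sd`` with ``sd = 1`` when ``ii_sq`` is omitted (sd is
    floored at 1 regardless, so near-constant windows do not blow up).
    """
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    if window.x < 0 or window.y < 0 or window.x + window.w > w \
            or window.y + window.h > h:
        raise BoundsError(f"window {window} outside {h}x{w} image")
    sx = window.w / cascade.window_w
    sy = window.h / cascade.window_h
    sd = max(_window_sd(ii, ii_sq, window), 1.0) if ii_sq is not None else 1.0
    norm = window.area * sd
    win_mean = rect_sum(ii, window) / window.area
    for stage in cascade.stages:
        total = 0.0
        for feat in stage.features:
            score = 0.0
            for r in feat.rects:
                sr = _scaled_rect(r, window, sx, sy)
                score += r[4] * (rect_sum(ii, sr) - sr.area * win_mean)
            score /= norm
            total += feat.right_val if score >= feat.threshold else feat.left_val
        if total < stage.stage_threshold:
            return False
    return True


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: int  # number of raw windows merged into this box


def _iou(a: BoundingBox, b: BoundingBox) -> float:
    ix0, iy0 = max(a.x, b.x), max(a.y, b.y)
    ix1, iy1 = min(a.x + a.w, b.x + b.w), min(a.y + a.h, b.y + b.h)
    iw, ih = max(0, ix1 - ix0), max(0, iy1 - iy0)
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _group_boxes(hits: list[BoundingBox]) -> list[Detection]:
    """Connected components under IoU >= 0.5; component mean is the rep."""
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _iou(hits[i], hits[j]) >= 0.5:
                parent[find(i)] = find(j)
    groups: dict[int, list[BoundingBox]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    out = []
    for members in groups.values():
        out.append(
            Detection(
                box=BoundingBox(
                    x=round(np.mean([b.x for b in members])),
                    y=round(np.mean([b.y for b in members])),
                    w=round(np.mean([b.w for b in members])),
                    h=round(np.mean([b.h for b in members])),
                ),
                confidence=len(members),
            )
        )
    out.sort(key=lambda d: (-d.confidence, d.box.y, d.box.x))
    return out


def detect_objects(
    img: np.ndarray,
    cascade: Cascade,
    scale_factor: float = 1.2,
    min_size: tuple[int, int] | None = None,
    step: int | None = None,
) -> list[Detection]:
    """Multiscale sliding-window scan with overlap grouping.

    Windows grow geometrically by ``scale_factor`` from ``min_size``
    (default: the cascade base window) until they no longer fit; accepted
    windows are merged by >= 50% intersection-over-union and returned
    sorted by confidence (merged-hit count), then top-left position.
    """
    img = np.asarray(img)
    if scale_factor <= 1.0:
        raise ParameterError("scale_factor must be > 1")
    mw, mh = min_size if min_size else (cascade.window_w, cascade.window_h)
    if img.shape[1] < mw or img.shape[0] < mh:
        raise ParameterError("image smaller than the minimum window")
    ii = integral_image(img)
    ii_sq = integral_image(img.astype(np.int64) ** 2)
    hits: list[BoundingBox] = []
    scale = 1.0
    while True:
        ww, wh = round(mw * scale), round(mh * scale)
        if ww > img.shape[1] or wh > img.shape[0]:
            break
        st = step if step is not None else max(1, ww // 8)
        for y in range(0, img.shape[0] - wh + 1, st):
            for x in range(0, img.shape[1] - ww + 1, st):
                win = BoundingBox(x, y, ww, wh)
                if run_cascade(ii, win, cascade, ii_sq=ii_sq):
                    hits.append(win)
        scale *= scale_factor
    return _group_boxes(hits)


class FixedROIDetector:
    """Returns the same configured boxes for every frame.

    The default detector for pre-cropped synthetic sessions, where the
    whole frame already is the eye region.
    """

    def __init__(self, config_boxes: list[BoundingBox]):
        self.boxes = list(config_boxes)

    def __call__(self, frame: np.ndarray) -> list[Detection]:
        h, w = frame.shape[:2]
        for b in self.boxes:
            if b.x < 0 or b.y < 0 or b.x + b.w > w or b.y + b.h > h:
                raise ConfigError(
                    f"configured ROI {b} outside the {h}x{w} frame"
                )
        return [Detection(box=b, confidence=1) for b in self.boxes]


def fixed_roi_detector(config_boxes: list[BoundingBox]) -> FixedROIDetector:
    return FixedROIDetector(config_boxes)


# ---------------------------------------------------------------------------
# cascade I/O

def cascade_from_dict(payload: dict) -> Cascade:
    try:
        stages = tuple(
            CascadeStage(
                features=tuple(
                    HaarFeature(
                        rects=tuple(tuple(r) for r in f["rects"]),
                        threshold=float(f["threshold"]),
                        left_val=float(f["left_val"]),
                        right_val=float(f["right_val"]),
                    )
                    for f in s["features"]
                ),
                stage_threshold=float(s["stage_threshold"]),
            )
            for s in payload["stages"]
        )
        cascade = Cascade(
            window_w=int(payload["window_w"]),
            window_h=int(payload["window_h"]),
            stages=stages,
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed cascade description: {exc}") from exc
    for stage in cascade.stages:
        for feat in stage.features:
            for x, y, w, h, _ in feat.rects:
                if x < 0 or y < 0 or x + w > cascade.window_w \
                        or y + h > cascade.window_h:
                    raise FormatError(
                        f"rect ({x},{y},{w},{h}) outside the base window"
                    )
    return cascade


def load_cascade_json(path: str | Path) -> Cascade:
    return cascade_from_dict(json.loads(Path(path).read_text()))


def load_cascade_opencv_xml(path: str | Path) -> Cascade:
    """Parse the documented subset of the old-style OpenCV Haar XML.

    Expected grammar: ``<opencv_storage>`` containing one element with
    ``type_id="opencv-haar-classifier"``, whose ``<size>`` holds the base
    window and whose ``<stages>`` hold trees of single-split features
    (``<rects>``, ``<threshold>``, ``<left_val>``, ``<right_val>``) plus a
    ``<stage_threshold>``.
    """
    root = ET.parse(Path(path)).getroot()
    clf = None
    for child in root:
        if child.get("type_id") == "opencv-haar-classifier":
            clf = child
            break
    if clf is None:
        raise FormatError("no opencv-haar-classifier element found")
    size = clf.findtext("size")
    if size is None:
        raise FormatError("cascade XML lacks a <size> element")
    window_w, window_h = (int(v) for v in size.split())
    stages = []
    for stage_el in clf.find("stages") or []:
        feats = []
        for tree_el in stage_el.find("trees") or []:
            node = tree_el.find("_")  # single-split tree: one node
            if node is None:
                raise FormatError("empty tree in cascade XML")
            feature_el = node.find("feature")
            rects = []
            for rect_el in feature_el.find("rects"):
                vals = rect_el.text.split()
                rects.append(
                    (int(vals[0]), int(vals[1]), int(vals[2]), int(vals[3]),
                     float(vals[4]))
                )
            feats.append(
                HaarFeature(
                    rects=tuple(rects),
                    threshold=float(node.findtext("threshold")),
                    left_val=float(node.findtext("left_val")),
                    right_val=float(node.findtext("right_val")),
                )
            )
        stages.append(
            CascadeStage(
                features=tuple(feats),
                stage_threshold=float(stage_el.findtext("stage_threshold")),
            )
        )
    return Cascade(window_w=window_w, window_h=window_h, stages=tuple(stages))


def fixture_cascade() -> Cascade:
    """The bundled single-stage dark-disc cascade used by tests and demos."""
    data = resources.files("blinkwatch.data").joinpath("fixture_cascade.json")
    return cascade_from_dict(json.loads(data.read_text()))
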