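"""Per-frame eye-state classification from gray-level eye crops.

The classifier follows a fixed chain of image operators: illumination
normalization to a target mean, Otsu binarization into dark/light pixels,
morphological cleanup of the dark phase, an upper/lower split of the crop,
and a decision on the ratio of dark-pixel fractions.  The physical cue is
that an open eye concentrates dark pixels (pupil, iris, lashes) in the
upper half of the crop, while a closed eye hides them behind the light
eyelid and drops the lash line into the lower half.

Images are plain ``numpy`` arrays: a *gray image* is a 2-D ``uint8`` array
with intensities in [0, 255]; a *binary image* is a 2-D array of {0, 1}
where 1 marks a dark ("black") pixel.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError, FormatError, ParameterError

#: Guard added to the lower-half ratio so the compound ratio stays finite
#: when the lower half contains no dark pixels.
COMPOUND_EPS = 1e-6

#: 3x3 cross (4-connected) structuring element used by default cleanup.
CROSS_3X3 = ndimage.generate_binary_structure(2, 1)


class EyeState(enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class EyeFeatures:
    """Dark-pixel fractions of the two halves of a binarized eye crop.

    ``compound`` is ``upper_ratio / (lower_ratio + eps)``, the open/closed
    discriminant: well above 1 for open eyes, well below 1 for closed.
    """

    upper_ratio: float
    lower_ratio: float
    compound: float


@dataclass(frozen=True)
class FrameAnalysis:
    """Full record of one frame's classification, for logging."""

    features: EyeFeatures
    state: EyeState
    otsu_t: int | None
    degenerate: bool


def to_grayscale(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to 8-bit luminance with BT.601 weights.

    ``Y = round(0.299 R + 0.587 G + 0.114 B)``.
    """
    arr = np.asarray(rgb_frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected an (H, W, 3) RGB frame, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    y = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.rint(y).clip(0, 255).astype(np.uint8)


def normalize_illumination(
    img: np.ndarray, target_mean: float = 128.0
) -> np.ndarray:
    """Rescale global gain so the image mean equals ``target_mean``.

    For a grayscale frame the HSV value channel is the intensity itself, so
    normalizing the mean intensity normalizes mean V.  Output is clipped to
    [0, 255] and rounded back to uint8.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ParameterError("empty image")
    mean = float(img.mean())
    if mean == 0.0:
        raise DegenerateImageError("image mean is zero; cannot normalize gain")
    scaled = img.astype(np.float64) * (target_mean / mean)
    return np.rint(scaled).clip(0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu threshold over the 256-bin histogram.

    Returns the ``t`` in [0, 254] that maximizes the between-class variance
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` where class 0 holds pixels
    ``<= t``.  Ties break toward the smallest ``t``.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ParameterError("empty image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(
        np.float64
    )
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "constant image: Otsu needs at least two gray levels"
        )
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:255]
    s0 = np.cumsum(hist * levels)[:255]
    total = hist.sum()
    total_s = float((hist * levels).sum())
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    mu0 = np.divide(s0, w0, out=np.zeros(255), where=valid)
    mu1 = np.divide(total_s - s0, w1, out=np.zeros(255), where=valid)
    sigma_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first maximizer


def binarize(img: np.ndarray, t: int) -> np.ndarray:
    """Mark pixels with intensity ``<= t`` as dark (1), the rest light (0)."""
    if not 0 <= t <= 254:
        raise ParameterError(f"threshold must be in [0, 254], got {t}")
    return (np.asarray(img) <= t).astype(np.uint8)


def clean_binary(
    img: np.ndarray,
    structuring_element: np.ndarray = CROSS_3X3,
    mode: str = "open_dark",
) -> np.ndarray:
    """Remove small dark specks from a binary image.

    Default is morphological opening of the dark (value-1) phase: erosion
    followed by dilation with a 3x3 cross, which deletes isolated dark
    pixels and is idempotent and anti-extensive.  ``mode='close_dark'``
    instead closes the dark phase (fills small light holes).
    """
    dark = np.asarray(img).astype(bool)
    if mode == "open_dark":
        out = ndimage.binary_opening(dark, structure=structuring_element)
    elif mode == "close_dark":
        out = ndimage.binary_closing(dark, structure=structuring_element)
    else:
        raise ParameterError(f"unknown cleanup mode: {mode!r}")
    return out.astype(np.uint8)


def split_and_ratio(img: np.ndarray) -> EyeFeatures:
    """Dark-pixel fraction of the upper and lower halves of a binary image.

    Row 0 is the top of the crop.  The upper half takes rows
    ``[0, floor(H/2))`` and the lower half the rest, so for odd heights the
    lower half gets the extra row.
    """
    img = np.asarray(img)
    h = img.shape[0]
    if h < 2:
        raise ParameterError(f"need at least 2 rows to split, got {h}")
    mid = h // 2
    upper = float(img[:mid].mean())
    lower = float(img[mid:].mean())
    return EyeFeatures(
        upper_ratio=upper,
        lower_ratio=lower,
        compound=upper / (lower + COMPOUND_EPS),
    )


def classify_eye_state(
    features: EyeFeatures, ratio_threshold: float = 1.0
) -> EyeState:
    """OPEN iff the compound ratio strictly exceeds the threshold.

    Ties classify CLOSED: for a safety monitor, ambiguity should err toward
    the drowsy interpretation.
    """
    return EyeState.OPEN if features.compound > ratio_threshold else EyeState.CLOSED


def analyze_frame(
    eye_crop: np.ndarray,
    ratio_threshold: float = 1.0,
    target_mean: float = 128.0,
    cleanup_mode: str = "open_dark",
) -> FrameAnalysis:
    """Run the full per-frame chain and keep intermediates for logging.

    normalize -> Otsu -> binarize -> cleanup -> split -> classify.
    A degenerate crop (constant or zero-mean) cannot be thresholded; it is
    logged with a warning and classified CLOSED, the fail-safe state.
    """
    crop = np.asarray(eye_crop)
    if crop.ndim != 2:
        raise FormatError(f"expected a 2-D gray crop, got shape {crop.shape}")
    if crop.shape[0] < 2:
        raise ParameterError("eye crop must have at least 2 rows")
    try:
        norm = normalize_illumination(crop, target_mean=target_mean)
        t = otsu_threshold(norm)
    except DegenerateImageError as exc:
        warnings.warn(f"degenerate eye crop, classified CLOSED: {exc}")
        feats = EyeFeatures(0.0, 0.0, 0.0)
        return FrameAnalysis(feats, EyeState.CLOSED, None, True)
    binary = clean_binary(binarize(norm, t), mode=cleanup_mode)
    feats = split_and_ratio(binary)
    state = classify_eye_state(feats, ratio_threshold=ratio_threshold)
    return FrameAnalysis(feats, state, t, False)


def frame_to_features(
    eye_crop: np.ndarray,
    ratio_threshold: float = 1.0,
    target_mean: float = 128.0,
) -> tuple[EyeFeatures, EyeState]:
    """Convenience wrapper around :func:`analyze_frame`."""
    res = analyze_frame(eye_crop, ratio_threshold=ratio_threshold,
                        target_mean=target_mean)
    return res.features, res.state


def calibrate_ratio_threshold(
    compounds: np.ndarray, states: list[EyeState]
) -> float:
    """Pick the compound-ratio cut maximizing balanced accuracy.

    Candidates are midpoints between consecutive sorted compound values.
    Ties prefer the smallest threshold.  Useful when the default cut of 1.0
    is off for a particular camera geometry.
    """
    compounds = np.asarray(compounds, dtype=float)
    is_open = np.array([s is EyeState.OPEN for s in states])
    if compounds.size != is_open.size or compounds.size < 2:
        raise ParameterError("need >= 2 labeled compounds of equal length")
    if is_open.all() or (~is_open).all():
        raise ParameterError("need both OPEN and CLOSED examples")
    uniq = np.unique(compounds)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_score = 1.0, -1.0
    for cand in candidates:
        pred_open = compounds > cand
        tpr = (pred_open & is_open).sum() / is_open.sum()
        tnr = (~pred_open & ~is_open).sum() / (~is_open).sum()
        score = 0.5 * (tpr + tnr)
        if score > best_score:
            best_t, best_score = float(cand), score
    return best_t
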