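"""Automated isolation of individual knees from bilateral radiographs.

A bilateral AP knee radiograph shows both knees side by side; classification
operates on one knee at a time, so each image must be split into two
normalized single-knee slices. The pipeline:

1. ``standardize`` — grayscale + resize to 224x224.
2. ``sharpen`` — unsharp masking to enhance bone edges.
3. ``otsu_threshold`` — binarize; bone (radiopaque) becomes foreground.
4. ``morphological_opening`` — drop specks and thin annotation text.
5. ``detect_knee_columns`` — column-projection runs locate the two knees.
6. ``crop_knees`` — cut each knee out, rows trimmed to foreground extent.
7. ``pad_and_normalize`` — zero-pad to square (aspect ratio preserved),
   resize to 224x224, scale to [0, 1].

``fix_identical_rows`` is a pixel-correction fallback: rows that are
entirely one value (scanner borders, burnt-in strips) are zeroed before a
second detection attempt. ``isolate`` composes all of the above on a
:class:`~kneegrade.phantom.RadiographRecord` and returns two labeled
:class:`KneeSlice` objects.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantom import RadiographRecord

__all__ = [
    "BinaryMask",
    "ColumnInterval",
    "KneeSlice",
    "IsolationParams",
    "KneeSeparationError",
    "standardize",
    "sharpen",
    "otsu_threshold",
    "morphological_opening",
    "fix_identical_rows",
    "detect_knee_columns",
    "crop_knees",
    "pad_and_normalize",
    "isolate",
]

TARGET_SIZE = 224

BinaryMask = np.ndarray  # {0,1} / bool array, same shape as its source image

# RGB -> luminance weights (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])


class KneeSeparationError(RuntimeError):
    """Raised when column-projection analysis cannot find two knees."""

    def __init__(self, message: str, runs=None, record_id: str | None = None):
        self.runs = runs or []
        self.record_id = record_id
        if record_id:
            message = f"{message} (record {record_id})"
        super().__init__(message + f"; candidate runs: {self.runs}")


@dataclass(frozen=True)
class ColumnInterval:
    """Half-open [start, end) column range of one knee."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid column interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def jaccard(self, other: "ColumnInterval") -> float:
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union if union else 0.0


@dataclass
class KneeSlice:
    """One isolated knee: 224x224 pixels in [0, 1] plus its provenance."""

    patient_id: str
    side: str  # "left" | "right"
    grade: int
    pixels: np.ndarray
    pain: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != (TARGET_SIZE, TARGET_SIZE):
            raise ValueError(f"slice must be {TARGET_SIZE}x{TARGET_SIZE}, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("slice pixels must lie in [0, 1]")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.pixels = px


@dataclass(frozen=True)
class IsolationParams:
    """Tunable knobs of the isolation pipeline (all config-exposed)."""

    sharpen_amount: float = 1.0
    sharpen_sigma: float = 1.0
    opening_kernel: int = 5  # side of the square structuring element
    min_gap: int = 5         # zero-column gaps narrower than this are bridged
    min_run: int = 10        # column runs narrower than this are dropped
    row_margin: int = 2      # extra rows kept around the foreground extent
    sharpen_feeds_threshold: bool = True
    crop_sharpened: bool = False
    midline_fallback: bool = False


def standardize(image: np.ndarray) -> np.ndarray:
    """Grayscale-convert and resize to 224x224, preserving the 8-bit range.

    RGB input is collapsed by luminance weighting; an input that is already
    224x224 grayscale passes through pixel-identically.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError(f"expected 3 channels, got shape {img.shape}")
        img = img @ _LUMA
    elif img.ndim != 2:
        raise ValueError(f"expected 2-D or 3-channel image, got ndim={img.ndim}")
    if img.size == 0 or min(img.shape) < 2:
        raise ValueError(f"image too small to standardize: shape {img.shape}")
    if img.shape == (TARGET_SIZE, TARGET_SIZE):
        return img
    out = _sk_resize(img, (TARGET_SIZE, TARGET_SIZE), order=1,
                     preserve_range=True, anti_aliasing=True)
    return np.clip(out, 0.0, 255.0)


def sharpen(image: np.ndarray, amount: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    """Unsharp mask: ``img + amount * (img - gaussian_blur(img, sigma))``."""
    if amount < 0:
        raise ValueError(f"sharpen amount must be >= 0, got {amount}")
    img = np.asarray(image, dtype=float)
    if amount == 0:
        return img.copy()
    blurred = ndimage.gaussian_filter(img, sigma=sigma)
    return np.clip(img + amount * (img - blurred), 0.0, 255.0)


def otsu_threshold(image: np.ndarray) -> tuple[int, BinaryMask]:
    """Otsu binarization over the 256-bin gray histogram.

    Returns ``(t, mask)`` where ``t`` is the smallest threshold maximizing
    the between-class variance and ``mask = image > t``. Radiopaque bone is
    bright, so foreground means bone.
    """
    img = np.asarray(image, dtype=float)
    levels = np.clip(np.rint(img), 0, 255).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single gray level")

    p = hist / hist.sum()
    omega = np.cumsum(p)                # class-0 probability for t = 0..255
    mu = np.cumsum(p * np.arange(256))  # first moment up to t
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf, posinf=-np.inf, neginf=-np.inf)
    t = int(np.argmax(sigma_b))  # argmax returns the smallest maximizer
    return t, (levels > t)


def morphological_opening(mask: BinaryMask, kernel: np.ndarray | int = 5) -> BinaryMask:
    """Binary opening (erosion then dilation) with a square kernel by default.

    Removes foreground components that cannot contain the structuring
    element — specks, thin strokes, disconnected pixels.
    """
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary, found values {vals[:8]}")
    m = m.astype(bool)
    struct = np.ones((kernel, kernel), dtype=bool) if np.isscalar(kernel) else np.asarray(kernel, dtype=bool)
    eroded = ndimage.binary_erosion(m, structure=struct)
    return ndimage.binary_dilation(eroded, structure=struct)


def fix_identical_rows(image: np.ndarray) -> np.ndarray:
    """Zero out every row whose pixels are all equal (to any value)."""
    img = np.asarray(image).copy()
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    constant = (img == img[:, :1]).all(axis=1)
    img[constant] = 0
    return img


def _column_runs(counts: np.ndarray, min_gap: int, min_run: int):
    """Maximal runs of columns with count > 0, gap-bridged and length-filtered.

    Returns (start, end, area) triples, area being the foreground pixel count
    inside the run.
    """
    nz = counts > 0
    runs = []
    start = None
    for i, on in enumerate(nz):
        if on and start is None:
            start = i
        elif not on and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(nz)])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    kept = [(s, e, int(counts[s:e].sum())) for s, e in merged if e - s >= min_run]
    return kept


def detect_knee_columns(
    mask: BinaryMask, min_gap: int = 5, min_run: int = 10
) -> tuple[ColumnInterval, ColumnInterval]:
    """Locate the two knees from the column projection of a bone mask.

    Per-column foreground counts are segmented into maximal nonzero runs;
    runs separated by fewer than ``min_gap`` empty columns are bridged, runs
    narrower than ``min_run`` columns dropped, and the two largest-area runs
    are returned ordered left to right.
    """
    m = np.asarray(mask).astype(bool)
    counts = m.sum(axis=0)
    kept = _column_runs(counts, min_gap, min_run)
    if len(kept) < 2:
        raise KneeSeparationError(
            f"knee separation failed: found {len(kept)} column run(s), need 2",
            runs=kept,
        )
    top2 = sorted(sorted(kept, key=lambda r: r[2], reverse=True)[:2], key=lambda r: r[0])
    return ColumnInterval(top2[0][0], top2[0][1]), ColumnInterval(top2[1][0], top2[1][1])


def crop_knees(
    image: np.ndarray,
    intervals: tuple[ColumnInterval, ColumnInterval],
    mask: BinaryMask,
    row_margin: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut out each knee: the interval's columns, rows trimmed to foreground.

    The row range is the span of mask-foreground rows within the interval
    plus ``row_margin`` rows each side, clipped to the image. The first
    (leftmost) interval yields the left knee.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    crops = []
    for iv in intervals:
        if iv.width < 2:
            raise ValueError(f"degenerate column interval {iv}")
        sub = m[:, iv.start : iv.end]
        rows = np.flatnonzero(sub.any(axis=1))
        if rows.size == 0:
            raise ValueError(f"no foreground rows inside interval {iv}")
        r0 = max(int(rows[0]) - row_margin, 0)
        r1 = min(int(rows[-1]) + 1 + row_margin, img.shape[0])
        crops.append(img[r0:r1, iv.start : iv.end])
    return crops[0], crops[1]


def pad_and_normalize(crop: np.ndarray) -> np.ndarray:
    """Zero-pad to square, resize to 224x224, scale to [0, 1].

    The shorter dimension is padded symmetrically (an odd remainder puts the
    extra row/column at the bottom/right), so the knee's aspect ratio is
    preserved by the final resize.
    """
    img = np.asarray(crop, dtype=float)
    if img.size == 0:
        raise ValueError("empty crop")
    h, w = img.shape
    side = max(h, w)
    pad_r, pad_c = side - h, side - w
    img = np.pad(img, ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)))
    if side != TARGET_SIZE:
        img = _sk_resize(img, (TARGET_SIZE, TARGET_SIZE), order=1,
                         preserve_range=True, anti_aliasing=side > TARGET_SIZE)
    return np.clip(img / 255.0, 0.0, 1.0)


def isolate(record: RadiographRecord, params: IsolationParams | None = None) -> list[KneeSlice]:
    """Run the full isolation pipeline on one radiograph.

    Returns ``[left_slice, right_slice]`` carrying the record's patient id
    and the per-side grade. If column detection fails, the mask is retried
    after ``fix_identical_rows``; with ``midline_fallback`` enabled, a final
    attempt splits at the widest empty column gap nearest the midline.
    """
    p = params or IsolationParams()
    std = standardize(record.image)
    sharp = sharpen(std, p.sharpen_amount, p.sharpen_sigma)
    _, mask = otsu_threshold(sharp if p.sharpen_feeds_threshold else std)
    opened = morphological_opening(mask, p.opening_kernel)

    try:
        intervals = detect_knee_columns(opened, p.min_gap, p.min_run)
    except KneeSeparationError:
        fixed = fix_identical_rows(opened.astype(np.uint8)).astype(bool)
        try:
            intervals = detect_knee_columns(fixed, p.min_gap, p.min_run)
            opened = fixed
        except KneeSeparationError as err:
            if not p.midline_fallback:
                raise KneeSeparationError(str(err), runs=err.runs,
                                          record_id=record.patient_id) from None
            intervals = _midline_split(opened)

    source = sharp if p.crop_sharpened else std
    crop_l, crop_r = crop_knees(source, intervals, opened, p.row_margin)
    out = []
    for side, crop, grade, pain in (
        ("left", crop_l, record.grade_left, record.pain_left),
        ("right", crop_r, record.grade_right, record.pain_right),
    ):
        out.append(KneeSlice(
            patient_id=record.patient_id, side=side, grade=grade,
            pixels=pad_and_normalize(crop), pain=pain,
        ))
    return out


def _midline_split(mask: BinaryMask) -> tuple[ColumnInterval, ColumnInterval]:
    """Fallback: split at the widest zero-column gap nearest the midline."""
    counts = np.asarray(mask).astype(bool).sum(axis=0)
    w = len(counts)
    zero = counts == 0
    best, best_score = None, -np.inf
    start = None
    for i in range(w + 1):
        if i < w and zero[i] and start is None:
            start = i
        elif (i == w or not zero[i]) and start is not None:
            width = i - start
            center = (start + i) / 2
            score = width - abs(center - w / 2) * 0.1
            if 0 < start and i < w and score > best_score:
                best, best_score = (start + i) // 2, score
            start = None
    split = best if best is not None else w // 2
    return ColumnInterval(0, max(split, 1)), ColumnInterval(min(split, w - 1), w)
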