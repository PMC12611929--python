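"""Synthetic bilateral knee-radiograph phantoms with known KL grades.

Real KL-graded radiograph collections are rarely shareable, so the pipeline
is exercised on phantoms that carry exactly the image cues an orthopedic
reader (and the classifier) uses: two bright bone columns per image (femur
above tibia), a joint-space gap that narrows with increasing
Kellgren-Lawrence grade, marginal osteophyte bumps whose number grows with
grade, plus the nuisance features the isolation stage must survive — a
text-like annotation block in the upper-left corner and per-image size
jitter.

Grades 0 and 1 are rendered from identical geometry: clinically, a grade-1
knee is a radiographically normal knee in a patient reporting pain, so the
0-vs-1 distinction lives in a latent pain flag and never in the pixels.
Any classifier trained on these phantoms should therefore sit at chance on
the 0-vs-1 boundary, which is the qualitative behaviour the package's
evaluation suite checks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomConfig",
    "RadiographRecord",
    "DEFAULT_CLASS_MIX",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

KL_GRADES = (0, 1, 2, 3, 4)

#: Default per-grade knee probabilities, taken as the clinical per-grade
#: tallies 18/67/105/126/86 renormalised. (Those tallies overcount the
#: 301-patient cohort they describe; they are used here only as proportions.)
DEFAULT_CLASS_MIX = tuple(np.array([18, 67, 105, 126, 86]) / 402.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of the phantom generator.

    Intensities are 8-bit gray levels; sizes are pixels. ``joint_gap_by_grade``
    maps each KL grade to the femur-tibia gap height and must be equal for
    grades 0 and 1 (their images are identical by construction) and
    non-increasing from grade 1 to 4 (joint-space narrowing).
    """

    image_height: int = 400
    image_width: int = 600
    bone_intensity: int = 200
    background_mean: int = 15
    noise_sd: float = 5.0
    joint_gap_by_grade: dict[int, int] = field(
        default_factory=lambda: {0: 12, 1: 12, 2: 8, 3: 4, 4: 1}
    )
    osteophyte_count_by_grade: dict[int, int] = field(
        default_factory=lambda: {0: 0, 1: 0, 2: 1, 3: 2, 4: 4}
    )
    annotation_block: tuple[int, int] = (12, 60)
    size_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_mean < self.bone_intensity <= 255):
            raise ValueError(
                "require 0 <= background_mean < bone_intensity <= 255, got "
                f"{self.background_mean} / {self.bone_intensity}"
            )
        gaps = self.joint_gap_by_grade
        osteo = self.osteophyte_count_by_grade
        if set(gaps) != set(KL_GRADES) or set(osteo) != set(KL_GRADES):
            raise ValueError("grade maps must cover KL grades 0-4")
        if gaps[0] != gaps[1] or osteo[0] != osteo[1]:
            raise ValueError(
                "grades 0 and 1 must be image-identical: equal gap and "
                "osteophyte count"
            )
        if any(gaps[g + 1] < gaps[g + 2] for g in range(3)):
            # non-increasing gap from grade 1 to 4 = joint-space narrowing
            raise ValueError("joint gap must be non-increasing for grades 1..4")
        if any(gaps[g] < 1 for g in KL_GRADES):
            raise ValueError("joint gaps must be >= 1 pixel")
        if not 0 <= self.size_jitter < 0.5:
            raise ValueError("size_jitter must lie in [0, 0.5)")


@dataclass
class RadiographRecord:
    """One bilateral radiograph with per-knee labels and (synthetic) truth.

    ``truth_boxes`` holds two half-open ``(col_start, col_end, row_start,
    row_end)`` boxes, left knee first, bounding each knee's bone pixels;
    it is ``None`` for real data.
    """

    patient_id: str
    age: float
    sex: str
    image: np.ndarray
    grade_left: int
    grade_right: int
    pain_left: bool
    pain_right: bool
    truth_boxes: tuple[tuple[int, int, int, int], tuple[int, int, int, int]] | None = None

    def __post_init__(self) -> None:
        for g in (self.grade_left, self.grade_right):
            if g not in KL_GRADES:
                raise ValueError(f"KL grade must be in 0..4, got {g!r}")
        if self.grade_left == 1 and not self.pain_left:
            raise ValueError("grade 1 requires the pain flag (normal X-ray + pain)")
        if self.grade_left == 0 and self.pain_left:
            raise ValueError("grade 0 requires no pain (normal X-ray, no pain)")
        if self.grade_right == 1 and not self.pain_right:
            raise ValueError("grade 1 requires the pain flag (normal X-ray + pain)")
        if self.grade_right == 0 and self.pain_right:
            raise ValueError("grade 0 requires no pain (normal X-ray, no pain)")
        if self.truth_boxes is not None:
            left, right = self.truth_boxes
            if left[1] > right[0]:
                raise ValueError("truth boxes must be column-disjoint, left first")

    @property
    def grades(self) -> tuple[int, int]:
        return (self.grade_left, self.grade_right)


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _paint_knee(
    canvas: np.ndarray,
    bone_mask: np.ndarray,
    col_lo: int,
    col_hi: int,
    grade: int,
    cfg: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Paint femur/tibia blocks plus osteophytes; return the knee's bone box."""
    h = canvas.shape[0]
    gap = cfg.joint_gap_by_grade[grade]
    row_top = int(round(h * (0.15 + rng.uniform(-0.02, 0.02))))
    row_bot = int(round(h * (0.85 + rng.uniform(-0.02, 0.02))))
    gap_top = int(round(h * 0.5 + rng.uniform(-0.02, 0.02) * h - gap / 2))
    gap_bot = gap_top + gap

    canvas[row_top:gap_top, col_lo:col_hi] = cfg.bone_intensity
    canvas[gap_bot:row_bot, col_lo:col_hi] = cfg.bone_intensity
    bone_mask[row_top:gap_top, col_lo:col_hi] = True
    bone_mask[gap_bot:row_bot, col_lo:col_hi] = True

    # Marginal osteophytes: bright half-ellipses protruding laterally at the
    # joint margins, alternating sides and femoral/tibial corners. Sized
    # relative to the image so they stay visible after the 224x224 resize
    # (their count is the zoom/rotation-invariant grade cue, as in real
    # radiographic lipping).
    n_osteo = cfg.osteophyte_count_by_grade[grade]
    osteo_val = min(cfg.bone_intensity + 30, 255)
    a, b = max(4, h // 33), max(6, canvas.shape[1] // 40)  # semi-axes (rows, cols)
    mid = (gap_top + gap_bot) // 2
    sites = [
        (mid, col_lo),              # joint line, lateral
        (mid, col_hi - 1),          # joint line, medial
        (mid - 3 * a, col_lo),      # femoral margin, lateral
        (mid + 3 * a, col_hi - 1),  # tibial margin, medial
    ]
    for k in range(min(n_osteo, 4)):
        cy, cx = sites[k]
        yy, xx = np.ogrid[-a : a + 1, -b : b + 1]
        ell = (yy / a) ** 2 + (xx / b) ** 2 <= 1.0
        r0, r1 = max(cy - a, 0), min(cy + a + 1, h)
        c0, c1 = max(cx - b, 0), min(cx + b + 1, canvas.shape[1])
        sub = ell[(r0 - (cy - a)) : (r1 - (cy - a)), (c0 - (cx - b)) : (c1 - (cx - b))]
        canvas[r0:r1, c0:c1][sub] = osteo_val
        bone_mask[r0:r1, c0:c1][sub] = True

    rows = np.flatnonzero(bone_mask.any(axis=1))
    cols = np.flatnonzero(bone_mask.any(axis=0))
    return (int(cols[0]), int(cols[-1]) + 1, int(rows[0]), int(rows[-1]) + 1)


def _paint_annotation(canvas: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> None:
    """Text-like overlay in the upper-left corner: thin bright strokes.

    Strokes are <= 1 px thick so that, after resize to 224x224 and a 5x5
    morphological opening, they vanish — emulating faint annotation text
    that real segmentation discards.
    """
    ah, aw = cfg.annotation_block
    top, left = 2, 2
    for r in range(top + 1, top + ah, 4):
        # broken horizontal stroke with random gaps, like a line of text
        on = rng.random(aw) < 0.7
        canvas[r, left : left + aw][on] = min(cfg.bone_intensity + 40, 255)


def generate_phantom(
    grade_left: int,
    grade_right: int,
    cfg: PhantomConfig | None = None,
    rng_state=None,
    *,
    patient_id: str = "P0000",
    age: float = 60.0,
    sex: str = "F",
) -> RadiographRecord:
    """Render one bilateral phantom radiograph with the given per-knee grades.

    Deterministic given ``rng_state`` (a seed or ``numpy.random.Generator``).
    The two knees occupy disjoint column bands; ``truth_boxes`` bound the
    painted bone pixels of each knee (osteophytes included).
    """
    cfg = cfg or PhantomConfig()
    for g in (grade_left, grade_right):
        if g not in KL_GRADES:
            raise ValueError(f"KL grade must be an integer in 0..4, got {g!r}")
    rng = _as_rng(rng_state if rng_state is not None else cfg.seed)

    jit = cfg.size_jitter
    h = int(round(cfg.image_height * (1.0 + rng.uniform(-jit, jit))))
    w = int(round(cfg.image_width * (1.0 + rng.uniform(-jit, jit))))

    canvas = np.full((h, w), float(cfg.background_mean))
    bone = np.zeros((h, w), dtype=bool)

    # Column bands: left knee in ~[8%, 42%) of width, right in ~[58%, 92%).
    def band(lo_frac: float, hi_frac: float) -> tuple[int, int]:
        lo = int(round(w * (lo_frac + rng.uniform(-0.02, 0.02))))
        hi = int(round(w * (hi_frac + rng.uniform(-0.02, 0.02))))
        return lo, hi

    left_band = band(0.08, 0.42)
    right_band = band(0.58, 0.92)

    left_mask = np.zeros_like(bone)
    right_mask = np.zeros_like(bone)
    box_l = _paint_knee(canvas, left_mask, *left_band, grade_left, cfg, rng)
    box_r = _paint_knee(canvas, right_mask, *right_band, grade_right, cfg, rng)
    bone |= left_mask | right_mask

    _paint_annotation(canvas, cfg, rng)

    canvas += rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    pain_left = True if grade_left == 1 else (False if grade_left == 0 else bool(rng.random() < 0.85))
    pain_right = True if grade_right == 1 else (False if grade_right == 0 else bool(rng.random() < 0.85))

    return RadiographRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        image=image,
        grade_left=grade_left,
        grade_right=grade_right,
        pain_left=pain_left,
        pain_right=pain_right,
        truth_boxes=(box_l, box_r),
    )


def generate_cohort(
    n_patients: int,
    class_mix=DEFAULT_CLASS_MIX,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
) -> list[RadiographRecord]:
    """Sample a reproducible cohort of phantom radiographs.

    Per-knee grades are i.i.d. from ``class_mix``; ages are uniform on
    [40, 80] (the study-population inclusion band); sex follows the cohort's
    54/46 female/male ratio. Patient ids are unique. The same seed yields a
    bit-identical cohort.
    """
    cfg = cfg or PhantomConfig()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (5,):
        raise ValueError(f"class_mix must have 5 entries, got shape {mix.shape}")
    for g, p in enumerate(mix):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"class_mix[{g}] = {p} is not a probability")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mix sums to {mix.sum():.12f}, expected 1")

    parent = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(parent.spawn(1)[0])
    child_seeds = parent.spawn(n_patients + 1)[1:]

    records = []
    for i in range(n_patients):
        gl, gr = meta_rng.choice(5, size=2, p=mix)
        age = float(meta_rng.uniform(40.0, 80.0))
        sex = "F" if meta_rng.random() < 162 / 301 else "M"
        rec = generate_phantom(
            int(gl),
            int(gr),
            cfg,
            np.random.default_rng(child_seeds[i]),
            patient_id=f"P{i:04d}",
            age=age,
            sex=sex,
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Disk round-trip (the `kneegrade simulate` artifact format)

_COHORT_COLUMNS = [
    "patient_id", "age", "sex", "grade_left", "grade_right",
    "pain_left", "pain_right",
    "left_col_start", "left_col_end", "left_row_start", "left_row_end",
    "right_col_start", "right_col_end", "right_row_start", "right_row_end",
]


def save_cohort(records: list[RadiographRecord], out_dir: str | Path) -> Path:
    """Write one 8-bit grayscale PNG per record plus ``cohort.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        Image.fromarray(rec.image, mode="L").save(out / f"{rec.patient_id}.png")
        (bl, br) = rec.truth_boxes if rec.truth_boxes is not None else ((-1,) * 4, (-1,) * 4)
        rows.append([rec.patient_id, rec.age, rec.sex, rec.grade_left, rec.grade_right,
                     rec.pain_left, rec.pain_right, *bl, *br])
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    df.to_csv(out / "cohort.csv", index=False)
    return out / "cohort.csv"


def load_cohort(in_dir: str | Path) -> list[RadiographRecord]:
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "cohort.csv")
    records = []
    for row in df.itertuples(index=False):
        image = np.asarray(Image.open(in_dir / f"{row.patient_id}.png").convert("L"))
        boxes = None
        if row.left_col_start >= 0:
            boxes = (
                (row.left_col_start, row.left_col_end, row.left_row_start, row.left_row_end),
                (row.right_col_start, row.right_col_end, row.right_row_start, row.right_row_end),
            )
        records.append(RadiographRecord(
            patient_id=row.patient_id, age=float(row.age), sex=row.sex,
            image=image, grade_left=int(row.grade_left), grade_right=int(row.grade_right),
            pain_left=bool(row.pain_left), pain_right=bool(row.pain_right),
            truth_boxes=boxes,
        ))
    return records
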