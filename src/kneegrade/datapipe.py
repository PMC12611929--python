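"""Patient-level splitting and training-set augmentation.

Both knees of one patient are strongly correlated, so evaluation must keep
every patient entirely on one side of the train/test boundary (patient-level
split). The training pool is then expanded with random rotation, zoom,
shift, shear and horizontal flips, and divided 90/10 into train/validation
at the slice level; the held-out test set is never augmented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from .isolation import KneeSlice, TARGET_SIZE
from .phantom import RadiographRecord

__all__ = ["AugmentConfig", "CohortSplit", "patient_split", "augment", "build_sets"]


@dataclass(frozen=True)
class AugmentConfig:
    """Random-transform ranges for training-set augmentation.

    Defaults mirror common radiograph practice: rotation within ±30°, zoom
    0.8–1.2, shifts up to 10% of the image size, shear within ±20°, and
    horizontal flipping. ``copies_per_image`` augmented variants are added
    per original slice.
    """

    rotation_deg: float = 30.0
    zoom_range: tuple[float, float] = (0.8, 1.2)
    shift_frac: float = 0.10
    shear_deg: float = 20.0
    hflip: bool = True
    copies_per_image: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zoom_range[0] >= self.zoom_range[1]:
            raise ValueError("zoom_range must satisfy low < high")
        if min(self.rotation_deg, self.shift_frac, self.shear_deg) < 0:
            raise ValueError("augmentation ranges must be nonnegative")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass
class CohortSplit:
    """Disjoint patient-level train/val/test slice sets."""

    train: list[KneeSlice]
    val: list[KneeSlice]
    test: list[KneeSlice]
    patient_partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        train_pat = {s.patient_id for s in self.train} | {s.patient_id for s in self.val}
        test_pat = {s.patient_id for s in self.test}
        leaked = train_pat & test_pat
        if leaked:
            raise ValueError(f"patient leakage across train/test boundary: {sorted(leaked)[:5]}")


def patient_split(
    records: list[RadiographRecord],
    test_frac: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[RadiographRecord], list[RadiographRecord]]:
    """Shuffle patients and hold out ``ceil(test_frac * n)`` of them for test.

    When every stratum (a patient's maximum knee grade) has at least two
    patients, the held-out set is stratified by largest-remainder allocation;
    otherwise the split is unstratified with a warning.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0.0 < test_frac < 1.0:
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    n_test = math.ceil(test_frac * n)
    rng = np.random.default_rng(seed)

    strata: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(max(rec.grade_left, rec.grade_right), []).append(i)

    if stratify and all(len(v) >= 2 for v in strata.values()):
        test_idx: list[int] = []
        # largest-remainder allocation so stratum test counts sum to n_test
        quotas = {g: n_test * len(idx) / n for g, idx in strata.items()}
        base = {g: int(q) for g, q in quotas.items()}
        short = n_test - sum(base.values())
        for g in sorted(quotas, key=lambda g: quotas[g] - base[g], reverse=True)[:short]:
            base[g] += 1
        for g in sorted(strata):
            idx = np.array(strata[g])
            rng.shuffle(idx)
            take = min(base[g], len(idx) - 1)  # keep >=1 train patient per stratum
            test_idx.extend(idx[:take].tolist())
        # top up (or trim) if the per-stratum cap changed the total
        remaining = [i for i in range(n) if i not in set(test_idx)]
        rng.shuffle(remaining)
        while len(test_idx) < n_test and remaining:
            test_idx.append(remaining.pop())
        test_set = set(test_idx[:n_test])
    else:
        if stratify:
            warnings.warn("a grade stratum has < 2 patients; splitting unstratified",
                          stacklevel=2)
        order = rng.permutation(n)
        test_set = set(order[:n_test].tolist())

    train = [records[i] for i in range(n) if i not in test_set]
    test = [records[i] for i in range(n) if i in test_set]
    return train, test


def _draw_transform(cfg: AugmentConfig, rng: np.random.Generator) -> tuple[AffineTransform, bool]:
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    zoom = rng.uniform(*cfg.zoom_range)
    shift = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * TARGET_SIZE
    shear = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    flip = cfg.hflip and rng.random() < 0.5

    c = TARGET_SIZE / 2.0
    center = AffineTransform(translation=(-c, -c))
    core = AffineTransform(rotation=theta, scale=(zoom, zoom), shear=shear,
                           translation=tuple(shift))
    uncenter = AffineTransform(translation=(c, c))
    return center + core + uncenter, flip


def augment(slice_: KneeSlice, cfg: AugmentConfig, rng_state=None) -> KneeSlice:
    """One random augmented variant of a knee slice.

    Rotation, isotropic zoom, shift, shear (each drawn independently from
    the configured ranges) and an optional horizontal flip; bilinear
    resampling with zero fill, output clipped to [0, 1]. Label, patient id
    and side are untouched.
    """
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    tform, flip = _draw_transform(cfg, rng)
    px = slice_.pixels
    if flip:
        px = px[:, ::-1]
    out = warp(px, tform.inverse, order=1, cval=0.0, preserve_range=True,
               output_shape=(TARGET_SIZE, TARGET_SIZE))
    return KneeSlice(
        patient_id=slice_.patient_id, side=slice_.side, grade=slice_.grade,
        pixels=np.clip(out, 0.0, 1.0), pain=slice_.pain,
    )


def build_sets(
    train_slices: list[KneeSlice],
    test_slices: list[KneeSlice],
    cfg: AugmentConfig | None = None,
    val_frac: float = 0.1,
    seed: int = 0,
) -> CohortSplit:
    """Expand the training slices and carve out a slice-level validation set.

    Each training slice contributes itself plus ``copies_per_image``
    augmented variants; the pooled result is shuffled and split
    ``(1 - val_frac)/val_frac`` into train/validation. Test slices pass
    through untouched (never augmented).

    Validation sharing augmented siblings with training mirrors the common
    augment-then-split protocol; use a patient-level validation split
    (``patient_split`` twice) when stricter leakage control is needed.
    """
    if not train_slices:
        raise ValueError("empty training pool")
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(seed)

    pool: list[KneeSlice] = []
    for s in train_slices:
        pool.append(s)
        for _ in range(cfg.copies_per_image):
            pool.append(augment(s, cfg, rng))

    order = rng.permutation(len(pool))
    n_val = int(round(val_frac * len(pool)))
    val_idx = set(order[:n_val].tolist())
    train = [pool[i] for i in range(len(pool)) if i not in val_idx]
    val = [pool[i] for i in range(len(pool)) if i in val_idx]

    partition = {s.patient_id: "train" for s in train_slices}
    partition.update({s.patient_id: "test" for s in test_slices})
    return CohortSplit(train=train, val=val, test=list(test_slices),
                       patient_partition=partition)
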