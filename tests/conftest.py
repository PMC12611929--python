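import numpy as np
import pytest

from kneegrade.isolation import KneeSlice, isolate
from kneegrade.phantom import PhantomConfig, RadiographRecord, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """24 phantom patients with a uniform grade mix."""
    return generate_cohort(24, [0.2] * 5, seed=101)


@pytest.fixture(scope="session")
def small_slices(small_cohort):
    return [s for rec in small_cohort for s in isolate(rec)]


def make_fake_record(patient_id: str, grade_left: int, grade_right: int,
                     size: tuple[int, int] = (8, 8)) -> RadiographRecord:
    """A minimal record (blank image) for split/label-plumbing tests."""
    return RadiographRecord(
        patient_id=patient_id, age=55.0, sex="F",
        image=np.zeros(size, dtype=np.uint8),
        grade_left=grade_left, grade_right=grade_right,
        pain_left=grade_left >= 1, pain_right=grade_right >= 1,
    )


def make_fake_slice(patient_id: str = "P0", side: str = "left", grade: int = 2,
                    seed: int = 0) -> KneeSlice:
    rng = np.random.default_rng(seed)
    return KneeSlice(patient_id=patient_id, side=side, grade=grade,
                     pixels=rng.random((224, 224)), pain=grade >= 1)
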