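import numpy as np
import pytest

from flupk import DoseRegimen, PopulationModel, Subject

#: documented fixture value for the unpublished typical clearance
CL_POP_FIXTURE = 3.0


@pytest.fixture
def pop_model() -> PopulationModel:
    return PopulationModel(cl_pop=CL_POP_FIXTURE)


@pytest.fixture
def ref_subject() -> Subject:
    """Adult at the model's reference scale: FFM 12 kg, CrCL 100 (overrides)."""
    return Subject(
        id="ref", age=30.0, sex="male", weight=40.0, height=140.0,
        serum_creatinine=0.8, crcl=100.0, ffm=12.0,
    )


@pytest.fixture
def child_subject() -> Subject:
    """A cohort-median-like 8-year-old."""
    return Subject(
        id="child", age=8.0, sex="male", weight=23.6, height=121.7,
        serum_creatinine=0.45,
    )


@pytest.fixture
def daily_regimen() -> DoseRegimen:
    return DoseRegimen.daily(30.0, 4)


def random_params(rng: np.random.Generator):
    """Physiologically plausible random two-compartment parameters."""
    from flupk import PKParameters

    return PKParameters(
        cl=rng.uniform(0.5, 15.0),
        vc=rng.uniform(4.0, 60.0),
        q=rng.uniform(0.3, 6.0),
        vp=rng.uniform(3.0, 50.0),
    )


def random_regimen(rng: np.random.Generator) -> DoseRegimen:
    n = int(rng.integers(3, 6))
    return DoseRegimen.daily(
        daily_dose=float(rng.uniform(5.0, 200.0)),
        n_days=n,
        duration=float(rng.uniform(0.25, 3.0)),
    )
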