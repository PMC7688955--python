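import numpy as np
import pytest

from her2forecast.grid import (
    BreastDomain,
    ImageVolume,
    StudyConfig,
    TreatmentSchedule,
)
from her2forecast.model import ModelParameters
from her2forecast.quantities import CellularityMap, DrugFieldSet


@pytest.fixture
def unit_volume():
    return ImageVolume(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))


def make_single_voxel(
    n0_frac=0.5,
    theta=1.0e6,
    k=0.0,
    d0=0.0,
    alpha1=0.0,
    alpha2=0.0,
    beta1=0.1,
    beta2=0.1,
    mu=0.0,
    dose_times=(),
    scan2_time=10.0,
    surgery_time=200.0,
    trastuzumab=0.0,
    chemo_map=1.0,
    config=None,
):
    """One-voxel model problem with uniform maps; the workhorse for
    closed-form ODE comparisons."""
    shape = (1, 1, 1)
    cfg = config or StudyConfig()
    state = CellularityMap(
        ImageVolume(np.full(shape, n0_frac * theta)), theta, np.ones(shape, bool)
    )
    domain = BreastDomain(
        ImageVolume(np.ones(shape)), ImageVolume(np.ones(shape))
    )
    schedule = TreatmentSchedule(tuple(dose_times), 0.0, scan2_time, surgery_time)
    m = ImageVolume(np.full(shape, chemo_map))
    drugs = DrugFieldSet(m, m, ImageVolume(np.full(shape, trastuzumab)), schedule)
    params = ModelParameters(
        d0=d0, k_map=np.full(shape, k), theta=theta,
        alpha1=alpha1, alpha2=alpha2, beta1=beta1, beta2=beta2, mu=mu,
        config=cfg,
    )
    return state, domain, drugs, params


@pytest.fixture
def single_voxel_factory():
    return make_single_voxel


def make_breast_phantom(
    shape=(16, 16, 16),
    spacing=(2.0, 2.0, 2.0),
    semiaxes=(13.0, 13.0, 13.0),
    tumor_radius=6.0,
    seed=0,
    config=None,
):
    """Small synthetic breast with a drawn scan-1 cellularity map."""
    from her2forecast.synthetic import (
        SyntheticPatientSpec,
        generate_breast_domain,
        generate_scan1_cellularity,
    )

    spec = SyntheticPatientSpec(
        shape=shape, spacing=spacing, breast_semiaxes_mm=semiaxes,
        tumor_radius_mm=tumor_radius, seed=seed,
        config=config or StudyConfig(),
    )
    domain = generate_breast_domain(spec)
    cells = generate_scan1_cellularity(spec, domain)
    return spec, domain, cells


@pytest.fixture
def breast_phantom_factory():
    return make_breast_phantom
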