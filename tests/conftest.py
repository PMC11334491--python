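import math

import numpy as np
import pytest

from metmorph import PhantomSpec, detect_necrosis, segment_ce, voxelize

SPHERE_VOLUME = 4.0 / 3.0 * math.pi  # unit-radius sphere, cm^3
SPHERE_AREA = 4.0 * math.pi  # cm^2
CORE_VOLUME = 4.0 / 3.0 * math.pi * 0.5**3  # core fraction 0.5

#: threshold midway between background (20) and enhancing (100) levels
MID_THRESHOLD = 60.0


@pytest.fixture(scope="session")
def unit_sphere_spec():
    return PhantomSpec(base_radius=1.0)


@pytest.fixture(scope="session")
def shell_spec():
    """Unit sphere with a concentric necrotic core of half its radius."""
    return PhantomSpec(base_radius=1.0, core_radius_fraction=0.5)


@pytest.fixture(scope="session")
def perturbed_spec():
    """Oblate phantom: unit base radius with a zonal l=2 perturbation."""
    return PhantomSpec(base_radius=1.0, perturbation=((2, 0, 0.2),))


@pytest.fixture(scope="session")
def sphere_mask_05(unit_sphere_spec):
    """Noiseless unit sphere voxelized at 0.5 mm, segmented and hole-filled."""
    img = voxelize(unit_sphere_spec, (0.5, 0.5, 0.5))
    return detect_necrosis(segment_ce(img, MID_THRESHOLD))


@pytest.fixture(scope="session")
def shell_mask_05(shell_spec):
    """Noiseless hollow-shell phantom at 0.5 mm with necrosis labeled."""
    img = voxelize(shell_spec, (0.5, 0.5, 0.5))
    return detect_necrosis(segment_ce(img, MID_THRESHOLD))


def exponential_records(rng, n, hazards, censor_rate=1e-9, max_followup=np.inf, covariates=None):
    """Small helper: exponential event times with per-subject hazards."""
    from metmorph.cohort import CohortRecord

    hazards = np.broadcast_to(np.asarray(hazards, dtype=float), (n,))
    event_time = rng.exponential(1.0 / hazards)
    censor = np.minimum(rng.exponential(1.0 / censor_rate, n), max_followup)
    time = np.minimum(event_time, censor)
    event = event_time <= censor
    covariates = covariates or {}
    return [
        CohortRecord(
            lesion_id=f"r{i}",
            covariates={k: float(v[i]) for k, v in covariates.items()},
            time=float(time[i]),
            event=bool(event[i]),
        )
        for i in range(n)
    ]
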