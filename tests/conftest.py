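"""Shared fixtures: small, fast synthetic IBII runs reused across test modules.

The small configuration (40x24 solver mesh, 120x75 px camera, reduced
smoothing kernels scaled to the image size) keeps single tests in the
seconds range; the full-size study configuration is exercised only by the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ibii import (
    CrackSpec,
    FieldSequence,
    ImpactPulse,
    MaterialOrientation,
    OrthotropicPlaneStress,
    SmoothingSpec,
    SpecimenGeometry,
    compute_kinematics,
    sample_to_camera,
    simulate_ibii,
)

BONE = dict(Q11=26.0, Q22=15.0, Q12=4.16, Q66=7.0, rho=2000.0)

SMALL_MESH = (40, 24)
SMALL_PIXELS = (120, 75)
SMALL_SMOOTHING = SmoothingSpec(spatial_radius_px=8, temporal_window=11, temporal_order=3)


@pytest.fixture(scope="session")
def material() -> OrthotropicPlaneStress:
    return OrthotropicPlaneStress.from_gpa(**BONE)


@pytest.fixture(scope="session")
def small_sim(material):
    """Aligned longitudinal impact on the coarse solver mesh."""
    return simulate_ibii(material, mesh=SMALL_MESH)


@pytest.fixture(scope="session")
def small_sim_misaligned(material):
    """Tilted impact pulse activating a shear response."""
    return simulate_ibii(material, pulse=ImpactPulse(misalignment_coeff=0.3), mesh=SMALL_MESH)


#: failure-study loading: the reflected tensile wave peaks just above the
#: 100 MPa trigger (spall regime: the strength is only just exceeded, so
#: fracture occurs near the rounded wave peak), and the failure gauge is
#: processed with a short temporal window that resolves the near-instant
#: traction release of the synthetic crack
FAILURE_PULSE = ImpactPulse(amplitude=115e6, duration=10e-6)
FAILURE_SMOOTHING = SmoothingSpec(spatial_radius_px=8, temporal_window=7, temporal_order=3)


@pytest.fixture(scope="session")
def small_crack_sim(material):
    """Stress-triggered crack at mid-length in the spall regime."""
    return simulate_ibii(
        material,
        pulse=FAILURE_PULSE,
        mesh=SMALL_MESH,
        crack=CrackSpec(xc=8e-3, trigger_stress=100e6),
    )


def camera_fields(sim, pixels=SMALL_PIXELS):
    return sample_to_camera(sim, pixels=pixels)


def kinematics_from_truth(sim, pixels=SMALL_PIXELS, spec=SMALL_SMOOTHING):
    """FieldSequence carrying the solver's own strain/acceleration fields at
    pixel centres (bypasses the imaging chain for identification tests)."""
    fields, gt = sample_to_camera(sim, pixels=pixels)
    kin = FieldSequence(
        pixel_size=fields.pixel_size, dt=fields.dt,
        ux=fields.ux, uy=fields.uy,
        ax=gt["ax"], ay=gt["ay"],
        eps_xx=gt["eps_xx"], eps_yy=gt["eps_yy"], gamma_xy=gt["gamma_xy"],
        meta=fields.meta,
    )
    kin.eps_xx_rate = np.gradient(gt["eps_xx"], fields.dt, axis=0)
    kin.eps_yy_rate = np.gradient(gt["eps_yy"], fields.dt, axis=0)
    kin.gamma_xy_rate = np.gradient(gt["gamma_xy"], fields.dt, axis=0)
    return kin, gt


@pytest.fixture(scope="session")
def truth_kin(small_sim):
    kin, _ = kinematics_from_truth(small_sim)
    return kin


@pytest.fixture(scope="session")
def truth_kin_misaligned(small_sim_misaligned):
    kin, gt = kinematics_from_truth(small_sim_misaligned)
    return kin, gt


@pytest.fixture(scope="session")
def processed_crack_kin(small_crack_sim):
    """Smoothed + raw kinematics computed from the crack run's displacement
    fields (camera sampling, no imaging noise), with the failure-study
    temporal window."""
    fields, _ = sample_to_camera(small_crack_sim, pixels=SMALL_PIXELS)
    kin = compute_kinematics(fields, FAILURE_SMOOTHING)
    raw = compute_kinematics(fields, FAILURE_SMOOTHING, smooth=False)
    return kin, raw
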