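"""Plane-stress linear orthotropic constitutive law for cortical-bone-like plates.

The in-plane elastic response is described by the reduced stiffness matrix

    [sxx]   [Q11  Q12   0 ] [exx]
    [syy] = [Q12  Q22   0 ] [eyy]
    [sxy]   [ 0    0   Q66] [gxy]

with ``gxy`` the engineering shear strain (twice the tensorial one).  Material
axis 1 is the bone shaft (longitudinal) axis; a transverse specimen simply has
Q11 and Q22 interchanged in the specimen frame.  All quantities are SI (Pa,
kg/m^3); GPa appears only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "OrthotropicPlaneStress",
    "EngineeringConstants",
    "MaterialOrientation",
    "q_from_engineering",
    "engineering_from_q",
    "minor_poisson_from_reciprocity",
    "stress_from_strain",
]

#: relative tolerance for accepting user-supplied engineering constants whose
#: Poisson ratios should satisfy the orthotropy reciprocity relation
RECIPROCITY_RTOL = 1e-6


class MaterialOrientation(str, Enum):
    """Mapping of the specimen x-axis onto the material axes.

    ``longitudinal``: specimen x parallel to material axis 1 (bone shaft).
    ``transverse``: specimen x parallel to material axis 2; in the specimen
    frame Q11 and Q22 are interchanged.
    """

    LONGITUDINAL = "longitudinal"
    TRANSVERSE = "transverse"


@dataclass(frozen=True)
class OrthotropicPlaneStress:
    """Reduced plane-stress stiffness matrix and density.

    Parameters are in Pa (stiffnesses) and kg/m^3 (density).  ``rho`` may be
    None for purely constitutive conversions.
    """

    Q11: float
    Q22: float
    Q12: float
    Q66: float
    rho: float | None = None

    def __post_init__(self) -> None:
        if min(self.Q11, self.Q22, self.Q66) <= 0:
            raise ValueError("Q11, Q22 and Q66 must be positive")
        if self.Q11 * self.Q22 - self.Q12**2 <= 0:
            raise ValueError("stiffness matrix is not positive definite")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("density must be positive")

    def matrix(self, orientation: MaterialOrientation | str = MaterialOrientation.LONGITUDINAL) -> np.ndarray:
        """3x3 stiffness matrix in the specimen frame."""
        q = self.in_specimen_frame(orientation)
        return np.array(
            [[q.Q11, q.Q12, 0.0], [q.Q12, q.Q22, 0.0], [0.0, 0.0, q.Q66]]
        )

    def in_specimen_frame(self, orientation: MaterialOrientation | str) -> "OrthotropicPlaneStress":
        """Swap Q11/Q22 for a transverse specimen; identity for longitudinal."""
        if MaterialOrientation(orientation) is MaterialOrientation.TRANSVERSE:
            return replace(self, Q11=self.Q22, Q22=self.Q11)
        return self

    @classmethod
    def from_gpa(cls, Q11, Q22, Q12, Q66, rho=None) -> "OrthotropicPlaneStress":
        return cls(Q11 * 1e9, Q22 * 1e9, Q12 * 1e9, Q66 * 1e9, rho)


@dataclass(frozen=True)
class EngineeringConstants:
    """Engineering elastic constants of the orthotropic plate (Pa, -)."""

    E11: float
    E22: float
    nu12: float
    nu21: float
    G12: float

    def __post_init__(self) -> None:
        if min(self.E11, self.E22, self.G12) <= 0:
            raise ValueError("moduli must be positive")
        if self.nu12 * self.nu21 >= 1:
            raise ValueError("nu12*nu21 must be < 1")


def minor_poisson_from_reciprocity(nu12: float, E11: float, E22: float) -> float:
    """Minor Poisson's ratio implied by orthotropy reciprocity.

    nu21 = nu12 * E22 / E11, e.g. nu12=0.18, E11=20.8, E22=14.1 -> 0.12.
    """
    if E11 == 0:
        raise ValueError("E11 must be nonzero")
    return nu12 * E22 / E11


def q_from_engineering(
    ec: EngineeringConstants, *, project_to_reciprocal: bool = False
) -> OrthotropicPlaneStress:
    """Reduced stiffnesses from engineering constants.

    Q11 = E11/(1 - nu12*nu21), Q22 = E22/(1 - nu12*nu21),
    Q12 = nu21*Q11 = nu12*Q22, Q66 = G12.

    Experimental tables usually violate reciprocity; with
    ``project_to_reciprocal`` the supplied nu21 is replaced by the value
    implied by nu12, E11 and E22 before converting.  Otherwise a violation
    beyond ``RECIPROCITY_RTOL`` raises.
    """
    nu21 = ec.nu21
    expected = minor_poisson_from_reciprocity(ec.nu12, ec.E11, ec.E22)
    if project_to_reciprocal:
        nu21 = expected
    elif abs(nu21 * ec.E11 - ec.nu12 * ec.E22) > RECIPROCITY_RTOL * abs(ec.nu12 * ec.E22):
        raise ValueError(
            f"nu21={nu21} violates reciprocity (expected {expected:.6g}); "
            "pass project_to_reciprocal=True to recompute it"
        )
    denom = 1.0 - ec.nu12 * nu21
    if denom <= 0:
        raise ValueError("nu12*nu21 must be < 1")
    Q11 = ec.E11 / denom
    Q22 = ec.E22 / denom
    return OrthotropicPlaneStress(Q11=Q11, Q22=Q22, Q12=nu21 * Q11, Q66=ec.G12)


def engineering_from_q(q: OrthotropicPlaneStress) -> EngineeringConstants:
    """Inverse of :func:`q_from_engineering` (positive definite q required)."""
    nu21 = q.Q12 / q.Q11
    nu12 = q.Q12 / q.Q22
    denom = 1.0 - nu12 * nu21
    return EngineeringConstants(
        E11=q.Q11 * denom, E22=q.Q22 * denom, nu12=nu12, nu21=nu21, G12=q.Q66
    )


def stress_from_strain(
    q: OrthotropicPlaneStress,
    orientation: MaterialOrientation | str,
    eps_xx: np.ndarray,
    eps_yy: np.ndarray,
    gamma_xy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise stress fields from strain fields (engineering shear in)."""
    eps_xx = np.asarray(eps_xx, dtype=float)
    eps_yy = np.asarray(eps_yy, dtype=float)
    gamma_xy = np.asarray(gamma_xy, dtype=float)
    if not (eps_xx.shape == eps_yy.shape == gamma_xy.shape):
        raise ValueError("strain fields must share one shape")
    qs = q.in_specimen_frame(orientation)
    sxx = qs.Q11 * eps_xx + qs.Q12 * eps_yy
    syy = qs.Q12 * eps_xx + qs.Q22 * eps_yy
    sxy = qs.Q66 * gamma_xy
    return sxx, syy, sxy
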