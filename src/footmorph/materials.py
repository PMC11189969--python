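"""Constitutive models for the foot finite-element specification.

Three materials cover the model: linearly elastic bone (E = 10 GPa,
nu = 0.34), a second-order polynomial hyperelastic bulk soft tissue

    U = sum_{i+j=1..2} C_ij (I1b - 3)^i (I2b - 3)^j
        + sum_{i: D_i > 0} (1/D_i) (J_el - 1)^(2i)

with the deviatoric invariants I1b = sum lb_i^2, I2b = sum lb_i^-2 built
from the J^(-1/3)-scaled principal stretches, and a first-order Ogden skin

    U = (2 mu / alpha^2) (l1^a + l2^a + l3^a - 3)

treated as incompressible (no volumetric term; the stretches entering it
are deviatoric).  Units are N·mm^-2 (MPa) and mm throughout.  A vanishing
volumetric coefficient (D2 = 0) means the corresponding term is absent,
not infinitely stiff.

``uniaxial_nominal_stress`` evaluates the analytic nominal (first
Piola-Kirchhoff) stress dU/dl under the incompressible uniaxial
substitution l2 = l3 = l^(-1/2), the standard verification output for
these models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearElasticMaterial",
    "PolynomialN2Material",
    "OgdenN1Material",
    "PrincipalStretches",
    "deviatoric_invariants",
    "strain_energy_polynomial",
    "strain_energy_ogden",
    "uniaxial_nominal_stress",
]


@dataclass(frozen=True)
class LinearElasticMaterial:
    """Isotropic linear elasticity; defaults are the bone values."""

    youngs_modulus: float = 10000.0  # MPa
    poissons_ratio: float = 0.34

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poissons_ratio < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")


@dataclass(frozen=True)
class PolynomialN2Material:
    """Second-order polynomial hyperelastic model (bulk soft tissue defaults)."""

    C10: float = 0.8556    # N mm^-2
    C01: float = -0.0584
    C20: float = 0.03900
    C11: float = -0.02319
    C02: float = 0.00851
    D1: float = 3.65273    # mm^2 N^-1
    D2: float = 0.000


@dataclass(frozen=True)
class OgdenN1Material:
    """First-order Ogden hyperelastic model (skin defaults)."""

    mu: float = 0.122      # MPa
    alpha: float = 18.0

    def __post_init__(self) -> None:
        if not self.mu * self.alpha > 0:
            raise ValueError("mu * alpha must be positive (ground-state stiffness)")


@dataclass(frozen=True)
class PrincipalStretches:
    """Principal stretches of a deformation state; all strictly positive."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if not (self.l1 > 0 and self.l2 > 0 and self.l3 > 0):
            raise ValueError("principal stretches must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3], dtype=np.float64)


def _stretches(s) -> np.ndarray:
    if isinstance(s, PrincipalStretches):
        return s.as_array()
    arr = np.asarray(s, dtype=np.float64).ravel()
    if arr.shape != (3,):
        raise ValueError("expected three principal stretches")
    if np.any(arr <= 0):
        raise ValueError("principal stretches must be strictly positive")
    return arr


def deviatoric_invariants(s) -> tuple[float, float, float]:
    """First/second deviatoric strain invariants and elastic volume ratio.

    J_el = l1 l2 l3; the deviatoric stretches lb_i = J_el^(-1/3) l_i give
    I1b = sum lb_i^2 and I2b = sum lb_i^-2 (equal to the second invariant
    of the deviatoric right Cauchy-Green tensor because prod lb_i = 1).
    Pure dilation leaves both at 3.
    """
    lam = _stretches(s)
    j = float(np.prod(lam))
    lb = lam * j ** (-1.0 / 3.0)
    return float(np.sum(lb ** 2)), float(np.sum(lb ** -2)), j


def strain_energy_polynomial(material: PolynomialN2Material, s) -> float:
    """Strain energy per unit reference volume (N·mm^-2) of the N=2 polynomial model."""
    i1, i2, j = deviatoric_invariants(s)
    a, b = i1 - 3.0, i2 - 3.0
    u = (material.C10 * a + material.C01 * b
         + material.C20 * a * a + material.C11 * a * b + material.C02 * b * b)
    if material.D1 > 0:
        u += (j - 1.0) ** 2 / material.D1
    if material.D2 > 0:
        u += (j - 1.0) ** 4 / material.D2
    return float(u)


def strain_energy_ogden(material: OgdenN1Material, s) -> float:
    """Strain energy per unit reference volume of the incompressible N=1 Ogden model."""
    lam = _stretches(s)
    a = material.alpha
    return float(2.0 * material.mu / a ** 2 * (np.sum(lam ** a) - 3.0))


def _uniaxial_invariant_derivatives(lam: float) -> tuple[float, float, float, float]:
    """I1b, I2b and their derivatives under l2 = l3 = lam^(-1/2) (J = 1)."""
    i1 = lam ** 2 + 2.0 / lam
    i2 = lam ** -2 + 2.0 * lam
    di1 = 2.0 * lam - 2.0 / lam ** 2
    di2 = -2.0 / lam ** 3 + 2.0
    return i1, i2, di1, di2


def uniaxial_nominal_stress(material, lam: float) -> float:
    """Analytic nominal stress dU/dl of an incompressible uniaxial state (MPa).

    Substituting l2 = l3 = l^(-1/2) (isochoric) into the strain energy and
    differentiating with respect to the loading-axis stretch gives the
    nominal (engineering) stress; at l = 1 the reference state is
    stress-free for every admissible parameter set.
    """
    lam = float(lam)
    if lam <= 0:
        raise ValueError("stretch must be strictly positive")
    if isinstance(material, PolynomialN2Material):
        i1, i2, di1, di2 = _uniaxial_invariant_derivatives(lam)
        a, b = i1 - 3.0, i2 - 3.0
        du_di1 = material.C10 + 2.0 * material.C20 * a + material.C11 * b
        du_di2 = material.C01 + material.C11 * a + 2.0 * material.C02 * b
        return float(du_di1 * di1 + du_di2 * di2)
    if isinstance(material, OgdenN1Material):
        a = material.alpha
        # d/dl [ 2mu/a^2 (l^a + 2 l^(-a/2) - 3) ]
        return float(2.0 * material.mu / a * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0)))
    raise TypeError(f"no uniaxial stress rule for {type(material).__name__}")
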