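"""Constitutive models for the growth simulation.

Two materials:

* ``neo_hookean`` — compressible neo-Hookean solid for bone and mandible,
  parametrised by Young's modulus E and Poisson's ratio nu.  Cauchy stress
  sigma = (mu/J)(B - I) + (lambda ln J / J) I.

* ``cell_growth`` — osmotic tissue-expansion material for brain and muscle.
  The same neo-Hookean form describes the solid ground matrix (moduli mu_s,
  lambda_s, soft relative to bone); superposed is an osmotic pressure

      pi = RT * ( cr / (J - phir) - ce )

  where phir is the intracellular solid volume fraction (per reference
  volume), cr the membrane-impermeant intracellular solute content, ce the
  extracellular osmolarity and RT the osmotic coefficient.  Growth is driven
  by ramping phir and cr: raising cr pulls water in, swelling the tissue
  until matrix stress balances pi.  With cr = ce (1 - phir) the baseline
  J = 1 is exactly stress free.

Units: lengths mm, pressures MPa, osmolarities in mOsm used verbatim
(ce = 300, cr ramping from 210).  RT defaults to R*T at 310 K expressed in
MPa per mOsm (8.314e-6 * 310), which keeps the osmotic pressure scale in
its physiological ratio to the 300 MPa bone modulus; only that ratio
matters to the mechanics, and it is exposed in the material config.

All stress/tangent routines are vectorised over elements and return the
first Piola-Kirchhoff stress P(F) and the consistent material tangent
A = dP/dF used by the Newton solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..mesh import DOMAIN_NAMES, MUSCLE_DOMAINS

__all__ = [
    "NeoHookean",
    "CellGrowth",
    "MaterialSpec",
    "default_materials",
    "StepFailure",
    "pk1_stress",
    "cauchy_from_pk1",
    "free_swelling_equilibrium",
]


class StepFailure(Exception):
    """Recoverable constitutive failure (element inversion, J <= phir);
    signals the solver to bisect the load step."""


@dataclass(frozen=True)
class NeoHookean:
    """Compressible neo-Hookean solid (E in model pressure units, i.e. MPa)."""

    E: float = 300.0
    nu: float = 0.3

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must be in (-1, 0.5)")

    @property
    def mu(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class CellGrowth:
    """Osmotic cell-growth material.

    phir and cr given here are the reference (baseline) values; the solver
    ramps them according to the growth schedule.  The baseline is stress
    free iff cr = ce * (1 - phir).
    """

    mu_s: float = 0.01
    lam_s: float = 0.01
    phir: float = 0.3
    cr: float = 210.0
    ce: float = 300.0
    #: width of the numerical regularisation layer above the J = phir
    #: singularity: for J - phir < reg_width the osmotic term continues
    #: linearly (C^1), so locally confined elements saturate at a large
    #: finite pressure instead of destroying the Newton iteration
    reg_width: float = 0.1
    #: R*T at body temperature: pi [MPa] = RT * c [mOsm]; keeps the
    #: osmotic-pressure scale (~0.77 MPa at 300 mOsm) in physical ratio to
    #: the 300 MPa bone modulus.
    RT: float = 8.314e-6 * 310.0

    def __post_init__(self) -> None:
        if self.phir < 0:
            raise ValueError("phir must be >= 0")
        if self.ce <= 0:
            raise ValueError("ce must be positive")
        if self.mu_s <= 0 or self.lam_s < 0:
            raise ValueError("ground-matrix moduli must be positive")

    def osmotic_pressure(self, J: np.ndarray | float, phir: float | None = None, cr: float | None = None):
        phir = self.phir if phir is None else phir
        cr = self.cr if cr is None else cr
        return self.RT * (cr / (np.asarray(J) - phir) - self.ce)


#: Per-domain material assignment.
MaterialSpec = dict


def default_materials() -> MaterialSpec:
    """Bone/mandible as 300 MPa neo-Hookean; brain and muscles as baseline
    cell-growth tissue (stress free at J = 1)."""
    mats: MaterialSpec = {
        "bone": NeoHookean(E=300.0, nu=0.3),
        "mandible": NeoHookean(E=300.0, nu=0.3),
        "brain": CellGrowth(),
    }
    for m in MUSCLE_DOMAINS:
        mats[m] = CellGrowth()
    return mats


def _neo_hookean_pk1(F: np.ndarray, mu: np.ndarray, lam: np.ndarray, tangent: bool = True):
    """P and tangent for the neo-Hookean form, vectorised over elements."""
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise StepFailure("element inversion (det F <= 0)")
    Finv = np.linalg.inv(F)
    FinvT = np.transpose(Finv, (0, 2, 1))
    lnJ = np.log(J)
    mu = mu[:, None, None]
    lamln = (lam * lnJ)[:, None, None]
    P = mu * (F - FinvT) + lamln * FinvT
    A = None
    if tangent:
        # A_{iJkL} = mu d_ik d_JL + (mu - lam lnJ) Fit_iL Fit_kJ + lam Fit_iJ Fit_kL
        eye = np.eye(3)
        A = (
            mu[..., None, None] * np.einsum("ik,JL->iJkL", eye, eye)[None]
            + (mu - lamln)[..., None, None] * np.einsum("miL,mkJ->miJkL", FinvT, FinvT)
            + lam[:, None, None, None, None] * np.einsum("miJ,mkL->miJkL", FinvT, FinvT)
        )
    return P, A, J, FinvT


def pk1_stress(
    F: np.ndarray,
    material: NeoHookean | CellGrowth,
    phir: float | None = None,
    cr: float | None = None,
    tangent: bool = True,
    strict: bool = True,
):
    """First Piola-Kirchhoff stress and consistent tangent dP/dF.

    Parameters
    ----------
    F : (m, 3, 3) or (3, 3) deformation gradients
    material : NeoHookean or CellGrowth
    phir, cr : float, optional
        Current growth state for cell-growth material (defaults to the
        reference values stored on the material).

    Raises
    ------
    StepFailure
        If det F <= 0, or (with ``strict``, the default) det F <= phir for
        the cell-growth material — the osmolarity denominator J - phir must
        stay positive.  With ``strict=False`` the regularised linear
        continuation of the osmotic term is used below ``reg_width``; the
        equilibrium solver relies on this so locally confined elements
        saturate instead of aborting the step.
    """
    single = F.ndim == 2
    F = F[None] if single else F
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    m = len(F)
    if isinstance(material, NeoHookean):
        mu = np.full(m, material.mu)
        lam = np.full(m, material.lam)
        P, A, _, _ = _neo_hookean_pk1(F, mu, lam, tangent=tangent)
    else:
        phir = material.phir if phir is None else phir
        cr = material.cr if cr is None else cr
        mu = np.full(m, material.mu_s)
        lam = np.full(m, material.lam_s)
        P, A, J, FinvT = _neo_hookean_pk1(F, mu, lam, tangent=tangent)
        if strict and np.any(J <= phir):
            raise StepFailure("det F <= phir in cell-growth material")
        x = J - phir
        eps = material.reg_width
        xs = np.maximum(x, eps)
        inv = np.where(x >= eps, 1.0 / xs, (2.0 * eps - x) / eps**2)
        dinv = np.where(x >= eps, -1.0 / xs**2, -1.0 / eps**2)
        pi = material.RT * (cr * inv - material.ce)
        # P_osm = -pi J F^{-T}
        P = P - (pi * J)[:, None, None] * FinvT
        if tangent:
            dpi = material.RT * cr * dinv
            coef = (dpi * J + pi) * J
            A = (
                A
                - coef[:, None, None, None, None] * np.einsum("miJ,mkL->miJkL", FinvT, FinvT)
                + (pi * J)[:, None, None, None, None] * np.einsum("miL,mkJ->miJkL", FinvT, FinvT)
            )
    if single:
        return P[0], (A[0] if A is not None else None)
    return P, A


def strain_energy_density(
    F: np.ndarray,
    material: NeoHookean | CellGrowth,
    phir: float | None = None,
    cr: float | None = None,
) -> np.ndarray:
    """Strain-energy density per reference volume (model pressure units).

    Both materials are hyperelastic: the neo-Hookean part is
    W = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2, and the osmotic term
    derives from the potential whose J-derivative is -pi (with the same
    regularised continuation as the stress).  The equilibrium solver uses
    the total energy as the line-search merit function.
    """
    single = F.ndim == 2
    F = F[None] if single else F
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise StepFailure("element inversion (det F <= 0)")
    i1 = np.einsum("mij,mij->m", F, F)
    lnJ = np.log(J)
    if isinstance(material, NeoHookean):
        mu, lam = material.mu, material.lam
        w = 0.5 * mu * (i1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
    else:
        phir = material.phir if phir is None else phir
        cr = material.cr if cr is None else cr
        mu, lam = material.mu_s, material.lam_s
        w = 0.5 * mu * (i1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
        x = J - phir
        eps = material.reg_width
        # G(x) = integral of the (regularised) 1/x factor
        g = np.where(
            x >= eps,
            np.log(np.maximum(x, 1e-300)),
            np.log(eps) + (2.0 * eps * x - 0.5 * x**2 - 1.5 * eps**2) / eps**2,
        )
        w = w - material.RT * (cr * g - material.ce * J)
    return w[0] if single else w


def cauchy_from_pk1(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma = P F^T / J."""
    single = F.ndim == 2
    F = F[None] if single else F
    P = P[None] if single else P
    J = np.linalg.det(F)
    sig = np.einsum("miJ,mkJ->mik", P, F) / J[:, None, None]
    return sig[0] if single else sig


def free_swelling_equilibrium(
    material: CellGrowth, phir: float | None = None, cr: float | None = None
) -> float:
    """Volume ratio J of an unconstrained homogeneous cell-growth body.

    Solves the scalar balance of volumetric matrix stress against osmotic
    pressure,

        (mu_s (J^{2/3} - 1) + lambda_s ln J) / J = RT (cr/(J - phir) - ce),

    for J > phir by bracketing and bisection (Brent).  This is the analytic
    oracle the FE patch test is checked against.
    """
    from scipy.optimize import brentq

    phir = material.phir if phir is None else phir
    cr = material.cr if cr is None else cr

    def g(J: float) -> float:
        solid = (material.mu_s * (J ** (2.0 / 3.0) - 1.0) + material.lam_s * np.log(J)) / J
        return solid - material.RT * (cr / (J - phir) - material.ce)

    lo = phir + 1e-9 if phir > 0 else 1e-9
    hi = max(2.0, 2.0 * (phir + cr / material.ce))
    for _ in range(60):
        if g(lo) < 0 < g(hi):
            break
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("no free-swelling root in bracket; parameters inconsistent")
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))
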