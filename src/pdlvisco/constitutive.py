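"""Closed-form viscoelastic constitutive relations for the periodontal ligament.

The PDL is idealised as a fiber spring (modulus ``Etf``) in parallel with a
Maxwell matrix branch (spring ``Em`` in series with a dashpot ``eta``) — a
standard linear solid.  Under a step stress the linear creep compliance is

    D(t) = 1/Etf - [Em / (Etf (Etf + Em))] * exp(-t / tau1),
    tau1 = eta (Etf + Em) / (Etf Em),

so D(0) = 1/(Etf+Em) (two springs in parallel) and D(inf) = 1/Etf (the
Maxwell branch has fully relaxed).

The nonlinear (Schapery-form) strain law used for creep fitting multiplies
the compliance terms of the equivalent first-order generalized Kelvin–Voigt
representation by dimensionless fiber-content factors g0, g1, g2:

    eps(t) = g0 * D0' * sigma0  -  g1 * g2 * |D1'| * (1 - exp(-t/tau1)) * sigma0

with D0' = (2 Em + Etf)/(Etf (Etf + Em)), D1' = -Em/(Etf (Etf + Em)).

Note D0' is *not* the SLS instantaneous compliance 1/(Etf+Em); the strain
law is implemented with D0' as written because the published fitted
parameter sets presuppose that form.  The linear SLS compliance
(:func:`creep_compliance`) is kept as a separate, internally consistent
operation.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SLSParameters",
    "SchaperyParameters",
    "KelvinVoigtParameters",
    "StepLoad",
    "ReducedCreepParameters",
    "creep_compliance",
    "kelvin_voigt_from_sls",
    "strain_response",
    "reduced_from_full",
    "full_from_reduced",
    "g1_from_strains",
    "stress_from_load",
]


class ValidationError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


class DomainError(ValueError):
    """Raised when an evaluation point lies outside the physical domain."""


class DegenerateInputError(ValueError):
    """Raised when an otherwise valid input makes a quantity undefined."""


@dataclass(frozen=True)
class SLSParameters:
    """Standard-linear-solid material parameters.

    Attributes
    ----------
    Etf : float
        Fiber elastic modulus, MPa.  Parallel spring.
    Em : float
        Matrix elastic modulus, MPa.  Spring of the Maxwell branch.
    eta : float
        Matrix viscosity, MPa*s.  Dashpot of the Maxwell branch.
    """

    Etf: float
    Em: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("Etf", "Em", "eta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def tau1(self) -> float:
        """Retardation time eta*(Etf+Em)/(Etf*Em), s."""
        return self.eta * (self.Etf + self.Em) / (self.Etf * self.Em)


@dataclass(frozen=True)
class SchaperyParameters:
    """Dimensionless nonlinear factors of the fiber-content strain law.

    ``g0`` scales the instantaneous term, ``g2`` the transient loading term
    (negative in the creep regime of the published fits), and ``g1`` is the
    strain-recovery factor, equal to 1 for fully rebounding tissue.
    """

    g0: float
    g1: float = 1.0
    g2: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.g0):
            raise ValidationError(f"g0 must be finite, got {self.g0!r}")
        if not np.isfinite(self.g2):
            raise ValidationError(f"g2 must be finite, got {self.g2!r}")
        if not (np.isfinite(self.g1) and self.g1 >= 0):
            raise ValidationError(f"g1 must be finite and >= 0, got {self.g1!r}")


@dataclass(frozen=True)
class KelvinVoigtParameters:
    """First-order generalized Kelvin–Voigt compliance parameters.

    D(t) = D0p + D1p * exp(-t/tau1) matched to the SLS, so the transient
    compliance D1p is negative and D0p + D1p equals the equilibrium
    compliance 1/Etf.
    """

    D0p: float
    D1p: float
    tau1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.D0p) and self.D0p > 0):
            raise ValidationError(f"D0p must be finite and > 0, got {self.D0p!r}")
        if not np.isfinite(self.D1p):
            raise ValidationError(f"D1p must be finite, got {self.D1p!r}")
        if not (np.isfinite(self.tau1) and self.tau1 > 0):
            raise ValidationError(f"tau1 must be finite and > 0, got {self.tau1!r}")


@dataclass(frozen=True)
class StepLoad:
    """A step stress held constant for t >= 0.

    ``sigma0`` is in the same stress unit as the moduli it multiplies
    (MPa when used with :class:`SLSParameters` defaults).
    """

    sigma0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma0) and self.sigma0 >= 0):
            raise ValidationError(f"sigma0 must be finite and >= 0, got {self.sigma0!r}")

    @classmethod
    def from_force(cls, F_mN: float, S_mm2: float) -> "StepLoad":
        """Step stress in MPa from a force in mN over an area in mm^2."""
        return cls(stress_from_load(F_mN, S_mm2) / 1000.0)


@dataclass(frozen=True)
class ReducedCreepParameters:
    """Identifiable reparameterization of the creep strain law.

    eps(t) = A + B * (1 - exp(-t/tau)); a single hold-stage curve
    determines exactly (A, B, tau).
    """

    A: float
    B: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValidationError(f"tau must be finite and > 0, got {self.tau!r}")
        if not np.isfinite(self.A) or not np.isfinite(self.B):
            raise ValidationError("A and B must be finite")

    def strain(self, t: np.ndarray | float) -> np.ndarray | float:
        t = _check_time(t)
        return self.A + self.B * (1.0 - np.exp(-t / self.tau))


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    return t


def creep_compliance(sls: SLSParameters, t) -> np.ndarray | float:
    """Linear SLS creep compliance D(t), MPa^-1.

    D(0) = 1/(Etf+Em); D(t) increases monotonically to 1/Etf.
    """
    t = _check_time(t)
    Etf, Em = sls.Etf, sls.Em
    return 1.0 / Etf - (Em / (Etf * (Etf + Em))) * np.exp(-t / sls.tau1)


def kelvin_voigt_from_sls(sls: SLSParameters) -> KelvinVoigtParameters:
    """Map SLS parameters to the first-order Kelvin–Voigt compliance triple.

    Satisfies D0p + D1p = 1/Etf exactly and shares the SLS retardation time.
    """
    Etf, Em = sls.Etf, sls.Em
    denom = Etf * (Etf + Em)
    return KelvinVoigtParameters(
        D0p=(2.0 * Em + Etf) / denom,
        D1p=-Em / denom,
        tau1=sls.tau1,
    )


def strain_response(
    sch: SchaperyParameters,
    sls: SLSParameters,
    load: StepLoad,
    t,
    alpha_sigma: float = 1.0,
) -> np.ndarray | float:
    """Fiber-content creep strain under a step stress.

    eps(t) = g0*D0p*sigma0 - g1*g2*|D1p|*(1 - exp(-(t/tau1)**alpha_sigma))*sigma0.

    ``alpha_sigma`` is a stress-dependent reduced-time exponent hook; the
    default 1 recovers the law used for all published fits.
    """
    t = _check_time(t)
    kv = kelvin_voigt_from_sls(sls)
    transient = 1.0 - np.exp(-((t / kv.tau1) ** alpha_sigma))
    return (
        sch.g0 * kv.D0p * load.sigma0
        - sch.g1 * sch.g2 * abs(kv.D1p) * transient * load.sigma0
    )


def reduced_from_full(
    sch: SchaperyParameters, sls: SLSParameters, load: StepLoad
) -> ReducedCreepParameters:
    """Collapse (g0, g1, g2, SLS, sigma0) to the identifiable (A, B, tau)."""
    kv = kelvin_voigt_from_sls(sls)
    return ReducedCreepParameters(
        A=sch.g0 * kv.D0p * load.sigma0,
        B=-sch.g1 * sch.g2 * abs(kv.D1p) * load.sigma0,
        tau=kv.tau1,
    )


def full_from_reduced(
    red: ReducedCreepParameters,
    Etf: float,
    Em: float,
    sigma0: float,
    g1: float = 1.0,
) -> tuple[SchaperyParameters, SLSParameters]:
    """Invert :func:`reduced_from_full` for fixed (Etf, Em, sigma0, g1).

    Returns the (Schapery, SLS) pair that reproduces ``red`` exactly; the
    map is bijective in (g0, g2, eta) for g1 > 0 and sigma0 > 0.
    """
    if sigma0 <= 0:
        raise ValidationError("sigma0 must be > 0 to invert")
    if g1 == 0 and red.B != 0:
        raise DegenerateInputError("g1 = 0 cannot produce a transient (B != 0)")
    kv_D0p = (2.0 * Em + Etf) / (Etf * (Etf + Em))
    kv_D1p_abs = Em / (Etf * (Etf + Em))
    g0 = red.A / (kv_D0p * sigma0)
    g2 = -red.B / (g1 * kv_D1p_abs * sigma0) if g1 > 0 else 0.0
    eta = red.tau * Etf * Em / (Etf + Em)
    return (
        SchaperyParameters(g0=g0, g1=g1, g2=g2),
        SLSParameters(Etf=Etf, Em=Em, eta=eta),
    )


def g1_from_strains(
    delta_eps_c: float, eps_p: float, eps_b0: float, eps_r0: float
) -> float:
    """Strain-recovery factor g1 from creep / rebound strain components.

    g1 = (d_eps_c - eps_p) / (d_eps_c - eps0 - eps_p), eps0 = eps_b0 - eps_r0.
    Full rebound (eps_b0 == eps_r0) gives g1 = 1.
    """
    eps0 = eps_b0 - eps_r0
    denom = delta_eps_c - eps0 - eps_p
    if denom == 0 or not math.isfinite(denom):
        raise DegenerateInputError("g1 undefined: zero or non-finite denominator")
    return (delta_eps_c - eps_p) / denom


def stress_from_load(F_mN: float, S_mm2: float) -> float:
    """Nominal step stress in kPa from force F (mN) over area S (mm^2).

    1 mN / mm^2 = 1 kPa.
    """
    if not (np.isfinite(S_mm2) and S_mm2 > 0):
        raise ValidationError(f"area must be finite and > 0, got {S_mm2!r}")
    if not (np.isfinite(F_mN) and F_mN >= 0):
        raise ValidationError(f"force must be finite and >= 0, got {F_mN!r}")
    return F_mN / S_mm2


def normalized_context(
    Etf: float = 1.0, Em: float = 1.0, sigma0: float = 1.0
) -> tuple[SLSParameters, StepLoad]:
    """Default fixed context Etf = Em = 1 MPa, sigma0 = 1.

    A single hold-stage curve identifies only (A, B, tau); the moduli and
    stress are never separately observable from one creep test, so the
    conventional normalization makes parameter round-trips well-posed.
    eta is left at 1 here; the fit replaces it.
    """
    return SLSParameters(Etf=Etf, Em=Em, eta=1.0), StepLoad(sigma0)
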