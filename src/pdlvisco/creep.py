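"""Creep-curve fitting: recover (g0, g2, eta) from hold-stage strain-time data.

The hold stage of a constant-load indentation test gives a strain history

    eps(t) = A + B * (1 - exp(-t/tau))

whose three observable parameters map one-to-one onto the fiber-content
factors (g0, g2) and the matrix viscosity eta once the non-identifiable
context (Etf, Em, sigma0, g1) is fixed — by convention Etf = Em = sigma0 = 1
and g1 = 1 (full strain rebound).  The optimizer works in (A, B, tau), which
is well-conditioned, and maps back.

`SchaperyCreepModel` / `SchaperyCreepResults` follow the statsmodels
Model/Results idiom; `fit_creep` and `fit_all` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constitutive import (
    ReducedCreepParameters,
    SLSParameters,
    SchaperyParameters,
    StepLoad,
    ValidationError,
    kelvin_voigt_from_sls,
    reduced_from_full,
)

__all__ = [
    "CreepCurve",
    "FitContext",
    "FitResult",
    "SchaperyCreepModel",
    "SchaperyCreepResults",
    "fit_creep",
    "fit_all",
]

REGIONS = ("neck", "middle", "apex")
PLANES = ("transverse", "longitudinal")


@dataclass(frozen=True)
class CreepCurve:
    """Hold-stage strain-time series with sample metadata.

    ``t`` is the hold-stage clock (t = 0 at hold onset), seconds; ``eps`` is
    dimensionless strain (indentation depth / PDL thickness).
    """

    t: np.ndarray
    eps: np.ndarray
    sample_id: str = ""
    region: str | None = None
    plane: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        eps = np.asarray(self.eps, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "eps", eps)
        if t.ndim != 1 or eps.ndim != 1 or len(t) != len(eps):
            raise ValidationError("t and eps must be 1-D arrays of equal length")
        if len(t) < 4:
            raise ValidationError("need at least 4 samples to fit 3 parameters")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("t must be non-negative and strictly increasing")
        if not np.all(np.isfinite(eps)):
            raise ValidationError("eps must be finite")
        if self.region is not None and self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.plane is not None and self.plane not in PLANES:
            raise ValidationError(f"plane must be one of {PLANES}, got {self.plane!r}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str = "") -> "CreepCurve":
        """Build from a frame with columns time_s, strain [, sample_id, region, plane]."""
        meta = {}
        for key in ("sample_id", "region", "plane"):
            if key in df.columns:
                vals = df[key].dropna().unique()
                if len(vals) > 1:
                    raise ValidationError(f"column {key!r} is not constant within a curve")
                if len(vals):
                    meta[key] = str(vals[0])
        meta.setdefault("sample_id", sample_id)
        return cls(t=df["time_s"].to_numpy(), eps=df["strain"].to_numpy(), **meta)


@dataclass(frozen=True)
class FitContext:
    """The non-identifiable constants held fixed during fitting."""

    Etf: float = 1.0
    Em: float = 1.0
    sigma0: float = 1.0
    g1: float = 1.0

    def __post_init__(self) -> None:
        if self.Etf <= 0 or self.Em <= 0 or self.sigma0 <= 0:
            raise ValidationError("Etf, Em, sigma0 must be > 0")
        if self.g1 <= 0:
            raise ValidationError("g1 must be > 0 to identify g2")


@dataclass(frozen=True)
class FitResult:
    """Per-curve creep fit: recovered parameters and goodness of fit."""

    g0: float
    g2: float
    eta: float
    r_squared: float | None
    residuals: np.ndarray
    converged: bool
    fixed_context: FitContext
    reduced: ReducedCreepParameters
    sample_id: str = ""
    region: str | None = None
    plane: str | None = None
    creep_regime: bool = True  # False flags a decreasing-strain (B < 0) fit


class SchaperyCreepModel:
    """Nonlinear least-squares model for hold-stage creep strain.

    Parameters
    ----------
    curve : CreepCurve
        Hold-stage strain-time data.
    context : FitContext, optional
        Fixed (Etf, Em, sigma0, g1); defaults to the unit normalization.

    Examples
    --------
    >>> model = SchaperyCreepModel(curve)
    >>> res = model.fit()
    >>> res.params  # (g0, g2, eta)
    """

    param_names = ("g0", "g2", "eta")

    def __init__(self, curve: CreepCurve, context: FitContext | None = None):
        self.curve = curve
        self.context = context or FitContext()
        kv_sls = SLSParameters(self.context.Etf, self.context.Em, 1.0)
        kv = kelvin_voigt_from_sls(kv_sls)
        self._D0p = kv.D0p
        self._absD1p = abs(kv.D1p)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, context: FitContext | None = None, sample_id: str = ""
    ) -> "SchaperyCreepModel":
        return cls(CreepCurve.from_dataframe(df, sample_id=sample_id), context)

    # -- model function in the reduced parameterization ---------------------
    def predict_reduced(self, theta: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
        A, B, tau = theta
        t = self.curve.t if t is None else t
        return A + B * (1.0 - np.exp(-t / tau))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.predict_reduced(theta) - self.curve.eps

    def fit(
        self,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
        gtol: float = 1e-12,
        max_nfev: int = 1000,
    ) -> "SchaperyCreepResults":
        """Fit by bounded trust-region least squares in (A, B, tau).

        Initial guess: A = eps[0], B = eps[-1] - eps[0], tau = span/3.
        tau is bounded to (0, 100x span]; A and B are free so decreasing
        curves fit (they are flagged, not rejected).
        """
        t, eps = self.curve.t, self.curve.eps
        span = t[-1] - t[0]
        A0 = float(eps[0])
        B0 = float(eps[-1] - eps[0])
        tau0 = max(span / 3.0, 1e-6)
        lb = [-np.inf, -np.inf, 1e-9 * max(span, 1.0)]
        ub = [np.inf, np.inf, 100.0 * max(span, 1.0)]
        x0 = np.clip([A0, B0 if B0 != 0 else 1e-12, tau0], lb, ub)
        sol = least_squares(
            self._residuals,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=xtol,
            ftol=ftol,
            gtol=gtol,
            max_nfev=max_nfev,
        )
        A, B, tau = sol.x
        ctx = self.context
        g0 = A / (self._D0p * ctx.sigma0)
        g2 = -B / (ctx.g1 * self._absD1p * ctx.sigma0)
        eta = tau * ctx.Etf * ctx.Em / (ctx.Etf + ctx.Em)
        resid = sol.fun
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((eps - eps.mean()) ** 2))
        # a flat curve has no variance to explain: R^2 is undefined
        r2 = None if np.ptp(eps) == 0 else 1.0 - ss_res / ss_tot

        # asymptotic parameter covariance from the trust-region jacobian
        bse = self._bse(sol, len(t))
        return SchaperyCreepResults(
            model=self,
            params=np.array([g0, g2, eta]),
            reduced=ReducedCreepParameters(A=float(A), B=float(B), tau=float(tau)),
            bse=bse,
            r_squared=r2,
            residuals=resid,
            converged=bool(sol.success),
            nfev=sol.nfev,
        )

    def _bse(self, sol, n: int) -> np.ndarray:
        """Standard errors of (g0, g2, eta) via the linear reduced->full map."""
        dof = max(n - 3, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        try:
            JtJ = sol.jac.T @ sol.jac
            cov_red = s2 * np.linalg.inv(JtJ)
            se_red = np.sqrt(np.clip(np.diag(cov_red), 0, None))
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)
        ctx = self.context
        scale = np.array(
            [
                1.0 / (self._D0p * ctx.sigma0),
                1.0 / (ctx.g1 * self._absD1p * ctx.sigma0),
                ctx.Etf * ctx.Em / (ctx.Etf + ctx.Em),
            ]
        )
        return se_red * scale


@dataclass
class SchaperyCreepResults:
    """Fit output: estimates, uncertainties, diagnostics.

    ``params`` is (g0, g2, eta); ``reduced`` the identifiable (A, B, tau);
    ``bse`` asymptotic standard errors; ``r_squared`` is None for a
    zero-variance (flat) curve where it is undefined.
    """

    model: SchaperyCreepModel
    params: np.ndarray
    reduced: ReducedCreepParameters
    bse: np.ndarray
    r_squared: float | None
    residuals: np.ndarray
    converged: bool
    nfev: int = 0

    @property
    def g0(self) -> float:
        return float(self.params[0])

    @property
    def g2(self) -> float:
        return float(self.params[1])

    @property
    def eta(self) -> float:
        return float(self.params[2])

    @property
    def creep_regime(self) -> bool:
        """True when the fitted transient amplitude is non-negative (strain creeps up)."""
        return self.reduced.B >= 0

    def predict(self, t: np.ndarray | None = None) -> np.ndarray:
        theta = np.array([self.reduced.A, self.reduced.B, self.reduced.tau])
        return self.model.predict_reduced(theta, t)

    def as_fit_result(self) -> FitResult:
        c = self.model.curve
        return FitResult(
            g0=self.g0,
            g2=self.g2,
            eta=self.eta,
            r_squared=self.r_squared,
            residuals=self.residuals,
            converged=self.converged,
            fixed_context=self.model.context,
            reduced=self.reduced,
            sample_id=c.sample_id,
            region=c.region,
            plane=c.plane,
            creep_regime=self.creep_regime,
        )

    def summary(self) -> str:
        c = self.model.curve
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.6f}"
        lines = [
            "Schapery creep fit",
            "=" * 46,
            f"sample: {c.sample_id or '<unnamed>'}  region: {c.region}  plane: {c.plane}",
            f"n = {len(c.t)}  hold span = {c.t[-1] - c.t[0]:.1f} s",
            f"converged: {self.converged}   nfev: {self.nfev}   R^2: {r2}",
            f"creep regime (B >= 0): {self.creep_regime}",
            "-" * 46,
            f"{'param':>6} {'estimate':>14} {'std err':>12}",
        ]
        for name, val, se in zip(self.model.param_names, self.params, self.bse):
            lines.append(f"{name:>6} {val:>14.6g} {se:>12.3g}")
        red = self.reduced
        lines += [
            "-" * 46,
            f"reduced: A = {red.A:.6g}, B = {red.B:.6g}, tau = {red.tau:.6g} s",
        ]
        return "\n".join(lines)


def fit_creep(curve: CreepCurve, context: FitContext | None = None) -> FitResult:
    """Fit one hold-stage curve; see :class:`SchaperyCreepModel`."""
    return SchaperyCreepModel(curve, context).fit().as_fit_result()


def fit_all(
    curves: Sequence[CreepCurve], context: FitContext | None = None
) -> pd.DataFrame:
    """Fit each curve and tabulate, one row per curve, input order preserved."""
    if len(curves) == 0:
        raise ValidationError("fit_all requires at least one curve")
    rows = []
    for curve in curves:
        r = fit_creep(curve, context)
        rows.append(
            {
                "sample_id": r.sample_id,
                "region": r.region,
                "plane": r.plane,
                "g0": r.g0,
                "g2": r.g2,
                "eta": r.eta,
                "r_squared": np.nan if r.r_squared is None else r.r_squared,
                "converged": r.converged,
                "creep_regime": r.creep_regime,
            }
        )
    return pd.DataFrame(rows)


def generate_curve(
    sch: SchaperyParameters,
    sls: SLSParameters,
    load: StepLoad,
    t: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **meta,
) -> CreepCurve:
    """Synthesize a hold-stage curve from the strain law (plus optional noise).

    ``noise_sd`` is the i.i.d. Gaussian noise standard deviation in strain
    units.  Noiseless output is deterministic.
    """
    red = reduced_from_full(sch, sls, load)
    eps = np.asarray(red.strain(t), dtype=float)
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noisy generation requires an explicit rng")
        eps = eps + rng.normal(0.0, noise_sd, size=eps.shape)
    return CreepCurve(t=t, eps=eps, **meta)
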