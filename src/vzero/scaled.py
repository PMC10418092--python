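"""Surfaces of balanced evolution in the space of scaled effects γ = Tc·s.

Three surfaces partition the scaled parameter space (γb, γd, η):

* ``v0`` — the rate of mean-fitness change vanishes: ∫ρ̃(γ) γe^γ dγ = 0.
  Beneficial and deleterious fixations exactly offset; above it the
  population adapts, below it Muller's ratchet wins and fitness declines.
* ``FU`` — the total selected fixation rate equals the mutation rate
  (dN/dS = 1): ∫ρ̃(γ)(e^γ−1) dγ = 0.
* ``alpha0`` — the McDonald–Kreitman-like statistic α vanishes:
  ∫ρ̃(γ)(γe^γ+1−e^γ)/γ dγ = 0.

For any scaled DFE the surfaces are strictly ordered,
η|v=0 < η|α=0 < η|F=U, and all three merge onto the neutral-accumulation
surface η = γd/γb as γb, γd → 0.

The v=0 surface has a "ridgeline" at γd* = 1 where the beneficial fraction η
required for balance is maximal — deleterious mutations of intermediate
scaled effect are maximally impactful.  For a two-effect DFE the ridgeline
beneficial coordinate is γb* = W(1/(e·η)) (Lambert W); above γb* the
population adapts for *every* γd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .dfe import (
    DivergentIntegralError,
    ScaledDFE,
    dfe_integral,
    with_eta,
)

__all__ = [
    "SurfacePoint",
    "SURFACE_KERNELS",
    "surface_residual",
    "eta_on_surface",
    "solve_eta",
    "ridgeline",
    "ridgeline_numeric",
    "adaptation_threshold",
    "exponential_divergence_threshold",
    "surface_ordering_check",
]

SURFACE_KERNELS = {"v0": "v", "FU": "F", "alpha0": "alpha"}

# bisection bracket for η root-solves (log10 η)
_ETA_BRACKET = (1e-12, 1e3)


@dataclass(frozen=True)
class SurfacePoint:
    """A point (γb, γd, η) labelled with the surface it lies on."""

    gamma_b: float
    gamma_d: float
    eta: float
    surface: str
    residual: float


def surface_residual(sdfe: ScaledDFE, surface: str, method: str = "auto") -> float:
    """Defining integral of a surface evaluated at a scaled DFE.

    The ``v0`` residual has the sign of Tc²·v, and the ``FU`` residual the
    sign of F − U, so the residual's sign says which side of the surface the
    DFE lies on.  ``method="quad"`` forces the adaptive-quadrature path.
    """
    return dfe_integral(sdfe, SURFACE_KERNELS[surface], method=method)


def _component_integrals(gamma_b, gamma_d, family, surface, shape_b=None, shape_d=None):
    """Per-side integrals (benefit Ib > 0, cost Id < 0) of the surface kernel."""
    one_sided = dict(family=family, shape_b=shape_b, shape_d=shape_d)
    kern = SURFACE_KERNELS[surface]
    big = ScaledDFE(gamma_b=gamma_b, gamma_d=gamma_d, eta=math.inf, **one_sided)
    small = ScaledDFE(gamma_b=gamma_b, gamma_d=gamma_d, eta=0.0, **one_sided)
    return dfe_integral(big, kern), dfe_integral(small, kern)


def eta_on_surface(
    gamma_b: float,
    gamma_d: float,
    family: str = "two_effect",
    surface: str = "v0",
) -> float:
    """The beneficial fraction η = Ub/Ud placing (γb, γd) on a surface.

    Closed forms for the delta and exponential families:

    * two-effect, v=0:  η = γd e^{−γd} / (γb e^{γb})
    * two-effect, F=U:  η = (1 − e^{−γd}) / (e^{γb} − 1)
    * exponential, v=0: η = (γd/γb)·((1−γb)/(1+γd))², requiring γb < 1

    The α=0 surface and other families use the per-side kernel integrals
    directly (η = −Id/Ib), which is exact for any mixture since the residual
    is linear in the component weights.
    """
    if gamma_b <= 0 or gamma_d <= 0:
        raise ValueError("scaled effects must be positive")
    if family == "two_effect" and surface == "v0":
        return gamma_d * math.exp(-gamma_d) / (gamma_b * math.exp(gamma_b))
    if family == "two_effect" and surface == "FU":
        return -math.expm1(-gamma_d) / math.expm1(gamma_b)
    if family == "exponential_pair" and surface == "v0":
        if gamma_b >= 1:
            raise DivergentIntegralError(
                f"exponential beneficial mean {gamma_b} >= 1: the adaptation "
                "integral diverges"
            )
        return (gamma_d / gamma_b) * ((1.0 - gamma_b) / (1.0 + gamma_d)) ** 2
    ib, id_ = _component_integrals(gamma_b, gamma_d, family, surface)
    if ib <= 0:
        raise ValueError(
            f"no positive η puts ({gamma_b}, {gamma_d}) on {surface}: "
            "the beneficial-side integral is non-positive"
        )
    return -id_ / ib


def solve_eta(
    gamma_b: float,
    gamma_d: float,
    family: str = "two_effect",
    surface: str = "v0",
    shape_b: float | None = None,
    shape_d: float | None = None,
    method: str = "auto",
) -> float:
    """Root-solve the surface residual in η by bisection on log η.

    Independent of the closed forms in :func:`eta_on_surface`; the residual
    is monotone in η (mixture linearity), so a bracketed bisection is safe.
    """

    def res(log_eta):
        sdfe = ScaledDFE(
            family=family,
            gamma_b=gamma_b,
            gamma_d=gamma_d,
            eta=math.exp(log_eta),
            shape_b=shape_b,
            shape_d=shape_d,
        )
        return surface_residual(sdfe, surface, method=method)

    lo, hi = (math.log(b) for b in _ETA_BRACKET)
    flo, fhi = res(lo), res(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no η in {_ETA_BRACKET} puts ({gamma_b}, {gamma_d}) on {surface}"
        )
    sol = optimize.brentq(res, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return math.exp(sol)


def adaptation_threshold(eta: float) -> float:
    """γb* = W(1/(e·η)): for a two-effect DFE with γb above this threshold,
    the population adapts (v > 0) for every deleterious effect γd."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    return float(special.lambertw(1.0 / (math.e * eta)).real)


def ridgeline(family: str, eta: float) -> tuple[float, float]:
    """The v=0 ridgeline point (γd*, γb*) at a given η.

    For both supported families the deleterious coordinate is γd* = 1.  The
    beneficial coordinate is W(1/(e·η)) for the two-effect family; for the
    exponential family it is found by a 1-D root-solve of
    ``eta_on_surface(γb, 1) = η`` (the closed solution is
    1 + 2η − 2√(η² + η), used as the initial bracket check).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if family == "two_effect":
        return 1.0, adaptation_threshold(eta)
    if family == "exponential_pair":
        sol = optimize.brentq(
            lambda gb: eta_on_surface(gb, 1.0, "exponential_pair", "v0") - eta,
            1e-14,
            1.0 - 1e-14,
            xtol=1e-15,
            rtol=8.9e-16,
        )
        return 1.0, float(sol)
    raise ValueError(f"no ridgeline closed form for family {family!r}")


def ridgeline_numeric(
    family: str,
    gamma_b: float,
    surface: str = "v0",
    bracket: tuple[float, float] = (0.01, 10.0),
    tol: float = 1e-10,
    method: str = "auto",
    n_scan: int = 41,
) -> tuple[float, float]:
    """Maximize η along a surface over γd at fixed γb, fully numerically.

    η(γd) is obtained by :func:`solve_eta` (bisection on the quadrature/
    closed residual, no surface closed form), then maximized by a coarse
    log-grid scan followed by golden-section refinement.  Returns
    ``(γd*, η*)``.  This is the independent check that the ridgeline sits at
    γd* = 1 for the delta and exponential families.
    """

    def eta_of(log_gd):
        return solve_eta(gamma_b, math.exp(log_gd), family, surface, method=method)

    lo, hi = (math.log(b) for b in bracket)
    grid = np.linspace(lo, hi, n_scan)
    vals = [eta_of(g) for g in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -eta_of(g),
        bracket=None,
        bounds=(a, b),
        method="bounded",
        options={"xatol": tol * 1e-2},
    )
    gd_star = math.exp(res.x)
    return gd_star, eta_of(res.x)


def exponential_divergence_threshold(
    window: tuple[float, float] = (0.5, 1.5), tol: float = 1e-6
) -> float:
    """Localize the mean scaled beneficial effect at which the adaptation
    integral ∫ρ̃b(γ) γe^γ dγ for an exponential beneficial DFE stops
    converging.

    Classifies candidate means by the sign of the integrand's tail exponent
    γ(1 − 1/m) (divergent iff ≥ 0, i.e. the density no longer outruns the
    kernel) and bisects the convergent/divergent boundary.  The boundary is
    exactly at mean 1.
    """

    def divergent(m):
        return 1.0 - 1.0 / m >= 0.0

    lo, hi = window
    if divergent(lo) or not divergent(hi):
        raise ValueError("window must bracket the convergence boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if divergent(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def surface_ordering_check(
    gamma_b: float,
    gamma_d: float,
    family: str = "two_effect",
    shape_b: float | None = None,
    shape_d: float | None = None,
) -> tuple[float, float, float]:
    """Return (η|v=0, η|α=0, η|F=U) at fixed (γb, γd); strictly increasing."""
    return tuple(
        solve_eta(gamma_b, gamma_d, family, s, shape_b, shape_d)
        for s in ("v0", "alpha0", "FU")
    )


def surface_point(
    gamma_b: float, gamma_d: float, family: str, surface: str
) -> SurfacePoint:
    """On-surface point with its residual re-checked through the integral."""
    eta = eta_on_surface(gamma_b, gamma_d, family, surface)
    sdfe = ScaledDFE(family=family, gamma_b=gamma_b, gamma_d=gamma_d, eta=eta)
    return SurfacePoint(
        gamma_b, gamma_d, eta, surface, surface_residual(sdfe, surface)
    )
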