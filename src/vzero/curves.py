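"""Theory curves in the space of unscaled effects (Nsd, Nsb).

At fixed η = Ub/Ud and compound mutation supply NU, each curve gives, for a
grid of scaled deleterious strengths Nsd, the beneficial strength Nsb at
which the population is exactly balanced (v = 0, F = U, or α = 0).  The
coalescence timescale Tc is resolved per point:

* the ``mssm`` branch solves the implicit traveling-wave relation for Tc and
  root-solves the balance condition in Nsb — valid up to the curve's nose
  (Nsd*, Nsb*), the maximal deleterious strength at which balance is
  possible under the MSSM;
* past the nose, the ``ne`` branch uses the background-selection coalescence
  estimate; for v=0 the patched prediction is
  Nsb = min[(Nsb)*, (Nsb)_NE] with the NE value from the single-locus
  diffusion fixation probability, and for α=0 the scaled α condition is
  evaluated at the heuristic Tc.  The F=U curve keeps the MSSM Tc on the
  whole grid (at large γd its scaled beneficial coordinate tends to
  log(1+1/η), so strong purifying selection never dominates its dynamics).

Per-point solver failures are recorded as NaN rows, never interpolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dfe import DFESpec, DivergentIntegralError, scale_dfe
from .mssm import (
    NoRootError,
    solve_Tc,
    tc_ne_heuristic,
    v_rate,
    v_rate_diffusion,
    fixation_rate,
)
from .scaled import SURFACE_KERNELS, ridgeline, surface_residual

__all__ = ["CurvePoint", "SurfaceCurve", "v0_curve", "fu_curve", "alpha0_curve",
           "star_vs_ridge_coincidence"]

logger = logging.getLogger("vzero")

DEFAULT_N = 1e6  # census size used to resolve U = NU/N unless overridden


@dataclass(frozen=True)
class CurvePoint:
    Nsd: float
    Nsb: float
    branch: str  # "mssm" | "ne"
    Tc: float
    residual: float


@dataclass
class SurfaceCurve:
    """A balance curve at fixed (η, NU) with its extremal landmarks.

    ``star`` is the curve's own extremal point (Nsd*, Nsb*) under the MSSM
    branch; ``ridge_scaled`` is the scaled-space ridgeline (γd*, γb*) for
    the same η, a nearby landmark when Tc varies slowly along the curve.
    """

    surface: str
    family: str
    eta: float
    NU: float
    N: float
    points: list[CurvePoint] = field(default_factory=list)
    star: tuple[float, float] | None = None   # Nsd-maximal nose (patch point)
    peak: tuple[float, float] | None = None   # Nsb-maximal point (extremal)
    ridge_scaled: tuple[float, float] | None = None

    @property
    def U(self) -> float:
        return self.NU / self.N

    def as_arrays(self):
        nsd = np.array([p.Nsd for p in self.points])
        nsb = np.array([p.Nsb for p in self.points])
        return nsd, nsb


def _surface_v(surface, N, U, dfe, Tc):
    """Signed balance measure for a surface at a given Tc (0 on-surface)."""
    if surface == "v0":
        return v_rate(N, U, dfe, Tc)
    if surface == "FU":
        return fixation_rate(N, U, dfe, Tc) - U
    # alpha0: the scaled residual (sign of alpha)
    return surface_residual(scale_dfe(dfe, Tc), "alpha0")


def _mssm_branch_root(surface, N, U, eta, family, Nsd, nsb_window=(1e-2, 3e3)):
    """Root-solve the balance condition in Nsb with Tc from the MSSM relation.

    Returns (Nsb, Tc, residual) or None when the condition has no zero in
    the window (the point is past the curve's nose).
    """
    sd = Nsd / N

    def measure(log_nsb):
        sb = math.exp(log_nsb) / N
        dfe = DFESpec(family=family, sb=sb, sd=sd, eta=eta)
        sol = solve_Tc(N, U, dfe)
        return _surface_v(surface, N, U, dfe, sol.Tc), sol.Tc

    lo, hi = (math.log(w) for w in nsb_window)
    grid = np.linspace(lo, hi, 25)
    vals = []
    for g in grid:
        try:
            vals.append(measure(g)[0])
        except (NoRootError, DivergentIntegralError, ValueError):
            vals.append(math.nan)
    vals = np.array(vals)
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if math.isfinite(a) and math.isfinite(b) and (a > 0) != (b > 0):
            root = optimize.brentq(
                lambda g: measure(g)[0], grid[i], grid[i + 1],
                xtol=1e-12, rtol=8.9e-16,
            )
            resid, tc = measure(root)
            # the inner Tc solve can jump between branches of the implicit
            # relation, making the measure discontinuous; a genuine zero has
            # a residual far below the bracketing values, a jump does not
            if abs(resid) > 1e-6 * max(abs(a), abs(b)):
                continue
            return math.exp(root), tc, resid
    return None


def _ne_branch_root(surface, N, U, eta, family, Nsd, nsb_window=(1e-12, 3e3)):
    """Balance root in Nsb with Tc from the Ne-based heuristic.

    The heuristic Tc depends only on the deleterious side, so it is constant
    in Nsb.  v=0 uses the diffusion fixation probability; α=0 evaluates the
    scaled α condition at the heuristic Tc.
    """
    sd = Nsd / N
    Ud = U / (1.0 + eta)
    dfe_d = DFESpec(family=family, sb=sd, sd=sd, eta=eta)
    tc = tc_ne_heuristic(N, Ud, dfe_d)

    def measure(log_nsb):
        sb = math.exp(log_nsb) / N
        dfe = DFESpec(family=family, sb=sb, sd=sd, eta=eta)
        if surface == "v0":
            return v_rate_diffusion(N, U, dfe, tc)
        return _surface_v(surface, N, U, dfe, tc)

    lo, hi = (math.log(w) for w in nsb_window)
    if family in ("exponential_pair", "gamma_pair"):
        hi = min(hi, math.log(N * (1.0 - 1e-9) / tc))  # keep Tc·sb < 1
        if hi <= lo:
            return None
    grid = np.linspace(lo, hi, 40)
    vals = []
    for g in grid:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                vals.append(measure(g))
        except (DivergentIntegralError, ValueError):
            vals.append(math.nan)
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if math.isfinite(a) and math.isfinite(b) and (a > 0) != (b > 0):
            root = optimize.brentq(
                measure, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16
            )
            return math.exp(root), tc, measure(root)
    return None


def _build_curve(surface, eta, NU, N, family, Nsd_grid, patch_ne):
    N = float(N)
    U = NU / N
    curve = SurfaceCurve(surface, family, eta, NU, N)
    mssm_pts = {}
    for Nsd in Nsd_grid:
        try:
            res = _mssm_branch_root(surface, N, U, eta, family, Nsd)
        except (NoRootError, DivergentIntegralError, ValueError) as err:
            logger.debug("%s curve: MSSM solve failed at Nsd=%g: %s", surface, Nsd, err)
            res = None
        if res is not None:
            mssm_pts[Nsd] = res
    # the inner relation's root families can swap at the near-neutral edge;
    # a discontinuous upward Tc jump along increasing Nsd marks the swap, and
    # everything beyond it belongs to the invalid branch
    if surface != "FU" and len(mssm_pts) > 1:
        ordered = sorted(mssm_pts)
        for prev, cur in zip(ordered, ordered[1:]):
            if mssm_pts[cur][1] > 2.0 * mssm_pts[prev][1]:
                for drop in [d for d in ordered if d >= cur]:
                    del mssm_pts[drop]
                break
    if mssm_pts:
        nsd_star = max(mssm_pts)
        nsb_star = mssm_pts[nsd_star][0]
        # refine the nose between the last grid success and the first failure
        fails = [g for g in Nsd_grid if g > nsd_star]
        if fails and surface != "FU":
            lo_d, hi_d = nsd_star, min(fails)
            for _ in range(6):
                mid = math.sqrt(lo_d * hi_d)
                try:
                    res = _mssm_branch_root(surface, N, U, eta, family, mid)
                except (NoRootError, DivergentIntegralError, ValueError):
                    res = None
                if res is None:
                    hi_d = mid
                else:
                    lo_d, (nsd_star, nsb_star) = mid, (mid, res[0])
        curve.star = (nsd_star, nsb_star)
        # Nsb-maximal (extremal) point, parabolic-refined on the log grid
        ordered = sorted(mssm_pts)
        j = int(np.argmax([mssm_pts[d][0] for d in ordered]))
        if 0 < j < len(ordered) - 1:
            x = np.log([ordered[j - 1], ordered[j], ordered[j + 1]])
            y = np.log([mssm_pts[d][0] for d in (ordered[j - 1], ordered[j], ordered[j + 1])])
            denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
            a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
            bq = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
            if a < 0:
                xv = -bq / (2 * a)
                yv = a * xv**2 + bq * xv + (
                    y[0] - a * x[0] ** 2 - bq * x[0]
                )
                curve.peak = (math.exp(xv), math.exp(yv))
        if curve.peak is None:
            curve.peak = (ordered[j], mssm_pts[ordered[j]][0])
    try:
        curve.ridge_scaled = ridgeline(family, eta)  # (γd*, γb*)
    except ValueError:
        curve.ridge_scaled = None

    for Nsd in Nsd_grid:
        if Nsd in mssm_pts:
            nsb, tc, resid = mssm_pts[Nsd]
            curve.points.append(CurvePoint(Nsd, nsb, "mssm", tc, resid))
            continue
        if not patch_ne:
            curve.points.append(CurvePoint(Nsd, math.nan, "gap", math.nan, math.nan))
            continue
        try:
            res = _ne_branch_root(surface, N, U, eta, family, Nsd)
        except (NoRootError, DivergentIntegralError, ValueError) as err:
            logger.debug("%s curve: NE solve failed at Nsd=%g: %s", surface, Nsd, err)
            res = None
        if res is None:
            curve.points.append(CurvePoint(Nsd, math.nan, "gap", math.nan, math.nan))
            continue
        nsb_ne, tc, resid = res
        if surface == "v0" and curve.star is not None and Nsd > curve.star[0]:
            nsb = min(curve.star[1], nsb_ne)  # the patched prediction
        else:
            nsb = nsb_ne
        curve.points.append(CurvePoint(Nsd, nsb, "ne", tc, resid))
    return curve


def v0_curve(eta, NU, N=DEFAULT_N, family="two_effect", Nsd_grid=()):
    """The v=0 curve: MSSM branch to the nose, then min[(Nsb)*, (Nsb)_NE]."""
    return _build_curve("v0", eta, NU, N, family, Nsd_grid, patch_ne=True)


def fu_curve(eta, NU, N=DEFAULT_N, family="two_effect", Nsd_grid=()):
    """The F=U (dN/dS = 1) curve; the MSSM Tc is used on the whole grid."""
    return _build_curve("FU", eta, NU, N, family, Nsd_grid, patch_ne=False)


def alpha0_curve(eta, NU, N=DEFAULT_N, family="two_effect", Nsd_grid=()):
    """The α=0 curve: MSSM branch at small Nsd, Ne branch past the MSSM
    branch's own turning point (the crossover mirrors the v=0 patch)."""
    return _build_curve("alpha0", eta, NU, N, family, Nsd_grid, patch_ne=True)


def star_vs_ridge_coincidence(curve: SurfaceCurve, flag_above: float = 0.20) -> dict:
    """Compare the curve's extremal point with the mapped scaled ridgeline.

    The scaled ridgeline (γd*, γb*) maps to unscaled coordinates through the
    on-curve Tc nearest the curve's extremal (Nsb-maximal) point; the two
    landmarks coincide exactly when Tc is constant along the curve, and
    nearly so in practice.  Returns the relative offsets and the spread of
    Tc along the curve.
    """
    if curve.peak is None or curve.ridge_scaled is None:
        raise ValueError("curve lacks extremal and/or ridgeline landmarks")
    nsd_star, nsb_star = curve.peak
    gd_star, gb_star = curve.ridge_scaled
    mssm = [p for p in curve.points if p.branch == "mssm" and math.isfinite(p.Tc)]
    if not mssm:
        raise ValueError("curve has no MSSM-branch points")
    near = min(mssm, key=lambda p: abs(p.Nsd - nsd_star))
    mapped_nsd = curve.N * gd_star / near.Tc
    mapped_nsb = curve.N * gb_star / near.Tc
    off_d = abs(mapped_nsd - nsd_star) / nsd_star
    off_b = abs(mapped_nsb - nsb_star) / nsb_star
    tcs = np.array([p.Tc for p in mssm])
    return {
        "extremal": curve.peak,
        "ridge_mapped": (mapped_nsd, mapped_nsb),
        "rel_offset_Nsd": off_d,
        "rel_offset_Nsb": off_b,
        "flagged": bool(off_d > flag_above or off_b > flag_above),
        "Tc_spread": float(tcs.max() / tcs.min()),
    }
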