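"""Fitness-mediated (macroscopic) epistasis: simulation and theory flows.

Under global fitness-mediated epistasis the DFE available to an individual
depends on its own log-fitness X.  The canonical joint pattern combines
diminishing-returns epistasis on beneficial effects with increasing costs
on deleterious ones,

    sb(X) = sb0 · e^{−X/λ},    sd(X) = sd0 · e^{+X/λ},

so the product sb·sd is exactly conserved along any fitness trajectory
(λ = 5 log-fitness units by default).  The simulation side applies the
rescaling per individual at each mutation event; the theory side integrates
the slow-epistasis flow dX/dt = v(N, U, ρ(·|X)), re-solving the coalescence
timescale as the DFE shifts, and classifies the fixed points where a
constraint line (horizontal for diminishing returns, vertical for
increasing/decreasing costs) crosses the v=0 curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dfe import DFESpec
from .mssm import NoRootError, solve_Tc
from .wf import EpochRun, Population
from .curves import SurfaceCurve

__all__ = [
    "EpistasisRule",
    "Trajectory",
    "effect_update",
    "simulate_epistatic",
    "theory_flow",
    "classify_fixed_points",
]

PATTERNS = (
    "diminishing_returns",
    "increasing_costs",
    "decreasing_costs",
    "dr_plus_ic",
    "custom",
)


@dataclass(frozen=True)
class EpistasisRule:
    """How the available effect scales depend on an individual's log-fitness.

    ``length_scale`` λ is the fitness scale of the exponential dependence;
    X is measured relative to the founding genotype (X = 0 at
    initialization).  ``dr_plus_ic`` holds sb·sd exactly constant.
    ``custom`` supplies arbitrary scale functions of X.
    """

    pattern: str
    sb0: float
    sd0: float
    length_scale: float = 5.0
    sb_of_X: callable = None
    sd_of_X: callable = None

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown epistasis pattern {self.pattern!r}")
        if self.sb0 <= 0 or self.sd0 <= 0:
            raise ValueError("initial effect scales must be positive")

    def scales(self, X):
        """(sb(X), sd(X)) for scalar or array X."""
        X = np.asarray(X, dtype=float)
        lam = self.length_scale
        if self.pattern == "custom":
            return self.sb_of_X(X), self.sd_of_X(X)
        if self.pattern == "diminishing_returns":
            return self.sb0 * np.exp(-X / lam), self.sd0 * np.ones_like(X)
        if self.pattern == "increasing_costs":
            return self.sb0 * np.ones_like(X), self.sd0 * np.exp(X / lam)
        if self.pattern == "decreasing_costs":
            return self.sb0 * np.ones_like(X), self.sd0 * np.exp(-X / lam)
        # dr_plus_ic
        fac = np.exp(-X / lam)
        return self.sb0 * fac, self.sd0 / fac

    def apply(self, effects, X):
        """Rescale drawn signed effects by the carrier's own fitness.

        Effects drawn from the base DFE (scales sb0, sd0) are multiplied by
        sb(X)/sb0 (beneficial) or sd(X)/sd0 (deleterious), which for the
        two-effect family reproduces the rule exactly and generalizes it to
        distributed effects.
        """
        sb, sd = self.scales(X)
        pos = effects > 0
        out = np.where(pos, effects * sb / self.sb0, effects * sd / self.sd0)
        return out


def effect_update(rule: EpistasisRule, X: float) -> tuple[float, float]:
    """Next available (sb, sd) for an individual at log-fitness X."""
    sb, sd = rule.scales(X)
    return float(sb), float(sd)


@dataclass
class Trajectory:
    """Time series of an epistatic run, sampled every ``record_every``
    generations, with a coarse qualitative classification."""

    generations: np.ndarray
    mean_fitness: np.ndarray
    fixed_selected: np.ndarray
    Nsb: np.ndarray  # N·sb(X̄) along the trajectory
    Nsd: np.ndarray
    classification: str = "unclassified"

    def classify(self, plateau_fraction: float = 0.10) -> str:
        """approaches_v0 | adapts_indefinitely | declines.

        The late rate of fitness change is compared with the early rate;
        a late rate below ``plateau_fraction`` of the early rate counts as
        a plateau (the v=0 attractor).
        """
        t, x = self.generations, self.mean_fitness
        third = max(len(t) // 3, 2)
        early = np.polyfit(t[:third], x[:third], 1)[0]
        late = np.polyfit(t[-third:], x[-third:], 1)[0]
        if early < 0 and late <= 0:
            cls = "declines"
        elif abs(late) < plateau_fraction * abs(early):
            cls = "approaches_v0"
        else:
            cls = "adapts_indefinitely"
        self.classification = cls
        return cls


def simulate_epistatic(
    pop: Population,
    rule: EpistasisRule,
    generations: int = 5000,
    record_every: int = 100,
) -> Trajectory:
    """Run the Wright–Fisher dynamics with per-individual effect rescaling.

    Identical to the fixed-DFE simulator except that after each mutation
    event the drawn effect is rescaled by the carrier's current log-fitness
    through ``rule``; with ``length_scale = inf`` the run is bitwise
    identical to the plain simulator under the same seed.
    """
    pop.epistasis = rule
    gens, fit, fixed, nsb, nsd = [], [], [], [], []
    for g in range(1, generations + 1):
        pop.generation_step()
        if g % record_every == 0:
            gens.append(pop.generation)
            fit.append(pop.mean_fitness())
            fixed.append(pop.fixed_selected)
            sb, sd = rule.scales(pop.mean_fitness())
            nsb.append(pop.N * float(sb))
            nsd.append(pop.N * float(sd))
    traj = Trajectory(
        np.array(gens, dtype=float),
        np.array(fit),
        np.array(fixed, dtype=float),
        np.array(nsb),
        np.array(nsd),
    )
    traj.classify()
    return traj


# ---------------------------------------------------------------------------
# Slow-epistasis theory flow
# ---------------------------------------------------------------------------


@dataclass
class FlowPath:
    X: np.ndarray
    t: np.ndarray
    v: np.ndarray
    Nsb: np.ndarray
    Nsd: np.ndarray
    terminated: str  # "fixed_point" | "horizon" | "solver_failure"


def theory_flow(
    N: float,
    U: float,
    eta: float,
    rule: EpistasisRule,
    X0: float = 0.0,
    horizon: float = 1e7,
    v_tol: float = 1e-12,
    max_steps: int = 2000,
    family: str = "two_effect",
) -> FlowPath:
    """Integrate the slow-epistasis flow dX/dt = v(N, U, ρ(·|X)).

    Explicit adaptive Euler: the step is limited so the per-step change in
    the effect scales stays below 1% (|ΔX| ≤ 0.01·λ), keeping the
    slow-epistasis assumption honest.  Terminates at the horizon, at a
    fixed point (|v| < v_tol), or on solver failure (last good state kept).
    """
    lam = rule.length_scale
    X, t = float(X0), 0.0
    Xs, ts, vs, nsbs, nsds = [], [], [], [], []
    status = "horizon"
    dX_max = 0.01 * lam  # slow-epistasis step bound; halved on overshoot
    prev_v = 0.0
    for _ in range(max_steps):
        sb, sd = effect_update(rule, X)
        dfe = DFESpec(family=family, sb=sb, sd=sd, eta=eta)
        try:
            sol = solve_Tc(N, U, dfe)
        except (NoRootError, ValueError):
            status = "solver_failure"
            break
        v = sol.v
        Xs.append(X); ts.append(t); vs.append(v)
        nsbs.append(N * sb); nsds.append(N * sd)
        if abs(v) < v_tol or dX_max < 1e-12 * lam:
            status = "fixed_point"
            break
        if v * prev_v < 0:  # crossed the balance surface: refine the step
            dX_max *= 0.5
        prev_v = v
        dt = min(dX_max / abs(v), horizon - t)
        X += v * dt
        t += dt
        if t >= horizon:
            status = "horizon"
            break
    return FlowPath(
        np.array(Xs), np.array(ts), np.array(vs),
        np.array(nsbs), np.array(nsds), status,
    )


# ---------------------------------------------------------------------------
# Fixed-point classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedPoint:
    Nsb: float
    Nsd: float
    stability: str  # "stable" | "unstable"


def classify_fixed_points(
    pattern: str,
    line_value: float,
    v0: SurfaceCurve,
) -> list[FixedPoint]:
    """Fixed points where an epistatic constraint line crosses a v=0 curve.

    ``diminishing_returns`` moves along Nsb at fixed Nsd = ``line_value``
    (horizontal line): v > 0 pushes Nsb down, so every crossing from the
    v > 0 side is stable.  ``increasing_costs`` moves along Nsd at fixed
    Nsb = ``line_value`` (vertical line): with Nsb above the curve's nose
    there is no crossing (no long-term attractor); below it there are two,
    the smaller-Nsd one stable.  ``decreasing_costs`` reverses the motion
    along Nsd, swapping the stabilities.
    """
    nsd, nsb = v0.as_arrays()
    ok = np.isfinite(nsd) & np.isfinite(nsb)
    nsd, nsb = nsd[ok], nsb[ok]
    points: list[FixedPoint] = []
    if pattern == "diminishing_returns":
        # crossings of Nsb(Nsd=line_value): interpolate the curve at Nsd
        if len(nsd) < 2 or not (nsd.min() <= line_value <= nsd.max()):
            return points
        nsb_at = float(np.interp(line_value, nsd, nsb))
        points.append(FixedPoint(nsb_at, line_value, "stable"))
        return points
    if pattern in ("increasing_costs", "decreasing_costs"):
        # crossings of the vertical line Nsb = line_value with the curve
        crossings = []
        for i in range(len(nsd) - 1):
            a, b = nsb[i], nsb[i + 1]
            if (a - line_value) * (b - line_value) <= 0 and a != b:
                frac = (line_value - a) / (b - a)
                crossings.append(nsd[i] + frac * (nsd[i + 1] - nsd[i]))
        crossings.sort()
        if not crossings:
            return points
        # under increasing costs, v>0 moves Nsd up; below the first crossing
        # the population adapts (v>0), between crossings it declines
        labels = ["stable", "unstable"]
        if pattern == "decreasing_costs":
            labels = ["unstable", "stable"]
        for j, c in enumerate(crossings[:2]):
            points.append(FixedPoint(line_value, float(c), labels[j % 2]))
        return points
    raise ValueError(f"no constraint-line geometry for pattern {pattern!r}")
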