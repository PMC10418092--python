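"""The MSSM core: fixation probabilities, rates, and the implicit Tc solver.

In a rapidly adapting (or declining) asexual population, linked selection
makes the fate of a mutation depend on the whole traveling wave of fitness
rather than on its own effect alone.  The moderate-selection strong-mutation
(MSSM) approximation summarizes this by a single coalescence timescale Tc
(about half the mean pairwise coalescent time T2): a mutation of effect s
fixes with probability

    p_fix(s) ≈ e^{Tc·s} / N,

for beneficial and deleterious effects alike.  The rate of mean-fitness
change and the total selected fixation rate follow by integration over the
DFE,

    v = U ∫ ρ(s) s e^{Tc·s} ds,        F = U ∫ ρ(s) e^{Tc·s} ds.

Tc itself is fixed by an implicit relation involving the wave's fitness lead
xc and an Airy-function fitness scale b (z0 ≈ −2.338 is the least negative
zero of Ai):

    log(N·xc) = Tc(xc − U) − v·Tc²/2 + U ∫ ρ(s) (e^{Tc·s} − 1)/s ds,
    xc = U ∫ ρ(s) [Tc·s·e^{Tc·s} + 1 − e^{Tc·s}] ds − b·z0 − 1/Tc,
    b³ = (U/2) ∫ ρ(s) s² e^{Tc·s} ds.

For strongly deleterious effects the MSSM relation gives way to a
background-selection heuristic, Tc ≈ N·exp(−Ud ∫ ρd(s)(1−e^{−Tc·s})/s ds),
the classic N·e^{−Ud/sd} when a single strong effect dominates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .dfe import (
    DFESpec,
    DivergentIntegralError,
    deleterious_magnitudes,
    dfe_integral,
    scale_dfe,
)

__all__ = [
    "MSSMSolution",
    "NoRootError",
    "airy_least_negative_zero",
    "pfix_mssm",
    "pfix_diffusion",
    "v_rate",
    "fixation_rate",
    "solve_Tc",
    "tc_ne_heuristic",
    "critical_population_size",
]

logger = logging.getLogger("vzero")

_EXP_CAP = 700.0  # log-space guard for e^{Tc·s}


class NoRootError(RuntimeError):
    """The Tc relation (or a nested search) has no sign change in bracket."""


def airy_least_negative_zero() -> float:
    """Least negative zero of Ai(z), found by root-finding (≈ −2.33811)."""
    return float(
        optimize.brentq(
            lambda z: special.airy(z)[0], -3.0, -1.0, xtol=1e-14, rtol=8.9e-16
        )
    )


# computed once at import; never hard-coded
Z0 = airy_least_negative_zero()


# ---------------------------------------------------------------------------
# Fixation probabilities
# ---------------------------------------------------------------------------


def pfix_mssm(s, Tc: float, N: float):
    """MSSM fixation probability e^{Tc·s}/N (valid for either sign of s)."""
    if N < 1 or Tc <= 0:
        raise ValueError("require N >= 1 and Tc > 0")
    logp = np.minimum(np.asarray(s, dtype=float) * Tc - math.log(N), _EXP_CAP)
    out = np.exp(logp)
    return float(out) if np.isscalar(s) else out


def pfix_diffusion(s, Tc: float, N: float):
    """Single-locus diffusion fixation probability (2Tc/N)·2s/(1−e^{−4Tc·s}).

    The classic independent-sites formula with T2/2 = Tc playing the role of
    an effective population size; continuous at s = 0 with value 1/N.
    """
    if N < 1 or Tc <= 0:
        raise ValueError("require N >= 1 and Tc > 0")
    x = 4.0 * Tc * np.asarray(s, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    # 2s/(1−e^{−4Tcs}) = (x/2Tc)/(1−e^{−x}); at x→0 the ratio x/(1−e^{−x})→1
    ratio = np.where(
        small, 1.0 + x / 2.0, xs / -np.expm1(np.clip(-xs, -_EXP_CAP, _EXP_CAP))
    )
    out = (1.0 / N) * ratio
    return float(out) if np.isscalar(s) else out


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


def v_rate(N: float, U: float, dfe: DFESpec, Tc: float) -> float:
    """Rate of mean-fitness change v = U ∫ρ(s) s e^{Tc·s} ds.

    (= N·U·∫ρ s p_fix with the MSSM p_fix; the N's cancel.)  Has the same
    sign as the scaled v=0 residual.
    """
    return U / Tc * dfe_integral(dfe, "v", Tc=Tc)


def fixation_rate(N: float, U: float, dfe: DFESpec, Tc: float) -> float:
    """Total selected fixation rate F = U ∫ρ(s) e^{Tc·s} ds.

    F − U has the sign of the F=U surface residual.
    """
    return U * (dfe_integral(dfe, "F", Tc=Tc) + 1.0)


def v_rate_diffusion(N: float, U: float, dfe: DFESpec, Tc: float) -> float:
    """v computed with the single-locus diffusion p_fix (the Ne-heuristic
    companion): v = N·U·∫ρ(s) s p_diff(s) ds."""
    return N * U * dfe_integral(
        dfe, lambda g: (g / Tc) * pfix_diffusion(g / Tc, Tc, N), Tc=Tc
    )


# ---------------------------------------------------------------------------
# The implicit Tc relation
# ---------------------------------------------------------------------------


@dataclass
class MSSMSolution:
    """Self-consistent MSSM state for one (N, U, ρ) parameter set."""

    N: float
    U: float
    dfe: DFESpec
    Tc: float
    xc: float
    b: float
    v: float
    F: float
    z0: float
    residual: float
    validity: dict = field(default_factory=dict)

    def pfix(self, s):
        """e^{Tc·s}/N at the solved Tc."""
        return pfix_mssm(s, self.Tc, self.N)

    @property
    def scaled_dfe(self):
        return scale_dfe(self.dfe, self.Tc)


def _relation_pieces(N, U, dfe, Tc):
    """(g(Tc), xc, b, v) for the implicit relation; g = 0 at the solution."""
    with np.errstate(over="ignore", invalid="ignore"):
        I_v = dfe_integral(dfe, "v", Tc=Tc)      # ∫ρ̃ γe^γ
        I_xc = dfe_integral(dfe, "xc", Tc=Tc)    # ∫ρ̃ (γe^γ+1−e^γ)
        I_b3 = dfe_integral(dfe, "b3", Tc=Tc)    # ∫ρ̃ γ²e^γ
        I_e8 = dfe_integral(dfe, "eq8", Tc=Tc)   # ∫ρ̃ (e^γ−1)/γ
    if not all(map(math.isfinite, (I_v, I_xc, I_b3, I_e8))):
        return math.nan, math.nan, math.nan, math.nan
    v = U * I_v / Tc
    b = (0.5 * U * I_b3 / Tc**2) ** (1.0 / 3.0)
    xc = U * I_xc - b * Z0 - 1.0 / Tc
    if xc <= 0:
        return math.nan, xc, b, v
    g = Tc * (xc - U) - 0.5 * v * Tc**2 + U * Tc * I_e8 - math.log(N * xc)
    return g, xc, b, v


def _tilted_mean(dfe, Tc, sign):
    """Mean |s| of the e^{Tc·s}-tilted DFE on one side (fixed-effect scale)."""
    from .dfe import with_eta

    try:
        side = with_eta(dfe, math.inf if sign > 0 else 0.0)
    except ValueError:
        return math.nan
    w = dfe.weight_beneficial if sign > 0 else dfe.weight_deleterious
    if w == 0:
        return math.nan
    ef = dfe_integral(side, "F", Tc=Tc) + 1.0  # ∫ρ_side e^γ
    sv = dfe_integral(side, "v", Tc=Tc) / Tc   # ∫ρ_side s e^{Tcs}
    if ef <= 0:  # e^{−γd} can underflow for very strong purifying selection
        return math.nan
    return abs(sv / ef)


def solve_Tc(
    N: float,
    U: float,
    dfe: DFESpec,
    bracket: tuple[float, float] | None = None,
    n_scan: int = 150,
) -> MSSMSolution:
    """Solve the implicit MSSM relation for the coalescence timescale Tc.

    Scans g(Tc) on a log grid over the bracket (default [1, N] — the neutral
    coalescence timescale T2/2 = N is the physical ceiling — capped
    below the convergence limit of exponential/gamma beneficial tails),
    brackets every sign change, polishes each with Brent's method, and keeps
    the root whose validity diagnostics (Tc·Ub, Tc·b) are best, logging the
    choice if there are several.

    Raises
    ------
    NoRootError
        If g has no sign change over the scanned bracket (the sign pattern
        is reported).
    """
    if N <= 0 or U <= 0:
        raise ValueError("N and U must be positive")
    tc_lo, tc_hi = bracket if bracket else (1.0, float(N))
    # keep e^{Tc·s} integrable against the beneficial tail
    theta_b = None
    if dfe.family == "exponential_pair":
        theta_b = dfe.sb
    elif dfe.family == "gamma_pair":
        theta_b = dfe.sb / dfe.shape_b
    if theta_b is not None and dfe.weight_beneficial > 0:
        tc_hi = min(tc_hi, (1.0 - 1e-9) / theta_b)
        if tc_hi <= tc_lo:
            raise DivergentIntegralError(
                "beneficial tail diverges over the entire Tc bracket"
            )
    grid = np.geomspace(tc_lo, tc_hi, n_scan)
    with np.errstate(over="ignore", invalid="ignore"):
        gvals = np.array([_relation_pieces(N, U, dfe, t)[0] for t in grid])
    finite = np.isfinite(gvals)
    roots = []
    for i in range(len(grid) - 1):
        if finite[i] and finite[i + 1] and (gvals[i] > 0) != (gvals[i + 1] > 0):
            tc = optimize.brentq(
                lambda t: _relation_pieces(N, U, dfe, t)[0],
                grid[i],
                grid[i + 1],
                xtol=1e-12,
                rtol=8.9e-16,
            )
            roots.append(tc)
    if not roots:
        pattern = "".join(
            "." if not f else ("+" if g > 0 else "-") for f, g in zip(finite, gvals)
        )
        raise NoRootError(
            f"no sign change of the Tc relation in [{tc_lo:.3g}, {tc_hi:.3g}] "
            f"(sign pattern {pattern})"
        )

    def build(tc):
        g, xc, b, v = _relation_pieces(N, U, dfe, tc)
        F = fixation_rate(N, U, dfe, tc)
        Ub = U * dfe.weight_beneficial
        s_b = _tilted_mean(dfe, tc, +1)
        s_d = _tilted_mean(dfe, tc, -1)
        validity = {
            "Tc_dxf": tc * b,
            "Tc_Ub": tc * Ub,
            "sb_over_dxf": s_b / b if b > 0 else math.nan,
            "sd_over_dxf": s_d / b if b > 0 else math.nan,
            "warnings": [],
        }
        if validity["Tc_Ub"] < 1.0:
            validity["warnings"].append("Tc*Ub < 1: MSSM may be invalid")
        if validity["Tc_dxf"] < 2.0:
            validity["warnings"].append("Tc*b < 2: population may not be rapidly evolving")
        return MSSMSolution(N, U, dfe, tc, xc, b, v, F, Z0, g, validity)

    sols = [build(tc) for tc in roots]
    if len(sols) > 1:
        # prefer the root that best satisfies the rapid-evolution conditions,
        # tie-broken toward the neutral (large-Tc) end
        sols.sort(key=lambda s: (len(s.validity["warnings"]), -s.Tc))
        logger.info(
            "Tc relation has %d roots (%s); keeping Tc=%.6g",
            len(sols),
            ", ".join(f"{s.Tc:.4g}" for s in sols),
            sols[0].Tc,
        )
    sol = sols[0]
    for w in sol.validity["warnings"]:
        logger.debug("solve_Tc(N=%g, U=%g): %s", N, U, w)
    return sol


def tc_ne_heuristic(
    N: float,
    Ud: float,
    dfe: DFESpec,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> float:
    """Background-selection coalescence estimate.

    Fixed point of Tc = N·exp(−Ud ∫ρd(s)(1−e^{−Tc·s})/s ds) over the
    deleterious component of ``dfe``, found by damped fixed-point iteration
    in log Tc.  With a single strong effect (Tc·sd ≫ 1) this reduces to the
    classic N·e^{−Ud/sd}.  Beneficial mutations are ignored by construction.
    """
    if Ud < 0 or N <= 0:
        raise ValueError("require N > 0 and Ud >= 0")
    if Ud == 0:
        return float(N)
    mags = deleterious_magnitudes(dfe)

    def rhs_log(tc):
        # ∫ρd(s)(1−e^{−Tc·s})/s ds = Tc·∫ρ̃d(γ)(1−e^{−γ})/γ dγ
        return math.log(N) - Ud * tc * dfe_integral(mags, "ne", Tc=tc)

    # damped fixed-point iteration in log Tc; the damping is halved whenever
    # the update overshoots (oscillating sign), which handles the strong
    # feedback of large Ud/sd
    log_tc = math.log(N)
    damp = 0.5
    prev_step = 0.0
    converged = False
    for _ in range(max_iter):
        step = rhs_log(math.exp(log_tc)) - log_tc
        if step * prev_step < 0:
            damp = max(damp * 0.5, 1e-3)
        prev_step = step
        log_tc += damp * step
        if abs(step) < 1e-13:
            converged = True
            break
    if not converged:
        # the map's RHS is strictly decreasing in Tc, so the fixed point is
        # unique; fall back to a bracketed root of log Tc − rhs(log Tc)
        lo, hi = math.log(1e-6), math.log(N)
        log_tc = optimize.brentq(
            lambda lt: lt - rhs_log(math.exp(lt)), lo, hi, xtol=1e-14
        )
    tc = math.exp(log_tc)
    resid = abs(tc - math.exp(rhs_log(tc))) / tc
    if resid > tol:
        raise NoRootError(f"Ne-heuristic fixed point residual {resid:.2e} > {tol}")
    return tc


def critical_population_size(
    U: float,
    dfe: DFESpec,
    bracket: tuple[float, float] = (1e2, 1e12),
) -> float:
    """Census size N0 at which v = 0 for fixed U and ρ(s).

    v > 0 for N > N0 (adaptation) and v < 0 for N < N0 (decline) over the
    bracket.  Raises :class:`NoRootError` when v has one sign throughout —
    e.g. when η exceeds the always-adapt threshold for every reachable Tc.
    """

    def v_of_logN(logN):
        sol = solve_Tc(math.exp(logN), U, dfe)
        return sol.v

    lo, hi = (math.log(b) for b in bracket)
    flo, fhi = v_of_logN(lo), v_of_logN(hi)
    if flo * fhi > 0:
        raise NoRootError(
            f"v has the same sign ({'+' if flo > 0 else '-'}) at both ends of "
            f"the N bracket {bracket}"
        )
    logN0 = optimize.brentq(v_of_logN, lo, hi, xtol=1e-10, rtol=8.9e-16)
    return math.exp(logN0)
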