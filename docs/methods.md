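# Methods

## Model

We consider N haploid individuals evolving asexually. Each generation,
every individual acquires a Poisson(U) number of selected mutations with
effects drawn from a DFE ρ(s) (beneficial s > 0, deleterious s < 0) plus
Poisson(Un) neutral mutations, and offspring are drawn multinomially with
expected number e^{X − X̄}, where X is log-fitness (the sum of carried
effects). Recombination, diploidy, back-mutation at a site, and demographic
change are outside the model; the genome is infinite-sites.

DFEs are two-component mixtures with weights η/(1+η) beneficial and
1/(1+η) deleterious, η = Ub/Ud (η ≤ 1 typical; deleterious scales are
stored positive, the sign lives in the kernels). Supported families:
`two_effect` (delta atoms), `exponential_pair`, `gamma_pair`
(numerical-quadrature path only), and `tabulated` (discrete atoms — the
simplest exactly-testable semantics; we do not interpolate a density).

## Theory pipeline

All theory quantities are integrals ∫ρ̃(γ)K(γ)dγ of the scaled DFE
(γ = Tc·s) against a small kernel family. Delta and exponential components
use closed forms; gamma and tabulated components use adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e−11), with the e^γ growth of
the kernels folded into the weight's exponent in log space so integrands
never overflow. Kernels with removable singularities at γ = 0 —
(e^γ−1)/γ, (1−e^{−γ})/γ, (γe^γ+1−e^γ)/γ — switch to Taylor branches below
|γ| ≈ 1e−4…1e−6 to avoid cancellation. An exponential (or gamma) beneficial
tail with scale ≥ 1 makes the e^γ-growing kernels diverge; this is raised
as an explicit error, and the divergence boundary is itself exposed as a
computed quantity (localized by bisecting the sign of the tail exponent
γ(1 − 1/m); the boundary is exactly m = 1).

The α = 0 kernel is (γe^γ + 1 − e^γ)/γ = e^γ + (1−e^γ)/γ. Written this
way it vanishes as γ → 0, which is what makes the three balance surfaces
merge onto the neutral-accumulation surface η = γd/γb for weak effects and
keeps the ordering η|v=0 < η|α=0 < η|F=U strict for every mixture; both
properties are enforced by property tests.

Balance fractions η on a surface are obtained two independent ways: closed
forms where they exist (two-effect v=0 and F=U; exponential v=0,
η = (γd/γb)((1−γb)/(1+γd))²) and bracketed bisection of the residual on
log η ∈ [log 1e−12, log 1e3] — safe because the residual is linear in the
mixture weights, hence monotone in η. Ridgeline searches maximize η over
γd by a coarse log-grid scan plus bounded golden-section refinement; the
two supported families both peak at γd* = 1, with γb* = W(1/(e·η))
(two-effect, `scipy.special.lambertw`, cross-checked against direct
bisection of w·e^w) and γb* = 1 + 2η − 2√(η² + η) (exponential; obtained
by maximizing the quadrature-backed surface rather than trusting any
printed formula, and verified against that closed expression).

## The coalescence timescale

Tc solves the implicit relation

    log(N·xc) = Tc(xc − U) − v·Tc²/2 + U∫ρ(s)(e^{Tc·s}−1)/s ds
    xc = U∫ρ(s)[Tc·s·e^{Tc·s} + 1 − e^{Tc·s}]ds − b·z0 − 1/Tc
    b³ = (U/2)∫ρ(s)s²e^{Tc·s}ds,

with v evaluated self-consistently at the same Tc, making this a
one-variable root problem. z0, the least negative zero of Ai(z), is found
by root-finding at import (≈ −2.3381074), never hard-coded. The b³
prefactor is U/2: only that reading gives b the units of a fitness rate.

The solver scans g(Tc) on a 150-point log grid over [1, N] — N is the
neutral ceiling Tc = T2/2 ≤ N — additionally capped below the beneficial
tail's convergence limit, brackets every sign change, and polishes each
with Brent's method (residual < 1e−8 asserted by tests). The relation has
a spurious root family at the edge of its domain (xc → 0⁺ makes
−log(N·xc) → +∞); when several roots exist the solver keeps the one with
the best rapid-evolution diagnostics (Tc·Ub ≥ 1, Tc·b ≥ 2 — thresholds
chosen for "≫ 1", reported as warnings, never silently enforced),
tie-broken toward the neutral end, and logs the choice. The typical fixed
effect diagnostics s̃b, s̃d are the means of the e^{Tc·s}-tilted DFE per
side (the mode degenerates to 0 for exponential tails); they feed no
computation.

For strongly deleterious effects the relation's Tc-dependence saturates
(every e^{−γd} term vanishes) and it has no root — the known breakdown
regime. There the background-selection heuristic
Tc = N·exp(−Ud∫ρd(s)(1−e^{−Tc·s})/s ds) applies, solved by damped
fixed-point iteration in log Tc with overshoot-halving and a bracketed
root fallback (the fixed point is unique since the right side decreases in
Tc); with a single strong effect it reduces to N·e^{−Ud/sd} (verified to
1%).

## Unscaled curves and patching

Predicted curves Nsb(Nsd) at fixed (η, NU) resolve U = NU/N with a default
N = 10⁶ (user-overridable; N enters only through log N in the relation).
Each grid point root-solves the balance measure in Nsb with Tc re-solved
per candidate (MSSM branch). Because the inner relation's root families
can swap discontinuously near the neutral edge, an outer "root" is
accepted only if its residual is far below the bracketing values, and the
MSSM branch is truncated at any discontinuous upward Tc jump along the
grid. Past the curve's nose (Nsd*, Nsb*) — refined by bisection between
the last success and first failure — the v=0 prediction is
min[(Nsb)*, (Nsb)_NE], with the NE value from the diffusion fixation
probability (2Tc/N)·2s/(1−e^{−4Tc·s}) at the heuristic Tc. The F=U curve
keeps the MSSM Tc on the whole grid (its scaled beneficial coordinate
tends to log(1+1/η) at large γd, so strong purifying selection never
dominates). The α=0 curve switches to the heuristic-Tc branch at its own
MSSM turning point — the exact crossover is not uniquely determined by the
theory; mirroring the v=0 patch is this package's documented choice.
Solver failures are emitted as NaN rows, never interpolated.

Two distinct landmarks are tracked per curve: the Nsd-maximal nose (the
patch point) and the Nsb-maximal extremal point. The scaled ridgeline
mapped through the on-curve Tc approximately coincides with the latter;
`star_vs_ridge_coincidence` reports the relative offsets and flags them
above 20%. At desk scale (NU = 10², η = 0.1, where Tc·Ub ≈ 1 at the ridge)
the Nsd offset is ≈ 20–25%, consistent with marginal validity; the offsets
shrink with NU.

## Simulator

Segregating mutations live in a boolean mutation × individual matrix;
log-fitness is maintained incrementally and checked on demand against the
fixed-background ledger plus carried effects. A mutation's fate resolves
the generation its carrier count hits 0 or N; fixed rows are compacted out
so memory is bounded by the segregating load. Pairwise heterozygosity per
class is computed exactly through π = Σ_m k_m(N−k_m)/C(N,2), the
frequency identity for the all-pairs symmetric-difference average, so no
pair subsampling is needed at any N this package targets.

The epoch protocol starts clonally; the time to the first fixation of any
mutation sets the epoch length, and mean fitness plus both
heterozygosities are recorded at each of up to 100 epochs. Runs that reach
a generation cap (default 10⁵) before fixating, or mid-protocol, are
returned flagged rather than discarded — an explicit cap replaces any
wall-clock rule, and the cap and epoch counts used are part of each run's
metadata. Estimators: v̂ is the least-squares slope of mean fitness over
epoch-end generations, F̂ the cumulative selected fixations per
generation, T̂c = π_neu/(4Un) run-averaged (an optional burn-in fraction
discards early, not-yet-equilibrated epochs), and
α = 1 − (Un·π_sel)/(F·π_neu), undefined (raised) at F = 0 or π_neu = 0.
Un defaults to 0.01 — small enough not to perturb the dynamics, large
enough that π_neu is measurable at desk-scale N; it is configurable
everywhere.

Grid extremal points follow the verbatim extraction rules: in scaled space
the v̂ < 0 cell with the largest measured γb; in unscaled space the
largest Nsb with v̂ < 0 and the median Nsd among its v̂ < 0 cells.

## Epistasis

Fitness-mediated rules rescale a drawn effect by the carrier's own
log-fitness relative to the founder: sb(X) = sb0·e^{−X/λ} and/or
sd(X) = sd0·e^{+X/λ}, λ = 5 by default; the joint pattern conserves sb·sd
to machine precision (asserted). The per-individual (not population-mean)
dependence matches the "next available mutation" semantics; with λ = ∞
the run is bitwise identical to the fixed-DFE simulator under the same
seed. Epistatic runs default to 5000 generations sampled every 100. The
slow-epistasis theory flow integrates dX/dt = v(N, U, ρ(·|X)) with
explicit Euler steps capped at ΔX = 0.01λ (so per-step scale changes stay
below 1%), halving the cap whenever v changes sign, down to a fixed-point
tolerance. Fixed-point classification intersects the constraint line
(horizontal in Nsd for diminishing returns, vertical for
increasing/decreasing costs) with a v=0 curve; stability follows from the
sign of v along the direction of motion, and decreasing costs swaps the
two stabilities relative to increasing costs.

## What the synthetic runs do and do not show

Simulated validation runs use desk-scale parameters — NU = 10², N = 10³,
grids of 5×5 cells with 3 seeds, epochs capped near 2×10³ generations —
rather than the much larger supplies where the traveling-wave limit is
cleanest. At this scale Tc·Ub ~ 1 near the ridgeline, so agreement is
assessed as sign agreement of v (≥ 80% of statistically resolvable cells;
measured ≈ 90%) rather than point-wise rate agreement, and cells within
two standard errors of the boundary are excluded as unresolvable. Passing
these tests shows the theory ↔ simulation correspondence in the regime
where both are computable in minutes; it does not by itself establish
quantitative accuracy at empirical parameter ranges, for real genomes with
recombination or finite sites, or for DFEs outside the tested families.

## Numerical conventions

Seeded `numpy.random.Generator` throughout; identical seeds give
byte-identical outputs (asserted down to the CLI's TSV bytes). Grid-cell
seeds are derived from the base seed by fixed offsets so cells are
independently reproducible. η root brackets, quadrature tolerances
(1e−11), solver residual targets (1e−8…1e−10) and the golden-section
tolerances are fixed constants noted at their definitions; none adapt to
data.
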