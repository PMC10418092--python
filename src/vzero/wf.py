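"""Individual-based Wright–Fisher simulator with tracked mutations.

Each generation consists of a mutation step — every individual acquires
Poisson(U) selected mutations with effects drawn from ρ(s), plus Poisson(Un)
neutral mutations — followed by a reproduction step in which N offspring are
resampled with replacement with probabilities proportional to e^{X}, where X
is an individual's log-fitness (the sum of its mutations' effects).  The
genome is infinite-sites: every mutation event is a new tracked record, and
a mutation's fate is resolved the generation its carrier count hits 0 (lost)
or N (fixed).

Internally the segregating state is a boolean mutation × individual matrix;
fixed mutations are compacted out into a ledger so memory stays bounded by
the segregating load.  Pairwise heterozygosity is computed exactly through
the per-mutation frequency identity Σ k(N−k)/C(N,2), which equals the
average symmetric difference over all unordered pairs of individuals.

The epoch protocol mirrors the standard measurement scheme for rapidly
evolving populations: from a clonal start, the time to the first fixation
sets the epoch length; mean fitness and neutral/selected heterozygosities
are recorded at every subsequent epoch, from which the rate of fitness
change v, the selected fixation rate F, the coalescence timescale
Tc = π_neu/(4 Un) and the McDonald–Kreitman-like statistic α are estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfe import DFESpec

__all__ = [
    "MutationRecord",
    "Population",
    "EpochReport",
    "EpochRun",
    "MeasuredRates",
    "run_epochs",
    "measured_rates",
    "alpha_stat",
    "GridResult",
    "simulate_grid",
    "ridgeline_from_grid",
]


@dataclass
class MutationRecord:
    """Fate record of one tracked mutation (neutral mutations have effect 0)."""

    id: int
    effect: float
    origin_generation: int
    status: str = "segregating"  # -> "fixed" | "lost"
    neutral: bool = False
    resolved_generation: int | None = None


def draw_effects(rng: np.random.Generator, dfe: DFESpec, n: int) -> np.ndarray:
    """Sample n signed fitness effects from a DFE."""
    if n == 0:
        return np.empty(0)
    if dfe.family == "tabulated":
        s = np.array([x for x, _ in dfe.table])
        w = np.array([w for _, w in dfe.table])
        return rng.choice(s, size=n, p=w)
    beneficial = rng.random(n) < dfe.weight_beneficial
    out = np.empty(n)
    nb = int(beneficial.sum())
    nd = n - nb
    if dfe.family == "two_effect":
        out[beneficial] = dfe.sb
        out[~beneficial] = -dfe.sd
    elif dfe.family == "exponential_pair":
        out[beneficial] = rng.exponential(dfe.sb, nb)
        out[~beneficial] = -rng.exponential(dfe.sd, nd)
    else:  # gamma_pair, mean = shape * scale
        out[beneficial] = rng.gamma(dfe.shape_b, dfe.sb / dfe.shape_b, nb)
        out[~beneficial] = -rng.gamma(dfe.shape_d, dfe.sd / dfe.shape_d, nd)
    return out


class Population:
    """Wright–Fisher population state with per-individual mutation sets.

    Parameters
    ----------
    N : population size (haploid individuals, constant).
    U : selected mutation rate per individual per generation.
    Un : neutral mutation rate per individual per generation.
    dfe : distribution of fitness effects of selected mutations.
    seed : RNG seed; runs with equal seeds are bit-reproducible.
    epistasis : optional fitness-mediated epistasis rule; when present, each
        individual's available effect magnitudes are rescaled by its own
        log-fitness before a drawn mutation is applied.
    """

    def __init__(self, N, U, Un, dfe, seed=0, epistasis=None):
        if N < 1:
            raise ValueError("N must be at least 1")
        self.N = int(N)
        self.U = float(U)
        self.Un = float(Un)
        self.dfe = dfe
        self.rng_seed = seed
        self.rng = np.random.default_rng(seed)
        self.epistasis = epistasis
        self.generation = 0
        self.X = np.zeros(self.N)
        # segregating state: rows = mutations, columns = individuals
        self.M = np.zeros((0, self.N), dtype=bool)
        self.row_ids = np.empty(0, dtype=np.int64)
        self.row_effects = np.empty(0)
        self.row_neutral = np.empty(0, dtype=bool)
        self.registry: dict[int, MutationRecord] = {}
        self._next_id = 0
        self.fixed_effect_sum = 0.0
        self.fixed_selected = 0
        self.fixed_neutral = 0
        self.lost = 0

    # -- mutation -----------------------------------------------------------

    def _new_rows(self, owners, effects, neutral):
        n = len(owners)
        if n == 0:
            return
        rows = np.zeros((n, self.N), dtype=bool)
        rows[np.arange(n), owners] = True
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        for i, s, nt in zip(ids, effects, neutral):
            self.registry[int(i)] = MutationRecord(
                int(i), float(s), self.generation, neutral=bool(nt)
            )
        self.M = np.vstack([self.M, rows]) if self.M.size else rows
        self.row_ids = np.concatenate([self.row_ids, ids])
        self.row_effects = np.concatenate([self.row_effects, effects])
        self.row_neutral = np.concatenate([self.row_neutral, neutral])
        self.X[owners] += effects

    def _mutation_step(self):
        n_sel = self.rng.poisson(self.U, self.N)
        n_neu = self.rng.poisson(self.Un, self.N)
        owners_sel = np.repeat(np.arange(self.N), n_sel)
        eff_sel = draw_effects(self.rng, self.dfe, len(owners_sel))
        if self.epistasis is not None and len(owners_sel):
            eff_sel = self.epistasis.apply(eff_sel, self.X[owners_sel])
        owners_neu = np.repeat(np.arange(self.N), n_neu)
        owners = np.concatenate([owners_sel, owners_neu])
        effects = np.concatenate([eff_sel, np.zeros(len(owners_neu))])
        neutral = np.concatenate(
            [np.zeros(len(owners_sel), bool), np.ones(len(owners_neu), bool)]
        )
        self._new_rows(owners, effects, neutral)

    # -- reproduction -------------------------------------------------------

    def _reproduction_step(self):
        w = np.exp(self.X - self.X.mean())  # e^{X−X̄}: stable, same law as e^X
        p = w / w.sum()
        parents = self.rng.choice(self.N, size=self.N, p=p)
        self.X = self.X[parents]
        if self.M.shape[0]:
            self.M = np.take(self.M, parents, axis=1)

    def _resolve_fates(self):
        if not self.M.shape[0]:
            return
        k = self.M.sum(axis=1)
        fixed = k == self.N
        lost = k == 0
        if not (fixed.any() or lost.any()):
            return
        for i in np.nonzero(fixed)[0]:
            rec = self.registry[int(self.row_ids[i])]
            rec.status = "fixed"
            rec.resolved_generation = self.generation
            self.fixed_effect_sum += self.row_effects[i]
            if self.row_neutral[i]:
                self.fixed_neutral += 1
            else:
                self.fixed_selected += 1
        for i in np.nonzero(lost)[0]:
            rec = self.registry[int(self.row_ids[i])]
            rec.status = "lost"
            rec.resolved_generation = self.generation
        self.lost += int(lost.sum())
        keep = ~(fixed | lost)
        self.M = self.M[keep]
        self.row_ids = self.row_ids[keep]
        self.row_effects = self.row_effects[keep]
        self.row_neutral = self.row_neutral[keep]

    def generation_step(self):
        """One generation: mutation, multinomial reproduction, fate updates."""
        self._mutation_step()
        self._reproduction_step()
        self.generation += 1
        self._resolve_fates()
        return self

    # -- measurements -------------------------------------------------------

    def mean_fitness(self) -> float:
        return float(self.X.mean())

    def measure_heterozygosity(self, klass: str = "neutral") -> float:
        """Average pairwise symmetric-difference count for one mutation class.

        Exact over all unordered pairs via π = Σ_m k_m (N−k_m) / C(N, 2).
        """
        if self.N < 2:
            raise ValueError("heterozygosity needs at least 2 individuals")
        if klass not in ("neutral", "selected"):
            raise ValueError("class must be 'neutral' or 'selected'")
        sel = self.row_neutral if klass == "neutral" else ~self.row_neutral
        if not sel.any():
            return 0.0
        k = self.M[sel].sum(axis=1).astype(float)
        return float((k * (self.N - k)).sum() / (self.N * (self.N - 1) / 2.0))

    def check_consistency(self, atol=1e-9) -> bool:
        """X of every individual equals fixed background + carried effects."""
        expect = self.fixed_effect_sum + self.row_effects @ self.M
        return bool(np.allclose(self.X, expect, atol=atol))

    @property
    def n_segregating(self) -> int:
        return self.M.shape[0]


# ---------------------------------------------------------------------------
# Epoch protocol
# ---------------------------------------------------------------------------


@dataclass
class EpochReport:
    epoch: int
    generation: int
    mean_fitness: float
    pi_neu: float
    pi_sel: float
    fixed_selected: int
    fixed_neutral: int
    fixed_effect_sum: float


@dataclass
class EpochRun:
    epoch_length: int | None
    reports: list[EpochReport]
    cap_exceeded: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.reports)


def _report(pop, epoch):
    return EpochReport(
        epoch=epoch,
        generation=pop.generation,
        mean_fitness=pop.mean_fitness(),
        pi_neu=pop.measure_heterozygosity("neutral"),
        pi_sel=pop.measure_heterozygosity("selected"),
        fixed_selected=pop.fixed_selected,
        fixed_neutral=pop.fixed_neutral,
        fixed_effect_sum=pop.fixed_effect_sum,
    )


def run_epochs(pop: Population, max_epochs: int = 100, generation_cap: int = 100_000) -> EpochRun:
    """Run the epoch protocol from a clonal start.

    The generations elapsing before the first fixation of any mutation set
    the epoch length; subsequent epochs have the same length, with mean
    fitness and both heterozygosities recorded at each epoch.  If no
    fixation occurs within ``generation_cap`` generations (or the cap is hit
    mid-run), the run is returned flagged rather than discarded.
    """
    if pop.generation != 0:
        raise ValueError("epoch protocol requires a fresh clonal population")
    total_fixed = 0
    while total_fixed == 0:
        if pop.generation >= generation_cap:
            return EpochRun(None, [], cap_exceeded=True)
        pop.generation_step()
        total_fixed = pop.fixed_selected + pop.fixed_neutral
    epoch_length = pop.generation
    reports = [_report(pop, 1)]
    for epoch in range(2, max_epochs + 1):
        if pop.generation + epoch_length > generation_cap:
            return EpochRun(epoch_length, reports, cap_exceeded=True)
        for _ in range(epoch_length):
            pop.generation_step()
        reports.append(_report(pop, epoch))
    return EpochRun(epoch_length, reports)


@dataclass
class MeasuredRates:
    v_hat: float
    F_hat: float
    Tc_hat: float
    n_epochs: int
    insufficient: bool  # fewer than 10 epochs measured


def measured_rates(run: EpochRun, Un: float | None = None, burn_in: float = 0.0) -> MeasuredRates:
    """Estimate (v̂, F̂, T̂c) from an epoch run.

    v̂ is the least-squares slope of mean fitness against generation at epoch
    resolution; F̂ is total selected fixations per generation; T̂c is the
    run-averaged π_neu/(4·Un) (requires Un).  ``burn_in`` discards a leading
    fraction of epochs from the π average (the fitness slope keeps all).
    """
    reports = run.reports
    if not reports:
        raise ValueError("epoch run has no reports")
    gens = np.array([r.generation for r in reports], dtype=float)
    fit = np.array([r.mean_fitness for r in reports])
    v_hat = float(np.polyfit(gens, fit, 1)[0]) if len(reports) > 1 else math.nan
    F_hat = reports[-1].fixed_selected / reports[-1].generation
    tc_hat = math.nan
    if Un:
        start = int(len(reports) * burn_in)
        pi = np.mean([r.pi_neu for r in reports[start:]])
        tc_hat = pi / (4.0 * Un)
    return MeasuredRates(v_hat, F_hat, tc_hat, len(reports), len(reports) < 10)


def alpha_stat(Un: float, pi_sel: float, pi_neu: float, F: float) -> float:
    """α = 1 − (Un·π_sel)/(F·π_neu), the McDonald–Kreitman-like contrast of
    selected vs neutral polymorphism against divergence."""
    if F <= 0 or pi_neu <= 0:
        raise ValueError("alpha undefined when F <= 0 or pi_neu <= 0")
    return 1.0 - (Un * pi_sel) / (F * pi_neu)


# ---------------------------------------------------------------------------
# Grid protocol
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    """Per-cell measurements over an (Nsb, Nsd) simulation grid."""

    N: int
    U: float
    Un: float
    eta: float
    cells: pd.DataFrame  # Nsb, Nsd, seed, v_hat, F_hat, Tc_hat, alpha, ...


def simulate_grid(
    N: int,
    U: float,
    eta: float,
    nsb_values,
    nsd_values,
    Un: float = 0.01,
    family: str = "two_effect",
    seeds=(0,),
    max_epochs: int = 100,
    generation_cap: int = 100_000,
) -> GridResult:
    """Run the epoch protocol on every (Nsb, Nsd) cell × seed."""
    rows = []
    for nsd in nsd_values:
        for nsb in nsb_values:
            dfe = DFESpec(family=family, sb=nsb / N, sd=nsd / N, eta=eta)
            for seed in seeds:
                pop = Population(N, U, Un, dfe, seed=seed)
                run = run_epochs(pop, max_epochs, generation_cap)
                row = {
                    "Nsb": nsb,
                    "Nsd": nsd,
                    "seed": seed,
                    "epochs": run.n_epochs,
                    "cap_exceeded": run.cap_exceeded,
                }
                if run.reports:
                    rates = measured_rates(run, Un=Un)
                    pi_neu = np.mean([r.pi_neu for r in run.reports])
                    pi_sel = np.mean([r.pi_sel for r in run.reports])
                    row.update(
                        v_hat=rates.v_hat,
                        F_hat=rates.F_hat,
                        Tc_hat=rates.Tc_hat,
                        pi_neu=pi_neu,
                        pi_sel=pi_sel,
                        gamma_b=rates.Tc_hat * nsb / N,
                        gamma_d=rates.Tc_hat * nsd / N,
                    )
                    try:
                        row["alpha"] = alpha_stat(Un, pi_sel, pi_neu, rates.F_hat)
                    except ValueError:
                        row["alpha"] = math.nan
                else:
                    row.update(
                        v_hat=math.nan, F_hat=math.nan, Tc_hat=math.nan,
                        pi_neu=math.nan, pi_sel=math.nan,
                        gamma_b=math.nan, gamma_d=math.nan, alpha=math.nan,
                    )
                rows.append(row)
    return GridResult(N=N, U=U, Un=Un, eta=eta, cells=pd.DataFrame(rows))


def ridgeline_from_grid(grid: GridResult, space: str = "unscaled"):
    """Extremal-point extraction from a simulated grid, by the printed rules.

    unscaled: Nsb* is the largest Nsb with v̂ < 0 for some cell; Nsd* is the
    median Nsd among cells with that Nsb and v̂ < 0.  scaled: the single cell
    with the largest measured γb among v̂ < 0 cells, returning (γb*, γd*).
    """
    cells = grid.cells
    neg = cells[cells["v_hat"] < 0]
    if neg.empty:
        raise ValueError("no grid cell has v < 0")
    if space == "unscaled":
        nsb_star = neg["Nsb"].max()
        nsd_star = float(neg.loc[neg["Nsb"] == nsb_star, "Nsd"].median())
        return float(nsb_star), nsd_star
    if space == "scaled":
        top = neg.loc[neg["gamma_b"].idxmax()]
        return float(top["gamma_b"]), float(top["gamma_d"])
    raise ValueError("space must be 'scaled' or 'unscaled'")
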