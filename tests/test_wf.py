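"""The individual-based simulator: bookkeeping, neutral oracles, estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from vzero.dfe import DFESpec
from vzero.wf import (
    GridResult,
    Population,
    alpha_stat,
    measured_rates,
    ridgeline_from_grid,
    run_epochs,
)

TWOFX = DFESpec("two_effect", sb=0.01, sd=0.02, eta=0.2)


class TestBookkeeping:
    def test_population_size_and_fitness_consistency(self):
        pop = Population(150, 0.05, 0.02, TWOFX, seed=2)
        for _ in range(150):
            pop.generation_step()
        assert len(pop.X) == 150
        assert pop.M.shape[1] == 150
        assert pop.check_consistency()

    def test_seeded_runs_bit_reproducible(self):
        runs = []
        for _ in range(2):
            pop = Population(100, 0.05, 0.02, TWOFX, seed=11)
            run = run_epochs(pop, max_epochs=5, generation_cap=5000)
            runs.append((run.epoch_length, [r.__dict__ for r in run.reports]))
        assert runs[0] == runs[1]

    def test_status_transitions_monotone(self):
        pop = Population(50, 0.1, 0.05, TWOFX, seed=4)
        for _ in range(400):
            pop.generation_step()
        statuses = {}
        for rec in pop.registry.values():
            statuses.setdefault(rec.status, 0)
            statuses[rec.status] += 1
            if rec.status in ("fixed", "lost"):
                assert rec.resolved_generation is not None
                assert rec.resolved_generation > rec.origin_generation - 1
        assert statuses.get("fixed", 0) == pop.fixed_selected + pop.fixed_neutral

    def test_single_individual_fixes_instantly(self):
        pop = Population(1, 0.5, 0.0, TWOFX, seed=0)
        pop.generation_step()
        assert pop.n_segregating == 0  # everything drawn is immediately fixed
        n_muts = len(pop.registry)
        assert pop.fixed_selected == n_muts

    def test_no_mutation_no_fixation_run_flagged(self):
        pop = Population(60, 0.0, 0.0, TWOFX, seed=1)
        run = run_epochs(pop, max_epochs=5, generation_cap=300)
        assert run.cap_exceeded
        assert run.reports == []
        assert pop.mean_fitness() == 0.0


class TestHeterozygosity:
    def test_clonal_population_has_zero_pi(self):
        pop = Population(80, 0.05, 0.02, TWOFX, seed=9)
        assert pop.measure_heterozygosity("neutral") == 0.0
        assert pop.measure_heterozygosity("selected") == 0.0

    def test_two_haplotype_value(self):
        # two equal groups differing by k mutations: pi = k*(N/2)^2 / C(N,2)
        N, k = 40, 3
        pop = Population(N, 0.0, 0.0, TWOFX, seed=0)
        pop.M = np.zeros((k, N), dtype=bool)
        pop.M[:, : N // 2] = True
        pop.row_ids = np.arange(k)
        pop.row_effects = np.zeros(k)
        pop.row_neutral = np.ones(k, dtype=bool)
        expect = k * (N / 2) ** 2 / (N * (N - 1) / 2)
        assert pop.measure_heterozygosity("neutral") == pytest.approx(expect)
        assert pop.measure_heterozygosity("selected") == 0.0

    def test_pi_requires_two_individuals(self):
        pop = Population(1, 0.0, 0.0, TWOFX, seed=0)
        with pytest.raises(ValueError):
            pop.measure_heterozygosity("neutral")


class TestNeutralOracles:
    """Classical neutral Wright-Fisher results as independent checks."""

    def test_fixation_probability_one_over_N(self):
        N, Un, gens = 50, 0.1, 4000
        pop = Population(N, 0.0, Un, TWOFX, seed=17)
        for _ in range(gens):
            pop.generation_step()
        resolved = [
            r for r in pop.registry.values()
            if r.status != "segregating" and r.origin_generation < gens - 10 * N
        ]
        fixed = sum(r.status == "fixed" for r in resolved)
        n = len(resolved)
        p_hat = fixed / n
        se = math.sqrt((1 / N) * (1 - 1 / N) / n)
        assert n > 5000
        assert abs(p_hat - 1 / N) < 2.576 * se  # 99% binomial CI

    def test_neutral_pi_matches_coalescent_expectation(self):
        # E[pi] = 2 N Un for a haploid WF population (E[T2] = N)
        N, Un = 100, 0.05
        pop = Population(N, 0.0, Un, TWOFX, seed=23)
        run = run_epochs(pop, max_epochs=40, generation_cap=40000)
        pis = [r.pi_neu for r in run.reports[10:]]
        assert np.mean(pis) == pytest.approx(2 * N * Un, rel=0.35)


class TestMeasuredRates:
    def test_neutral_run_rates(self):
        pop = Population(100, 0.0, 0.05, TWOFX, seed=5)
        run = run_epochs(pop, max_epochs=12, generation_cap=20000)
        rates = measured_rates(run, Un=0.05)
        assert rates.v_hat == 0.0
        assert rates.F_hat == 0.0
        assert 0.2 * 100 < rates.Tc_hat < 2.0 * 100

    def test_beneficial_run_gains_fitness(self):
        dfe = DFESpec("two_effect", sb=0.05, sd=0.01, eta=1e9)
        pop = Population(500, 1e-3, 0.01, dfe, seed=8)
        run = run_epochs(pop, max_epochs=15, generation_cap=20000)
        rates = measured_rates(run, Un=0.01)
        assert rates.v_hat > 0
        assert rates.F_hat > 0

    def test_weak_deleterious_ratchet_declines(self):
        dfe = DFESpec("two_effect", sb=0.01, sd=1e-3, eta=0.0)
        pop = Population(100, 0.05, 0.01, dfe, seed=13)
        run = run_epochs(pop, max_epochs=25, generation_cap=30000)
        rates = measured_rates(run, Un=0.01)
        assert rates.v_hat < 0

    def test_insufficient_epochs_flagged(self):
        pop = Population(100, 0.0, 0.05, TWOFX, seed=5)
        run = run_epochs(pop, max_epochs=4, generation_cap=20000)
        assert measured_rates(run, Un=0.05).insufficient


class TestAlphaStat:
    def test_no_selected_polymorphism_gives_one(self):
        assert alpha_stat(0.01, 0.0, 5.0, 0.02) == 1.0

    def test_fully_neutral_selected_class_gives_zero(self):
        # F = U and pi_sel/pi_neu = U/Un
        U, Un, pi_neu = 0.08, 0.02, 3.0
        assert alpha_stat(Un, pi_neu * U / Un, pi_neu, U) == pytest.approx(0.0)

    def test_undefined_for_zero_divergence_or_diversity(self):
        with pytest.raises(ValueError):
            alpha_stat(0.01, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            alpha_stat(0.01, 1.0, 0.0, 0.1)


class TestRidgelineFromGrid:
    def _grid(self, rows):
        return GridResult(
            N=1000, U=0.1, Un=0.01, eta=0.1, cells=pd.DataFrame(rows)
        )

    def test_unscaled_median_rule(self):
        rows = []
        for nsd in (10, 15, 20):
            for nsb in (2, 5, 8):
                v = -1.0 if (nsb == 5 and nsd in (10, 20)) else 1.0
                rows.append(dict(Nsb=nsb, Nsd=nsd, v_hat=v,
                                 gamma_b=nsb / 100, gamma_d=nsd / 100))
        assert ridgeline_from_grid(self._grid(rows), "unscaled") == (5.0, 15.0)

    def test_scaled_max_gamma_b_rule(self):
        rows = [
            dict(Nsb=2, Nsd=10, v_hat=-1.0, gamma_b=0.4, gamma_d=1.2),
            dict(Nsb=5, Nsd=10, v_hat=-1.0, gamma_b=0.9, gamma_d=1.0),
            dict(Nsb=8, Nsd=10, v_hat=1.0, gamma_b=1.5, gamma_d=0.8),
        ]
        assert ridgeline_from_grid(self._grid(rows), "scaled") == (0.9, 1.0)

    def test_all_adapting_grid_raises(self):
        rows = [dict(Nsb=2, Nsd=10, v_hat=0.5, gamma_b=0.1, gamma_d=0.5)]
        with pytest.raises(ValueError, match="v < 0"):
            ridgeline_from_grid(self._grid(rows), "unscaled")
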