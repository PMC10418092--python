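# vzero

**When does evolution stop going uphill?** In large asexual populations —
microbial evolution experiments, RNA viruses, cancer cell lines — many
beneficial and deleterious mutations segregate at once on the same
non-recombining background. Clonal interference and hitchhiking then blunt
selection: deleterious mutations fix, beneficial ones are wasted, and for
some parameter ranges Muller's ratchet outruns adaptation and mean fitness
*declines*. `vzero` computes the boundary between these regimes — the
surface in parameter space where the rate of mean-fitness change is exactly
zero — and the companion surfaces where molecular evolution merely *looks*
neutral, together with an individual-based Wright–Fisher simulator to test
the predictions.

It is aimed at population geneticists and evolution-experiment modellers
who want quantitative answers to: given a population size N, a mutation
rate U, and a distribution of fitness effects (DFE) ρ(s), will fitness go
up or down? How fast do selected mutations fix? Would dN/dS or a
McDonald–Kreitman test notice anything?

## The theory in brief

Under the moderate-selection strong-mutation (MSSM) traveling-wave
approximation, linked selection compresses into a single coalescence
timescale Tc (≈ T2/2, half the mean pairwise coalescent time), and a
mutation of effect s fixes with probability

    p_fix(s) ≈ e^{Tc·s} / N            (either sign of s)

so with scaled effects γ ≡ Tc·s the rate of fitness change v and the total
selected fixation rate F become weighted integrals of the scaled DFE ρ̃(γ):

    v ∝ ∫ ρ̃(γ) γ e^γ dγ          v = 0   — adaptation/decline boundary
    F − U ∝ ∫ ρ̃(γ) (e^γ − 1) dγ   F = U   — dN/dS = 1 surface
    α = 0  ⇔  ∫ ρ̃(γ) (γe^γ + 1 − e^γ)/γ dγ = 0   — McDonald–Kreitman-neutral

For a two-effect DFE (atoms at +γb, −γd with rate ratio η = Ub/Ud) the
v=0 surface is η = γd e^{−γd} / (γb e^{γb}); it has a *ridgeline* at
γd\* = 1 where deleterious mutations are maximally impactful, with
γb\* = W(1/(e·η)) (Lambert W) the beneficial effect above which a
population adapts for every γd. The three surfaces are strictly ordered,
η|v=0 < η|α=0 < η|F=U: on the v=0 surface molecular evolution is rapid,
α < 0 and F < U. Tc itself is fixed by an implicit relation involving the
wave's fitness lead xc and an Airy-function scale b (z0 ≈ −2.338); for
strongly deleterious effects a background-selection heuristic
Tc ≈ N·e^{−Ud ∫ρd(s)(1−e^{−Tc·s})/s ds} takes over, and predicted v=0
curves in (Nsd, Nsb) space patch the two regimes at the curve's nose.

The simulator is an infinite-sites multinomial Wright–Fisher model with
tracked mutation identities (Poisson(U) selected + Poisson(Un) neutral
mutations per individual per generation, resampling weights ∝ e^X). It
measures v, F, Tc = π_neu/(4Un) and α from the epoch protocol, and supports
fitness-mediated epistasis in which each individual's available effects
scale with its own log-fitness (e.g. sb ∝ e^{−X/5} with sb·sd held
constant).

## Worked example

Solve the coalescence relation for N = 10⁶, U = 10⁻², and a two-effect DFE
with sb = sd = 10⁻³ and one beneficial mutation per ten deleterious ones
(η = 0.1):

```bash
cat > dfe.yml <<EOF
family: two_effect
sb: 1.0e-3
sd: 1.0e-3
eta: 0.1
EOF
vzero solve-tc --N 1e6 --U 1e-2 --dfe dfe.yml
```

```json
{
  "Tc": 1656.489472049191,
  "xc": 0.01137927843185503,
  "b": 0.001481175982598474,
  "v": 3.0298216756744616e-06,
  "F": 0.006499051517418231,
  "z0": -2.3381074104597652,
  "residual": -3.552713678800501e-15,
  "validity": {
    "Tc_dxf": 2.453552421426488,
    "Tc_Ub": 1.505899520044719,
    "warnings": []
  },
  "Tc_ne_heuristic": 1309.9156367542282
}
```

Reading this: coalescence happens on a ~1700-generation timescale, far
below the census size 10⁶ — linked selection is strong. Scaled effects are
γb = γd = Tc·s ≈ 1.66. v > 0: this population adapts, at ~3×10⁻⁶ log-fitness
per generation; its selected fixation rate F ≈ 0.0065 is below U = 0.01
(deleterious fixations are suppressed more than beneficial ones are
boosted), so dN/dS-style divergence would look *under*-neutral even while
fitness climbs. The validity block confirms the rapid-evolution conditions
(Tc·b and Tc·Ub above 1); `residual` is the solved relation's remaining
error. Dropping η below ≈ e⁻²·(γd e^{−γd}/γb e^{γb}-wise) would flip v
negative — the `surface-scaled` and `surface-unscaled` subcommands map that
boundary:

```bash
vzero surface-unscaled --surface v0 --eta 0.1 --NU 1e2 --N 1e3 \
    --nsd-grid 2:60:6 --sidecar landmarks.json
```

emits the predicted curve Nsb(Nsd) with its `mssm`/`ne` branch per point
and the nose/ridgeline landmarks, and `vzero grid-sim` runs the matching
simulation grid. `vzero epistasis` and `vzero flow` explore
fitness-mediated epistasis (simulation and slow-epistasis theory flow).

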