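# antguild

A mechanistic, temperature-aware model of coexistence in a three-species
guild of ground-foraging woodland ants — *Nylanderia faisonensis*,
*Aphaenogaster rudis*, and *Prenolepis imparis* (the "winter ant") — and of
how that community restructures under climate change.  The package is
aimed at community ecologists who want a fully mechanistic alternative to
climate-envelope reasoning: every prediction emerges from competition for
discrete food patches under empirically grounded species traits, rather
than from correlations with temperature.

## The model

Within a year, discrete food patches per unit area are produced seasonally
at rate λₛσ(t), discovered by foragers, defended, stolen along a strict
behavioral dominance hierarchy, and consumed.  With
Dᵢ = λᵣ rᵢ aᵢ Nᵢ fᵢ(t) the discovery pressure of species *i* (rᵢ relative
per-capita discovery rate, aᵢ foragers per colony, Nᵢ colonies per area,
fᵢ(t) the seasonal fraction of maximal foraging effort):

    dp₀/dt = λₛσ(t) − p₀ ΣⱼDⱼ − b p₀
    dpᵢ/dt = Dᵢ(p₀ + Σⱼ Wᵢⱼ pⱼ) − pᵢ Σⱼ Wⱼᵢ Dⱼ − (λ_c cᵢ + b) pᵢ

where W is the patch-takeover matrix (strict hierarchy:
*N. faisonensis* < *A. rudis* < *P. imparis*), λ_c cᵢ the clearance rate,
and b losses to non-focal species.  Patch dynamics equilibrate within
hours while colony demography moves year to year, so each day is resolved
at its quasi-steady state — a linear solve per day — and colonies update
annually:

    Bᵢ = (ε′ λ_c cᵢ / wᵢaᵢ) Σ_days pᵢ*(d),      Nᵢ ← Nᵢ + μ(Bᵢ − L Nᵢ)

Food cleared by a species is converted to new colonies through its worker
mass wᵢ (small-bodied species mint more workers per mg of food) and colony
size aᵢ.  The equilibrium Nᵢ* = Bᵢ/L is independent of the colony death
rate μ, which is why food quality enters only as ε′ = ε/μ.

A "microhabitat" is one draw of the resource parameters
(λₛ, λ_c, ε′, b) from their empirical ranges; all reported statistics are
ensembles over thousands of microhabitats with common random numbers
across scenarios.  Experiments include trait equalizations (discovery,
clearance, mass, dominance, thermal niche), phenological shifts of 1–4
weeks (earlier springs, later falls), uniform warming of 1–5 °C through
per-species thermal performance curves, and a 100 000-point Latin
hypercube + PRCC analysis of seasonal food supplementation.

## Worked example

```python
import numpy as np
from antguild import Scenario, run_ensemble, summarize, abundance_weights

base = run_ensemble(Scenario(), K=2000, seed=1)
s = summarize(base, weights=abundance_weights(base, "biomass"))
print({k: round(v, 3) for k, v in s.mean_rel_abundance.items()})
print("evenness:", round(s.evenness, 3))
print("three-species microhabitats:", s.composition_fractions["111"])
```

prints (seed 1, K = 2000):

```
{'n_faisonensis': 0.708, 'a_rudis': 0.182, 'p_imparis': 0.11}
evenness: 0.726
three-species microhabitats: 0.1925
```

i.e. at equilibrium the subordinate *N. faisonensis* holds the largest
share of standing forager biomass, all three species persist together in
roughly 19% of sampled microhabitats, and the biomass distribution is
fairly even (Pielou's index 0.73 of a possible 1).  The same ensemble under
`Scenario(kind="shift", weeks=4)` shows the extended-summer effect: a
strong gain for *A. rudis* and a collapse of three-species coexistence.

The command-line interface exposes the same experiments
(`antguild baseline`, `antguild equalize --trait mass`,
`antguild shift --weeks 2`, `antguild warm --dt 3`,
`antguild single --species a_rudis`, `antguild report`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the historical baseline, the equalized-thermal-niche ensemble, the
1–4 week shift scenarios and the single-species *A. rudis* runs from
scratch (K = 2000 microhabitats, common random numbers), and writes the
summary statistics — ensemble evenness, community-composition fractions,
and the largest percent responses of each species to extended summers —
as a JSON file.  Runtime is a few minutes on one CPU.

See `docs/methods.md` for model assumptions, parameter provenance, the
abundance-currency convention, and known limitations.
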