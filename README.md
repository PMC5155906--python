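# hiercoop

Computational model and analysis pipeline for a two-stage economic game
probing how dominance hierarchies affect human cooperation.

Two players, each endowed with *E* = 20 experimental currency units (ECUs),
simultaneously contribute to a common pot. If the pot reaches the threshold
*T* = 20 it doubles to *P* = 40 units and enters a **splitting phase**: the
higher-ranked player offers a division *x* (an ultimatum game); if the
lower-ranked player rejects, a lottery assigns the whole pot to the
lower-ranked player with probability *p* tied to the rank difference —
*p* = *k*/10, where *k* ∈ {1..5} groups rank differences from largest
(*k* = 1, differences 8–9) to smallest (*k* = 5, adjacent ranks). Without a
hierarchy the lottery is a fair coin. Backward induction gives the
subgame-perfect offer

    x* = ceil(p · P) = 4k        (20 units when p = 1/2),

and the contribution stage then supports exactly-at-threshold Nash profiles
in which neither player stakes more than their splitting-phase continuation
value.

The package is aimed at behavioral/experimental economists and modelers who
want to (a) solve the game exactly, (b) generate seeded synthetic studies
with the original design — 240 participants, groups of 10, nine round-robin
rounds, five treatments (no hierarchy / earned hierarchy / random hierarchy,
plus earned and random splitting-only arms) — and (c) run the dyad-bootstrap
statistical pipeline (Helmert-style treatment contrasts, cluster bootstrap
with one member selected per dyad, percentile 95% CIs) on those data.

## Worked example

```python
import numpy as np
from hiercoop import spe_full_game, StudyDesign, generate_study
from hiercoop.analysis import fit_success_model

res = spe_full_game("earned", d=9)          # maximal rank gap, k = 1
print(res.offer_star, res.accept_star)      # -> 4 4
print(res.cont_high, res.cont_low)          # -> 36 4

records = generate_study(StudyDesign(master_seed=20151222))  # 24 sessions
fit = fit_success_model(records, n_boot=100, rng=np.random.default_rng(0))
print(fit.table.round(3))
```

The equilibrium offer at the maximal rank gap is 4 units (the responder's
expected lottery value 0.1 × 40), leaving continuation values of 36 vs 4.
The success-model table reports the logistic coefficients with bootstrap
CIs; the `h1` row is the no-hierarchy (+2) vs hierarchy (−1/−1) contrast, so
a positive `h1` means cooperation succeeds more often without a hierarchy.

The numbered drivers reproduce the full analysis narrative:

```bash
python analysis/01_simulate_study.py    # 24 sessions -> results/data/
python analysis/02_equilibrium_table.py # SPE for all treatments and rank gaps
python analysis/03_fit_models.py        # four bootstrap model families
python analysis/04_figure_tables.py     # figure-style summary tables
```

On the default seed, `01` reports cooperative success rates of 0.730
(control) vs 0.722/0.685 (earned/random hierarchy), and `04` reports mean
per-player successes of 6.57 vs 6.50/6.17 (of 9 possible) plus a positive
rank–earnings Spearman correlation (0.638) — higher-ranked players end up
with more. A `hiercoop` CLI (`simulate` / `spe` / `analyze` / `report` /
`config --dump-defaults`) wraps the same library for shell use.

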