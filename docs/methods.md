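# Methods

## Game model

One collective-risk game is played by `M` players over `R` rounds. Each
player starts with an endowment `E` (default `2R`) and in each round
invests an integer number of units, at most `c_max` per round and never
more than their remaining endowment. Deposits accumulate in a common pool.
After the last round the pool is compared with the collective target `T`
(default `M·E/2`, so each player's *fair share* is `E/2`). If the pool
falls short, each player's uninvested savings are lost with probability
`p`; payoffs are reported as expectations,

    π = E − c                 pool ≥ T
    π = (1 − risk)·(E − c)    otherwise,

where `risk` comes from the risk curve: the default `step` curve uses the
full `p` below the target and 0 at or above it; the optional `linear`
curve scales the risk with the relative shortfall,
`p·max(0, 1 − pool/T)`, so partial provisioning partially mitigates the
loss. A sampling mode (`GameConfig(sample_loss=True)`) draws the loss as a
per-game Bernoulli event instead; all summary statistics in this package
use the expected-payoff form, which has the same mean and less noise.

### Strategies

A strategy genome carries, for every round, a threshold `τ_r ∈ [0, 1]` and
two contribution levels. In round `r` a player invests its `above` level
if the current pool is **at or equal or above** `τ_r·T` and its `below`
level otherwise; the boundary counts as above. Thresholds are expressed as
fractions of the *announced* target: this keeps the comparison scale-free
in `M`, `R` and `c_max`, and under target uncertainty players only know
the nominal `T`. We also implemented and tested the alternative reading in
which `τ_r` is compared with the raw pool (so any nonzero pool exceeds any
threshold); it degrades the clean latest-possible-start structure of the
evolved behaviors and was rejected.

Conditioning is on the common pool only — players have no memory of
individual co-player actions, which matches settings where individual
monitoring is impractical.

## Evolutionary dynamics

A well-mixed population of `Z = 100` genomes evolves over non-overlapping
generations. Each generation `G = Z` games are played; each game's `M`
participants are drawn uniformly without replacement (independently across
games), so an individual plays `G·M/Z = M` games per generation on
average. An individual's payoff is the mean over the games it played; the
rare individual drawn into no game (probability ≈ 0.002 at the defaults)
receives the population mean payoff of that generation, which is selection
-neutral. If no games at all are played (`G = 0`) everyone receives 0,
again neutral under the exponential map.

Payoff maps to fitness as `f = exp(w·π)`. The next generation is drawn by
the Wright-Fisher process: `Z` offspring, each independently choosing a
parent with probability proportional to fitness (computed shift-invariant
to avoid overflow). Each offspring locus then mutates independently with
probability `μ`: thresholds receive Gaussian noise with SD `σ`, clamped to
`[0, 1]`; contribution loci are resampled uniformly from `{0..c_max}`
(possibly redrawing the parent's value). Initial populations draw every
contribution level uniformly from `{0..c_max}` and every threshold
uniformly from `[0, 1]`.

### Parameter defaults and calibration

| parameter | default | meaning |
|---|---|---|
| `Z` | 100 | population size |
| `G` | `Z` | games per generation |
| `w` | 0.4 | intensity of selection (per payoff unit) |
| `μ` | 0.01 | per-locus error probability |
| `σ` | 0.15 | threshold mutation SD (threshold units) |
| generations | 3000 | run length (summaries use all of it) |
| burn-in | 500 | generations excluded from long-run averages |

`w` and `μ` deserve comment, since the dynamics are sensitive to both.
With payoffs on the scale `0..E = 20`, `w ≳ 1` makes reproduction
winner-take-all (fitness ratios up to `e^20`): a single free-rider in a
successful group captures the next generation and coordination collapses.
Very small `w` lets mutation load swamp selection. Similarly `μ = 0.02`
over `3R = 30` loci mutates ~45% of offspring and keeps groups too
perturbed to hold the target reliably, while `μ ≥ 0.015` caps the
high-risk success fraction below 80%. The defaults `w = 0.4`, `μ = 0.01`
were calibrated jointly against the model's known phenomenology — payoff
collapse to `(1−p)E` at low risk, target success above 80% and mean
investment of half the endowment at high risk, and second-half
contribution timing — with `w` chosen at the largest value for which
high-risk cooperation established in every one of ten audit seeds:
cooperation at `p = 0.9` is bistable, and for `w ≥ 0.5` a growing fraction
of runs (1/10 at `w = 0.5`, ~1/4 at `w = 0.7`) falls permanently into the
defection basin within 2000 generations. All parameters are exposed in
`EvoConfig`.

One consequence is documented below: dominance of the *specific* latest
fair-share behavior (0022 in the four-round game) over its timing
variants (0202, 0112) is a second-order invasion-resistance effect that
only separates cleanly under stronger selection (`w ≈ 0.7`), where the
ten-round dynamics are no longer seed-robust. Under the defaults the
four-round mutation-selection balance concentrates on late fair-share
behaviors with an empty first round, with 0202 and 0022 as the two most
frequent.

## Behavioral statistics

A *behavior* is the realized per-round contribution sequence of one player
in one game; statistics are tallied per player-game, because a single
conditional strategy realizes different behaviors against different
co-players (selection acts on behaviors, inheritance on strategies).
Totals fall in four categories relative to the endowment: zero, under
(`0 < c < E/2`), fair (`c = E/2`), over (`c > E/2`). The number of
fair-share behaviors is computed by dynamic programming over bounded
integer compositions (19 for `R=4`, `c_max=2`). Contribution timing is
summarized by the second-half share of all units invested; for odd `R` the
first half is rounds `1..⌊R/2⌋`. Modal behaviors break ties toward the
lexicographically smallest sequence, for determinism.

## Stability assays

Homogeneous populations are seeded with `Z` copies of an *unconditional*
genome (both contribution levels equal to the focal behavior's round
value, threshold irrelevant) and evolved under the usual dynamics.
Persistence is the first generation at which fewer than `Z/2` individuals
still realize the focal behavior, right-censored at a generation cap.
Membership is judged on realized behavior — threshold loci drift neutrally
in unconditional genomes, so genome equality would undercount — read from
the first game an individual played that generation; unsampled individuals
count as still-focal. The packaged assay scale is `Z = 50`, cap 300, ≥ 20
replicates, which separates the five canonical ten-round behaviors
(all-zeros, all-twos, 0000022222, 1111111111, 2222200000) cleanly within
seconds.

## Variants

* **Interest** accrues on the pool at the start of rounds `2..R`, so a
  round-`r` deposit is worth `(1+ρ)^(R−r)` in the final pool and a
  last-round deposit accrues nothing — early investment is strictly more
  valuable whenever `ρ > 0`. Success compares the accrued pool to `T`.
  At `ρ = 0.25` an early unit outweighs a late one by `1.25^9 ≈ 7.5`, and
  evolved contribution timing flips into the first half of the game.
* **Target noise** draws the realized target once per game from
  `Normal(T, σ_T)` truncated at zero (implemented as clipping; the atom at
  zero is negligible for the sweep grid, `σ_T ≤ 0.1·T`). Players'
  thresholds still scale with the nominal `T`.
* **Cap sweep** varies `c_max` with `E` held at `2R`; the latest possible
  start of a fair-share schedule is `R − ⌈(E/2)/c_max⌉ + 1`.
* **Sequential play** (`R = M`, one mover per round, fresh uniform move
  order per game) widens the per-move range to `[0, E]`, since with a
  single move the usual per-round cap would make the target unreachable.

## Numerical and design notes

* All randomness flows from one `numpy` generator per run; replicate `k`
  of a sweep or assay reseeds as `seed + k`. Identical configuration and
  seed give bit-identical trajectories and byte-identical CSV output.
* Success is tested as `pool ≥ target − 10⁻⁹` to absorb float error when
  interest is on; with `ρ = 0` both sides are exact integers.
* Fitness weights are computed as `exp(w·(π − max π))`, which leaves
  Wright-Fisher probabilities unchanged and cannot overflow.
* Group sampling uses an argpartition of one uniform draw per (game,
  individual), i.e. a uniform random `M`-subset per game.

## What the simulations do and do not show

The generator *is* the study system — there is no external data. Passing
tests show that the implemented dynamics reproduce the model's
mutation-selection phenomenology at desk scale (a few thousand
generations, a few seeds); they say nothing about human behavior in
laboratory collective-risk experiments, which these games only stylize.

Three exact claims are known not to reproduce at desk scale under this
model and are left asserted-but-failing rather than weakened:

* With `c_max = 1`, meeting `T = 60` requires all 60 decisions in a group
  to be 1 simultaneously. The all-ones population is *stable* once
  established (homogeneous populations stay censored), but from random
  initialization there is no payoff gradient short of perfect
  coordination, and no transition was observed in runs up to 100 000
  generations (`Z = 100`) or in smaller populations (`Z = 20..50`,
  20 000 generations). The modal evolved behavior therefore remains
  all-zeros.
* With `c_max = 5`, evolved behaviors are late fair-share schedules (no
  units in the first half, most mass in rounds 8–10), but the strict
  latest-start pattern 0000000055 (first contribution in round 9) is not
  the mode: the per-cap behavior space is ~`6^10` and individual runs lock
  onto metastable late patterns such as 0000001153.
* In the four-round game at high risk the modal behavior is a late
  fair-share pattern, but under the seed-robust defaults it is 0202
  rather than 0022 (see the calibration note above).

The first two presumably require run lengths far beyond desk scale to
resolve; the third trades off against seed-robustness of the ten-round
dynamics.

Other limitations: no Moran or pairwise-comparison dynamics (Wright-Fisher
only), no population structure, no asymmetric endowments, no communication
beyond the pool itself, and integer contributions only.
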