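# kitepeck

Analysis of dynamic sibling-aggression networks and food allocation in
asynchronously hatching broods of three — the setting of facultatively
siblicidal raptors such as the red kite (*Milvus milvus*), where hatch order
creates an age-based dominance hierarchy and day-to-day food delivery shapes
who attacks whom and who gets fed.

The package is aimed at behavioural ecologists working with nest-camera
event logs: directed pecks (attacker → recipient), parental feeding bouts
and prey deliveries, recorded per second over a daily observation window.

## What it computes

**Tendency to peck.**  In a brood of three every attacker has two possible
targets, so random targeting implies each dyad's daily count has expectation
n/2 given the attacker's total n (Monte-Carlo permutation of recipients,
10 000 re-allocations by default; the Binomial(n, ½) closed form is the
built-in oracle).  The deviation

    tendency(a → r, day) = observed(a → r, day) − E_null[count]

is positive when a sibling is preferentially attacked and negative when
avoided.  Deviations are modelled smoothly against the signed age difference
Δ (negative = attacker older) and daily delivered biomass with a
phase-specific tensor-product penalized spline plus brood intercepts,
separately for attacker-older and attacker-younger dyads.  Uncertainty comes
from 100 bootstrap re-splits of 80% of the peck events; curves at the
minimum / median / maximum biomass are classified into *close-competitor*
(attack similar-aged peers, avoid much younger ones), *downward-heuristic*
(indistinguishable from random) or *bullying* (target the youngest only)
patterns.

**Food allocation.**  Which rank (S/M/J) receives each feeding bout is a
penalized multinomial logit with spline smoothers of daily biomass (k = 4),
of the daily log peck ratio ln(pecks received by M / pecks received by J)
(k = 3) — a proxy for the prevailing aggression pattern — and of the age of
the oldest nestling, plus brood intercepts.  Outputs are S/M/J share curves
(summing to 1) over biomass and over the log ratio.

**Synthetic broods.**  A seeded generator produces complete four-table
datasets with realistic hatching asynchrony, lognormal-AR(1) biomass,
phase-dependent Poisson peck rates and regime-dependent recipient choice, so
the whole pipeline is testable without field data.

## Worked example

```sh
kitepeck simulate --scenario paper_low_food --n-broods 12 --seed 7 --out demo/
kitepeck tendency --pecks demo/pecks.csv --bouts demo/bouts.csv \
    --deliveries demo/deliveries.csv --broods demo/broods.csv \
    --n-perm 500 --n-boot 25 --seed 42 --out demo/out
```

which prints the pattern labels of the attacker-older curves:

```json
{
  "phase1": {
    "max": "close_competitor",
    "median": "close_competitor",
    "min": "close_competitor"
  },
  "phase2": {
    "max": "close_competitor",
    "median": "close_competitor",
    "min": "close_competitor"
  }
}
```

The `paper_low_food` scenario simulates scarce food with aggression
concentrated on close-aged siblings, and the pipeline recovers exactly that:
at every food level the older attackers' tendency band is above zero toward
similar-aged targets and below zero at the largest age gaps.  Re-running
with `--scenario paper_high_food` (abundant food, random targeting) yields
`downward_heuristic` labels instead.  `demo/out/` also contains
`deviations.csv` (one row per directed dyad per brood-day), `curves.csv`
(mean and 95% band per side × phase × food level) and a run manifest; the
same dataset fed to `kitepeck allocation` produces S/M/J share curves, e.g.
a junior share rising from ≈ 13% of bouts under poor food to ≈ 34% under
favourable food.

The same functionality is available as a library:

```python
import kitepeck as kp
from kitepeck.simulate import default_weight_table

dataset = kp.generate_dataset(kp.make_scenario("paper_high_food"), seed=7)
result = kp.run_tendency_pipeline(dataset, default_weight_table())
print(result.patterns["phase1"])
```

Field data are ingested with `kp.load_dataset(pecks, bouts, deliveries,
broods)` from four CSVs (schemas in `kitepeck/data.py`); prey-category mean
masses are supplied as a YAML weight table (`--weights`).

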