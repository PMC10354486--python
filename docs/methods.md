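# Methods

`kitepeck` analyses within-brood aggression and food allocation in broods of
three asynchronously hatching nestlings (the motivating system is the red
kite, *Milvus milvus*, where eggs are laid roughly every 72 h and the junior
nestling can hatch up to 96 h after the middle one).  The package has four
statistical layers: a permutation null model for directed peck counts, smooth
regression of the resulting deviations, a multinomial model of feeding-bout
allocation, and a synthetic-brood generator that makes every stage testable
end to end.

## The tendency-to-peck statistic

For each brood-day the directed peck counts form a 3×3 table over the hatch
ranks S (senior), M (middle), J (junior), with a structurally zero diagonal.
In a brood of three an attacker has exactly two possible recipients, so a
null model of random targeting re-draws every peck's recipient uniformly from
those two siblings.  Under this null the permuted count for one recipient is
Binomial(n, ½) given the attacker's daily total n, hence the exact
expectation is n/2 per dyad.  `expected_counts_mc` implements the Monte-Carlo
version used in practice (default 10 000 re-allocations); the complementary
count is filled in as n minus the simulated mean, so observed attacker-day
totals are conserved exactly and the two deviations per attacker-day sum to
zero.  `expected_counts_analytic` is the closed form and serves as the
independent oracle: at P permutations the Monte-Carlo standard error of the
expected count is sqrt(n/4/P).

The *tendency to peck* (deviation) is the raw difference observed −
expected — positive when a target is preferentially attacked, negative when
avoided — joined per dyad-day with the signed age difference (hatch date of
attacker − hatch date of recipient, so negative means the attacker is
older), the day's delivered biomass and the phase.  Phase 1 covers junior
age 1–10 d, phase 2 ages 11–20 d; day 10 belongs to phase 1.  Zero-peck
brood-days inside a brood's observed span are recorded as zero-deviation
rows but excluded from model fitting by default (`--include-zero-days`
retains them); the field event logs are silent on how such days should enter
the models, so both paths are available.

## Smooth models and the bootstrap

Deviations are modelled as a Gaussian response with a phase-specific
tensor-product smooth over (age difference, biomass) plus a ridge-penalized
brood intercept, separately for attacker-older and attacker-younger dyads
(behaviour need not be continuous through Δ = 0; same-day hatchlings are
assigned by hatch order, the earlier rank to the attacker-older model).
Estimation is penalized least squares on cubic B-spline bases (5 basis
functions per margin) with order-2 difference penalties; smoothing
parameters are chosen by GCV on a small log grid.  Two deliberate additions
make the null case honest:

* **Null-space shrinkage.**  The difference penalty does not penalize
  plane-like surfaces, so pure noise can be fitted as a tilted plane that
  every bootstrap replicate reproduces.  A GCV-selected ridge on the whole
  surface (a "double penalty" in the Marra–Wood sense, with 0 in its grid)
  lets structureless data collapse to a flat zero surface while leaving
  strong signals untouched.
* **Subsampling correction.**  Uncertainty comes from refitting on 100
  random 80% subsets of the peck events.  Percentile bands of such
  fractional re-splits understate full-sample variability, because any two
  subsets share most of their events; the pipeline therefore stretches the
  percentile band around the bootstrap mean by sqrt(f/(1−f)) (= 2 at
  f = 0.8), the usual m-out-of-n subsampling scale factor.
  `predict_tendency_curves` itself defaults to the plain percentile rule.

Curves are reported per phase at the minimum, median and maximum daily
biomass over the modelled brood-days (poor / average / favourable food), on
an integer age-difference grid spanning the observed range per side.

### Pattern classification

Attacker-older curves are labelled with the three-way down-rank aggression
framework.  With `lo`/`hi` the 95% band at each grid point:

* `close_competitor` — band above 0 at every |Δ| ≤ 1 *and* below 0 at the
  most negative Δ (similar-aged peers targeted, the much younger sibling
  avoided);
* `downward_heuristic` — band covers 0 everywhere (indistinguishable from
  random targeting);
* `bullying` — band above 0 at the most negative Δ and nowhere else;
* `mixed` — anything else.

The rule is a deterministic reading of the curve geometry; it is deliberately
conservative in that a single stray exclusion sends the curve to `mixed`
rather than to one of the named patterns.

An optional sensitivity filter keeps only the opening peck of each dyadic
"battle": a peck is dropped when the nearest strictly earlier peck in the
same ordered dyad is less than `battle_gap_seconds` (default 60 s) before
it.  Event logs have 1 s resolution, so pecks sharing a timestamp are not
"earlier" and are retained.

## Food allocation

Each parental feeding bout goes to one rank.  The recipient is modelled as a
penalized multinomial logit (ridge; scikit-learn backend) with B-spline
smoothers of daily total biomass (basis dimension 4), of the daily log peck
ratio ln((pecks received by M + ½)/(pecks received by J + ½)) (dimension 3,
quadratic splines; the ½ is the Haldane–Anscombe constant for zero days),
and of the age of the oldest nestling (dimension 5), plus penalized brood
intercepts.  Bouts are only scored while the oldest nestling is ≤ 21 d old.
Predicted S/M/J shares sum to one by construction; share curves are reported
over the observed biomass range (log-ratio at its mean) and over the
observed log-ratio range (biomass at its mean), with a brood-day cluster
bootstrap supplying the uncertainty bands.  Prediction grids are clamped to
the observed covariate range with a warning rather than extrapolated.

## Biomass

Per delivery: the observer's visual mass estimate when present, otherwise
the category mean whole-item mass times the delivered fraction (1, ½, ¼;
missing fractions default to a whole item).  Category means are a required
configuration input (`weights.yaml`) because the underlying field
measurements are not distributed with the package; `unclassified` defaults
to the mean of the classified categories.  Daily biomass is the sum over a
brood-day's deliveries, zero when none were recorded.

## Synthetic broods

The generator encodes the study conditions the analysis assumes and is the
ground truth for the recovery tests:

* **Hatching**: S–M gap uniform on {0, 1, 2} days, M–J gap uniform on
  {1, …, 4} days (up to 96 h).
* **Biomass**: lognormal AR(1) (σ_log = 0.5, ρ = 0.3) with arithmetic means
  73.2 g/day in phase 1 and 120 g/day in phase 2; scenario presets scale
  these (×0.4 poor, ×1.6 favourable).
* **Pecking**: per-attacker daily Poisson rates (phase 1: S 170, M 32,
  J 1.4; phase 2: S 31.6, M 31, J 2.6) with a weak food coupling
  (biomass/phase-mean)^0.2.  These reproduce brood-day means of ≈ 203
  pecks/day in phase 1 and ≈ 65 in phase 2 and the dominance of the S→M
  dyad (two-thirds of phase-1 pecks with the default kernel decay
  τ = 1.75 d) — an order-of-magnitude calibration, not ground truth.
* **Recipient choice**: `close_competitor` picks siblings with probability
  ∝ exp(−|Δage|/τ); `downward_heuristic` is uniform over the permutation
  pool (both siblings), i.e. exactly the null the tendency statistic tests;
  `bullying` puts mass 1−ε on the youngest available target.
* **Feeding bouts**: daily count Poisson(0.8 × grams); the recipient is
  multinomial with S/M/J shares log-linearly interpolated (in log biomass)
  between anchors of (0.40, 0.47, 0.14) at 30 g, (0.50, 0.37, 0.13) at 90 g
  and (0.37, 0.29, 0.34) at 250 g, shifted on the logit scale by scenario
  regime and per-brood effects (sd 0.15).
* **Deliveries** carry observer masses that partition each day's generated
  grams, so re-estimated biomass reproduces the series exactly.

All randomness flows from a single seed through named substreams, so every
table is bitwise reproducible.  What the generator does *not* emulate:
behavioural overdispersion beyond Poisson/multinomial noise, winner–loser
dynamics or any day-to-day dependence of aggression beyond the biomass
autocorrelation, parental arrival processes within the day, or broods of
other sizes.  Passing recovery tests therefore demonstrate that the pipeline
identifies the generating structure under idealized noise, not that field
data meet these assumptions.

## Numerical choices and limitations

* GCV grids: surface smoothing {0.1, …, 10³} per phase, shrinkage
  {0, 0.01, 1, 100} × design scale, brood ridge {1, 100}; a ridge of
  10⁻⁷ × design scale guards the unpenalized null space.  A refit on
  identical data reproduces predictions to numerical tolerance.
* Percentiles use linear interpolation (numpy default); 95% bands are the
  2.5/97.5 pointwise percentiles.
* The observation window is half-open [08:00, 14:00) to avoid double
  counting at the boundary.
* Reduced-cost settings (e.g. 500 permutations, 25 bootstrap re-splits) are
  used in the test suite and acceptance runs; they widen Monte-Carlo
  tolerance but leave point estimates unbiased.
* Brood sizes other than three are out of scope: the two-recipient pool and
  its Binomial(n, ½) oracle are triad-specific.
* Bayesian credible intervals for individual model coefficients are not
  reproduced; uncertainty statements are bootstrap-based throughout.
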