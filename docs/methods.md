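# Methods

## Model structure

The simulation couples eleven stocks on a fixed monthly grid (default
t = 0…24 months, Euler step 0.25): safety culture `SC`; the safety
management system `SM` with sub-systems `SM1` (policy), `SM2`
(organizational structure) and `SM3` (procedures); individual safety
ability `SA` with components `SA1` (knowledge), `SA2` (awareness), `SA3`
(habits) and `SA4` (psychology); and the safe-acts level `UA`.  All stocks
are ratios in [0, 1] ("horizontal variable" HV = current level / maximum).

Four rate cores assemble every equation (all exponentials base 2):

| core | form | role |
|---|---|---|
| element uptake | `(1 − 2^(−S/80)) · 2^(−t/6)` | AV-driven inflow of SC, SM2, SM3, SA2, SA3, SA4 |
| knowledge uptake | `(1 − 2^(−S/80)) · 2^(−SA1)` | SA1 inflow, damped by its own level instead of time |
| layer uptake | `1.5 · (1 − 2^(−up/2)) · (1 − 2^(−W/n)) · 2^(−self)` | SC→SM and SM→SA transmission, through DELAY1(0.25) |
| acts / feedback | `(1 − 2^(−SA/2)) · 2^(−UA)` and `1 − 2^(−UA/4)` | UA inflow; delayed UA feedback on SC (delay 1), SM (0.5), SA (0.25) |

`S = Σ wᵢ·AVᵢ` is the weighted construction standard of the stock's element
group; `W` the weighted sum of the layer's sub-stocks (weights `d` for SM,
`h` for SA); `up` the upstream layer level.  The constants are readable as:
half-saturation of a standard at S = 80 out of 100; a six-month half-life of
construction effort; half-saturation of the upstream influence at up = 2 (so
the factor stays on the rising, nearly linear part of the curve over
[0, 1]); and a weak feedback with half-saturation at UA = 4.

## Parameters

* **Weights** — per-group proportions of cause elements among tallied
  accident causes.  Two groups are distributed as raw counts
  (culture categories 2:6:7:7, structure sub-elements 21:77:44) and are
  normalized exactly; the remaining six are available only as printed
  decimals and are used verbatim (each sums to 1 within 1e-3).
* **AV** (construction standard, 0–100): per-element; scenario code usually
  applies one value to all elements (default 60, experiments raise to 80).
* **HV** (initial safety level, 0–1): initial value of every stock; a new
  mine is HV = 0, production mines 0.25–0.75.
* **Delays** (months): culture feedback 1, management uptake 0.25, management
  feedback 0.5, ability uptake 0.25, ability feedback 0.25.

Integration is explicit Euler at dt = 0.25 by default (the conventional
system-dynamics default for this step size); dt is configurable, and a
step-halving check in the suite verifies first-order convergence (horizon-end
change < 0.01).  DELAY1 states initialize at steady state
(output(t0) = input(t0)); an `empty` option starts them at zero.  Stocks are
clamped to [0, 1] after each step, consistent with their definition as
ratios; `integrate()` accepts a `clamp` argument (including `None`) for
exploration of the unbounded variant.

## Structural ambiguities and the switches that expose them

The published equation list leaves several points open; each is implemented
as an explicit option so every run is auditable:

* `sm1` — no rate equation exists for safety policy.  Default `exogenous`:
  policy is pinned at AV/100 (a policy is promulgated, not accumulated),
  which makes policy the dominant management-system lever in new mines.
  Alternative `stock`: policy accumulates like the single-element habits
  stock; this reproduces the production-mine ordering *structure >
  procedures > policy*.
* `sa_damping` — the ability-layer uptake is damped by `2^(−SM)` as printed
  (`sm`, default) or by the symmetric `2^(−SA)` (`sa`).
* `ua_outflow` — no outflow of safe acts is printed (`none`, default); the
  `feedback` option adds a decay of the same form as the upper-layer
  feedback, letting UA fall as described qualitatively for production mines.
* `delay_init` — `steady` (default) or `empty`.

## What reproduces and what does not

With the default options the package reproduces: monotone growth of safe
acts in new mines; rise-then-fall of the three layers; culture peaks
monotone in the construction standard; *concept elements weakest* within the
culture layer; *knowledge first* within the ability layer (at production
levels; at HV = 0 the equations give negligible, slightly negative effects);
and *policy first* among management-system parts in new mines.

Two published findings are **not** reproducible from the equation list under
any documented option setting, and the corresponding acceptance checks are
expected to fail:

* the production-mine layer ordering *management system > ability >
  culture* in effect on safe acts.  Structurally, the only printed inflow of
  UA is `(1 − 2^(−SA/2))·2^(−UA)`, so the management system reaches safe
  acts only through the delayed SM→SA link while an ability-layer experiment
  lifts SA's sub-stocks directly; the time-averaged UA effect of ability
  therefore dominates at production levels.  At HV = 0.75 the unit-interval
  clamp saturates UA in every run and all effects vanish, so the claim that
  the gap widens with the safety level also fails.
* near-equality of the three management-system parts in production mines:
  with exogenous policy the policy experiment acts instantly and dominates
  by an order of magnitude (the `stock` alternative restores the published
  ordering but not near-equality).

Relatedly, the new-mine peak months (culture 13–14, management system 15–16,
ability 16–17) are not met on the unit-interval scale: at AV = 80 the
culture inflow (0.5/month) saturates the clamp by month ~2.3.  An unbounded
run (`clamp=None`, `sa_damping="sa"`) lands culture at 13.75 and ability at
16.5 with the management system at 16.25 — evidence that the original model
ran on an unnormalized scale — but the bounded scale is retained as the
package's definition of a level variable.  The peak-timing acceptance check
therefore searches the documented option space and, on a miss, reports it
and asserts the qualitative trend suite instead.

The influence metric itself is a package choice: the published record gives
only orderings, never a numeric definition of "degree of influence", so the
effect size is the time-averaged difference of the response stock over the
full horizon (a window option, e.g. months 10–18, is provided for
sensitivity checks).  Raising a "layer" raises the AVs of every element
feeding it (culture: the four category elements; management system: policy
plus the structure and procedure sub-elements; ability: the knowledge,
awareness and psychology sub-elements plus the habits element).

## Synthetic accident data

The weight-estimation input — a tally of cause elements over accident
investigations — is emulated per accident and element group as a
Poisson(3.0) number of cause occurrences allocated multinomially by the true
weight vector.  The mean of 3 causes per group per accident reflects that
investigation reports typically cite a handful of contributing causes at
each layer; the generator is exchangeable across accidents and carries no
between-cause correlation, over-dispersion, or reporting bias, so recovery
tests establish only that the ratio estimator is consistent under clean
multinomial sampling, not robustness to real investigation practice.
Estimation is exact proportion-taking per group; with 5 000 synthetic
accidents every weight entry is recovered within ±0.02, and the maximum
error shrinks from n = 84 to n = 5 000 in ≥ 95% of seeds.

## Numerical and interface choices

* Deterministic throughout; the only randomness is the synthetic generator's
  explicit seed (the CLI makes it mandatory).
* Peak = earliest grid argmax; trough = earliest argmin strictly after the
  peak, reported only when points after the peak exist.
* Trajectory CSVs are written in fixed 6-decimal format so identical runs
  are byte-identical; rankings are JSON `{factor, effect, rank}` lists; runs
  emit a manifest with the package version, seed and resolved options.
* The mapping of the four culture weight indices to the named categories
  (concept, discipline, responsibility, measures) is configurable
  (`a_category_map`); the default follows the listing order, with concept on
  the smallest weight.  The published tie *responsibility = discipline* is
  inconsistent with the printed weights (0.32 vs 0.27), so no mapping can
  reproduce it exactly.

## Limitations

* The model is a reconstruction from a printed equation list with garbled
  signs; the canonical reading (every uptake saturating, `1 − 2^(−x/d)`) is
  fixed, with the genuinely ambiguous points exposed as the options above.
* Constants (1.5, 80, 6, 4, 2) are taken as given; no calibration to data is
  provided or attempted.
* Scenario conclusions transfer to real mines only as far as the 24Model
  wiring and the published weights do; the package makes the machinery
  reproducible, not the sociology.
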