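# Methods

## Model

simplexcast forecasts a univariate, evenly spaced, complete series
y₁…y_T without a mechanistic model.  The state at time t is the delay
vector **v**_t = [y_{t−E+1}, …, y_t] (exactly E elements); the set of
all such vectors is the reconstructed state space.  A forecast from
origin t proceeds:

1. **Neighbor search.** Candidates are delay vectors at times tᵢ with
   E ≤ tᵢ, tᵢ ≠ t and tᵢ + tp ≤ t.  The last condition guarantees that
   every candidate's future vector **z**ᵢ = [y_{tᵢ+1}, …, y_{tᵢ+tp}] is
   fully observed *before* the origin, so mid-series forecasts are free
   of lookahead bias.  No further Theiler-style exclusion window is
   applied: vectors overlapping the query window remain eligible.  The n
   candidates with smallest Euclidean distance are kept; exact ties are
   broken by ascending tᵢ, making output deterministic.  If fewer than n
   candidates exist, all are returned with a logged warning — the tool
   is meant for exploration of short series, and hard failure would be
   unhelpful.
2. **Weighting.** wᵢ = exp(−θ·dᵢ/d̄), d̄ the mean distance over *enabled*
   neighbors.  θ = 0 gives all weights exactly 1.  When d̄ = 0 (every
   enabled neighbor is an exact repeat of the query) the expression is
   0/0; we define all weights as 1, the limit of equal distances, which
   makes forecasting of exactly periodic data well-defined.
3. **Simplex point forecast.** Per horizon step r,
   ŷ_{t+r} = Σᵢ wᵢ·zᵢ,ᵣ / Σᵢ wᵢ over enabled neighbors — a normalized
   weighted average, hence convex: every forecast lies within the range
   of the neighbors' values at that step.  Numerically the mean is
   computed anchored at one neighbor's value
   (z₀ + Σwᵢ(zᵢ − z₀)/Σw), which is algebraically identical but returns
   the shared value *exactly* when all neighbor futures coincide.
4. **Shaded forecast area.** Per step r a Gaussian kernel is centred on
   each enabled zᵢ,ᵣ:  Kᵢ,ᵣ(v) = s·wᵢ·f((v − zᵢ,ᵣ)/(α·q)), f the
   standard normal pdf.  K_r = Σᵢ Kᵢ,ᵣ is evaluated on a grid spanning
   [min zᵢ,ᵣ − α, max zᵢ,ᵣ + α] (kernels fall below the edge density c
   within ±α/2, so this covers them all) at 256 points per step by
   default.  Because s = 1/(f(0)·n), K_r ≤ Σwᵢ/n ≤ 1, and the opacity
   map is the identity clamped to [0, 1] — the simplest linear map with
   full opacity anchored at "all n neighbors agree with weight 1".
   s uses the *configured* n, not the enabled count, so disabling
   neighbors dims the area rather than renormalizing it.

## Kernel constants

- **q.** Defined so that α is the full width of the standardized kernel
  at density c: f(1/(2q)) = c, i.e. q = 1/(2·√(−2·ln(c·√(2π)))).  For
  the default c = 10⁻⁴, q ≈ 0.122784; the kernel's standard deviation in
  data units is α·q ≈ 0.123·α.  The unit test re-derives q by bracketed
  root finding on f(x) = c as an independent check of the closed form.
- **α.** α = σ_ref·kw with σ_ref the *sample standard deviation of the
  data observed up to the forecast origin* (the full series when
  forecasting from the end).  The reference scale σ is an
  implementation-defined choice; the series sd makes kw = 1 a
  data-scaled default, and restricting it to the prefix keeps mid-series
  forecasts strictly lookahead-free.  Constant series have σ_ref = 0 and
  require an explicit `alpha` override.
- **c** (default 10⁻⁴) is an arbitrarily low edge density; it only
  fixes what "width" means and has no visible effect at plotting
  resolution.

## Predictive pdf and scoring

K_r is a visual density, not a probability density.  For scoring, each
kernel integrates analytically to s·wᵢ·α·q, so
pdf(v) = K_r(v)/(s·α·q·Σwᵢ) is a proper Gaussian-mixture density
(component sd α·q).  CRPS is computed by trapezoidal quadrature of
(CDF(v) − 1{v ≥ obs})² on the step's grid, extended to cover the
observation and split at the observation to respect the discontinuity;
the quadrature is verified against the closed form for a Gaussian
observed at its mean, σ(√2 − 1)/√π.

## Rolling-origin evaluation

Origins default to every eligible step in the final third of the
series.  Per origin: simplex point forecast, kernel predictive pdf,
last-value naive, and seasonal naive (y at the same phase one period
earlier).  Point methods are scored by absolute error per horizon step,
the density by CRPS; scores are averaged per method per step.  The
evaluator rejects a seasonal period shorter than the horizon, because
the seasonal benchmark would then read observations after the origin.
These benchmark and metric choices reproduce a design intent (a sanity
comparison against "no change" baselines), not any published numbers.

## Synthetic exemplar

`gen_seasonal` emulates weekly all-cause mortality: T = 468 (nine years
of weeks), period 52, baseline 55,000 deaths/week, winter-peak amplitude
4,000 with sd-15% per-cycle multiplicative jitter (flu seasons of
varying severity), a +5/week drift (population growth), Gaussian
observation noise with sd 600, and an optional sustained +8,000 level
shift emulating a pandemic-style regime change that populates a new
region of phase space.  Values were chosen once to be plausible for
US-scale weekly mortality counts; the generator is *not* calibrated to
real surveillance data.  It reproduces the features the method relies
on — recurring seasonal shapes with varying amplitude, so nearby delay
vectors exist — but not reporting artefacts (revisions, holiday dips),
heteroskedastic counts, or genuine epidemic dynamics.  Passing tests on
it therefore demonstrate correctness of the algorithms, not forecast
skill on real mortality data.

`gen_logistic_map` (x_{t+1} = r·x_t·(1 − x_t), r = 3.9) supplies a
deterministic chaotic system on which short-horizon analog forecasting
has large, easily measurable skill over persistence.

## Numerical and design choices

- 1-based ordinal time indices in the data model (y₁…y_T); interfaces
  that expose arrays use ordinary 0-based numpy positions internally.
- Distances are computed vectorized over the candidate block; the test
  suite checks exact (t_i, d_i) agreement with an explicit per-element
  brute-force scan over hundreds of random configurations.
- Disabling a neighbor recomputes d̄ and all remaining weights over the
  enabled subset (disable → re-enable is an exact involution).
- Problem sizes in tests and the acceptance script (series of 50–468
  points, 100–200 random configurations, ~150 rolling origins) are
  chosen to exercise every code path at full fidelity while keeping the
  whole suite in the seconds range.
- Rendering asserts are made on the data handed to matplotlib
  (`DashboardData`), never on pixels; the colour ramps are
  implementation-defined, with only monotonicity in weight/opacity
  treated as contractual.

## Limitations

- Univariate embedding only; no S-map local-linear variant, no
  automatic hyperparameter selection.
- The method needs a well-populated state space: strong trends or
  regime shifts put the query vector in an empty region, and neighbors
  then resemble the present only superficially.  The phase-space panel
  makes this visible but the library does not detrend for you.
- Uneven spacing and missing values are rejected, not repaired.
- The shaded area is a weighted kernel sum, not a calibrated predictive
  distribution; the normalized pdf inherits the kernel-width choice α,
  so CRPS values depend on kw.
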