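# simplexcast

Interpretable, non-mechanistic forecasting of univariate time series by
**simplex projection** (empirical dynamic modeling, EDM), extended with a
weighted Gaussian-kernel **distributional forecast** — the "shaded
forecast area" — and a rolling-origin accuracy evaluator.  Built for
epidemiological surveillance series such as weekly all-cause mortality
counts, where forecasters need to see *why* a forecast looks the way it
does, not just its value.

## The method

Given an evenly spaced series y₁…y_T, the state at time t is the delay
vector **v**_t = [y_{t−E+1}, …, y_t].  The forecaster:

1. finds the *n* past delay vectors nearest (Euclidean) to the current
   one — the **nearest dynamic neighbors**, moments in the past whose
   recent dynamics most resemble the present;
2. weights each neighbor by wᵢ = exp(−θ·dᵢ/d̄), with dᵢ its distance and
   d̄ the mean neighbor distance (θ = 0 gives equal weights);
3. forecasts steps 1…tp as the weighted average of the neighbors'
   observed futures **z**ᵢ = [y_{tᵢ+1}, …, y_{tᵢ+tp}] (the simplex point
   forecast);
4. additionally sums, at each horizon step r, a Gaussian kernel centred
   on each zᵢ,ᵣ with height s·wᵢ·f(0) and width α in data units:
   K_r(v) = Σᵢ s·wᵢ·f((v − zᵢ,ᵣ)/(α·q)).  With s = 1/(f(0)·n) the kernel
   peaks sum to at most 1, so K_r maps directly onto an opacity gradient:
   the shaded forecast area, a visual predictive distribution that keeps
   *multiple* plausible futures visible where a point forecast would
   average them away.

α is the interval over which a kernel stays above a small edge density
c (default 10⁻⁴); q = 1/(2·√(−2·ln(c·√(2π)))) makes that definition
exact.  By default α = σ·kw with σ the sample standard deviation of the
series observed so far.

Neighbors can be disabled interactively (`set_neighbor_enabled`), which
removes them from d̄, the weights, the point forecast and the shaded
area — the library equivalent of right-clicking a neighbor in a
dashboard.

## Worked example

```python
from simplexcast import SimplexEDM, SyntheticSpec, gen_seasonal

ts = gen_seasonal(SyntheticSpec(seed=7))   # weekly mortality-like exemplar
res = SimplexEDM(ts, E=5, n=10, tp=8, theta=1.0).fit()
print(res.summary())
```

```
Simplex projection forecast
======================================================
observations: 468    origin t: 468
E=5  n=10  tp=8  theta=1.0  kw=1.0
kernel alpha=2826.6 (sigma_ref=2826.6, q=0.122784)
mean neighbor distance d_bar=1110.99

Neighbors
 t_i    distance   weight  enabled
 211  523.696402 0.624142     True
  56  767.599147 0.501118     True
 263  994.545476 0.408531     True
 ...
Forecast
 step   t     forecast  neighbor_min  neighbor_max
    1 469 57637.322492  56468.585814  58935.570995
    2 470 57960.253466  56727.646589  59135.511378
 ...
    8 476 59165.061104  57791.852774  61388.086444
```

The neighbor table shows *when* in the past the dynamics resembled the
present (weeks 211, 56, 263, … — the same phase of earlier winters) and
how much each contributes (weight).  The forecast column is the weighted
mean of those neighbors' futures; `neighbor_min`/`neighbor_max` bound it,
since a weighted mean is convex.  `res.density_grids` holds the shaded
area (per-step density/opacity), `res.predictive_pdf(step)` a proper
probability density for scoring, and `res.plot_dashboard("dash.png")`
renders the four-panel dashboard (series + forecast area, offset
neighbors, phase space, distance bars).

The same workflow is available from the shell:

```sh
simplexcast simulate --seed 7 --out series.csv
simplexcast forecast --input series.csv --out-point pf.csv
simplexcast evaluate --input series.csv --period 52
simplexcast plot --input series.csv --out dash.png
```

`evaluate` runs a rolling-origin comparison (MAE for point methods,
CRPS for the kernel density) against last-value and seasonal-naive
benchmarks, using only data available at each origin.

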