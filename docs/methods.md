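# Methods

## Scope and model

The package treats one question: under what conditions does a population
event train that is *not* internally critical produce the avalanche
statistics usually read as evidence of criticality? Three generators cover
the relevant space:

1. **Homogeneous Poisson process (HPP).** Independent Poisson(`r`) counts per
   bin. Only the product `r·Δt` matters, so all closed forms are written in
   events-per-bin units and bin-size dependence is explored by the `rebin`
   operation rather than by a second parameter.
2. **Inhomogeneous Poisson process (IPP).** Poisson counts with a per-bin
   rate envelope `r(t)` that varies slowly relative to avalanche durations:
   piecewise-constant epochs, a sinusoid `offset + amplitude·sin(t/T)`, or a
   tabulated vector.
3. **Driven branching process.** `A(t) = Σᵢ Yᵢ + h_t`: each of the `A(t−1)`
   active units activates each of `k = 2` targets with probability `q = σ/2`
   (so the offspring sum is a single `Binomial(2·A(t−1), σ/2)` draw), and a
   Bernoulli(`h`) drive seeds new cascades. For `σ < 1` the stationary mean
   rate is `h/(1−σ)`; all avalanche measures depend on the offspring family
   only through its mean `σ`.

Avalanches are maximal runs of non-empty bins bounded by empty bins
(half-open bins `[t, t+Δt)`, origin 0). Runs touching either end of the
recording lack a bounding empty bin; they are excluded and counted in
`n_discarded_boundary`.

## Closed forms and numerics

All PMFs are evaluated in log space. Stirling numbers of the second kind use
the additive recurrence `{s d} = d{s−1 d} + {s−1 d−1}` with `logaddexp`
accumulation (all terms positive), cached as a triangular table; the
alternating inclusion–exclusion sum is kept only as a small-`s` cross-check
because it cancels catastrophically beyond a few tens. The size PMF is also
cross-checked in the tests against an independent route that needs no
Stirling numbers, the ordered-set-partition identity
`Σ_d d!{s d} e^(−rd) = (1−x) Σ_k k^s x^k` with `x = 1/(1+e^r)`; the two agree
to 10⁻⁹ up to `s` of several hundred.

One consequence worth stating: the familiar exponential-tail description of
the size distribution, `P_S(s) ≈ λe^(−λs)` with
`λ = −ln r − 1 + B(s_c)` and `B(s) = s·ln ln s − (s+1)·ln ln(s+1)`, is
exposed (`hpp_tail_decay`) because its anchors — `B(1000) ≈ −2`, validity
bound `r < e^(B−1) ≈ 0.046` — are standard reference points. But the exact
tail of `P_S` decays with slope `−ln r + ln ln(1+e^r)` (from the generating
identity above; the `d!` growth moves the dominant duration from `s/ln s` to
≈ 0.72·s). The tests therefore validate the tail slope against the exact
route, and treat the `λ` form as the descriptive approximation it is.

`Q(x) = x(ln x + γ − Ei(x))/(1 − e^x)` is evaluated with `scipy.special.expi`
up to `x = 700` and by its asymptotic series `1 + 1/x + 2/x² + 6/x³` beyond
(the two branches agree to 10⁻⁴ at the seam). Empirically, `Q` averages
`A(i)/A(i−1)` over all consecutive pairs with `A(i−1) ≥ 1`, including pairs
whose current bin is empty. The Fano factor uses the population (1/N)
variance.

Rate superpositions integrate in the `μ = −ln(1−e^(−r))` coordinate, where
the superposition integrand becomes exactly `μ^(β−1) e^(−μd)` (the map is an
involution, `r(μ) = μ(r)` inverted by itself). Discrete rate sets are summed
exactly; continuous weightings use 256-node Gauss–Legendre quadrature in `μ`,
which matches the incomplete-gamma windowed form to machine precision over
`d ≤ 300`. Sampling from `w(r)` uses a trapezoid CDF on a 4096-point
log-spaced grid with interpolated inversion (KS distance to the quadrature
CDF ≈ 0.002 at 10⁵ draws).

## Conventions that were genuinely open

- **Event shuffling** redistributes all events uniformly over bins (one
  multinomial draw), not by permuting inter-event intervals: only the
  multinomial version turns an IPP into (conditioned) homogeneous Poisson
  counts, which is the property the control analysis needs.
- **Sub-bin timing does not exist** in binned data, so a bin with `a` events
  contributes `a − 1` zero inter-event intervals. Exponential-IEI
  comparisons are therefore made in sparse regimes (`r ≪ 1`), where the
  convention is immaterial.
- **IAI vs IEI**: the inter-avalanche interval is measured from the last
  non-empty bin of one avalanche to the first of the next, so IAI and IEI
  counts coincide for intervals > 2Δt except for up to two edge intervals
  affected by discarded boundary runs.
- **Mean avalanche shape** is reported only for durations with ≥ 20
  observations (configurable); below that the average profile is noise.
- **`s̄(d)`** uses the occupancy-corrected form `r·d/(1−e^(−r))`; the plain
  `r·d` is its large-`r` limit.
- **Piecewise envelopes renormalize**: the constructor takes raw rate ratios
  plus a target time-averaged mean (the four-rate reference process is
  `{1,2,5,10}` normalized to mean 1, i.e. `{1,2,5,10}/4.5`), because the
  ratios and the intended mean are the two things one actually wants to fix.
- **Power-law fits need explicit ranges.** The MLE of a truncated discrete
  power law is range-sensitive; defaults are `xmin = 1`,
  `xmax` = 95th percentile. Exponents carry the field's negative sign.
  Model comparison declares a preference only beyond 0.01 nats/sample.
- **No criticality score.** The report is a table of discriminators, not a
  classifier: a sufficiently contrived drive can mimic any passive
  statistic, so the output is meant to be read, not thresholded.

## Reference experiment sizes

The packaged experiments use the reference conditions throughout: four-rate
IPP epochs of 250,000 bins (10⁶ bins per run), sinusoidal drive with
`T = 250,000` bins run for 3·10⁶ bins, branching runs of 10⁷ steps at
`σ = 0.999`, `h = 0.001` with a 10⁵-step burn-in (≈ 100 mixing times at
`1/ε = 1000` steps), and three seeds per stochastic estimate. HPP reference
checks use 10⁶ bins, where Monte-Carlo error on the Fano factor is ≈ 0.0015
and on the empty-bin fraction ≈ 0.0005.

## What the generators do and do not emulate

The simulators generate the pooled population count series directly; unit
identities are never modeled, which matches the temporal-binning avalanche
definition (it pools channels anyway) but means subsampling and
coarse-sampling biases of real recordings are out of scope. Rate envelopes
are noiseless; real drives fluctuate within epochs. The branching process is
fully sampled and well mixed — observed `Q` maxima (≈ 250–500 at these
conditions, strongly seed-dependent because the statistic is an extreme over
bin sizes of a heavy-tailed ratio) would shrink under subsampling.
Consequently, passing tests demonstrate internal consistency of theory,
simulation, and measurement on fully observed processes, not robustness to
the observation effects of experimental data.

## Known limitations

- The MLE exponent of the four-rate duration distribution fitted on
  `d ∈ [1, 20]` is −1.75, not the tail slope −2: the `d ≤ 2` head of the
  mixture is flatter than `d^(−β)`. This is a property of the model, visible
  equally in the closed-form mixture and in simulation; fitting ranges that
  exclude the head recover steeper values.
- Continuous-mixture size PMFs cost one Stirling-table evaluation per
  quadrature node; very large `max_s` (≳ 2000) becomes memory-heavy
  (the table is O(max_s²)).
- `criticality_report` on very short series degrades to `inconclusive`
  model comparisons rather than failing; interpret accordingly.
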