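# avapoiss

Neuronal-avalanche statistics for Poisson and branching processes: simulation,
closed-form theory, and diagnostics that separate **apparent criticality**
(power-law-looking avalanche distributions produced by a slowly varying
external drive on non-interacting units) from **true criticality** (internal
near-critical branching dynamics).

## Who this is for

Researchers analyzing population event trains — spikes, LFP/EEG threshold
crossings, or any pooled point process — who extract avalanches by temporal
binning and want to know whether an observed power law is evidence of critical
dynamics or an artifact of a time-varying rate.

## The model

Pooled activity is a count series `A(t | Δt)`. An *avalanche* is a maximal run
of consecutive non-empty bins bounded by empty bins; its duration `d` is the
run length in bins and its size `s` the total event count.

For a homogeneous Poisson process (HPP) with rate `r` events/bin (only the
product `r·Δt` matters, so rate and bin size are interchangeable):

- empty-bin probability `p₀ = e^(−r)`; durations are geometric,
  `P_D(d) = e^(−rd)(e^r − 1)^(d−1)`, with decay constant
  `μ(r) = −ln(1 − e^(−r))`;
- per-bin counts inside an avalanche follow a zero-truncated Poisson,
  `P_A(a | a≥1) = r^a / ((e^r − 1) a!)`;
- sizes given duration involve Stirling numbers of the second kind,
  `P_S(s|d) = r^s d! {s d} / (s! (e^r − 1)^d)`, and
  `P_S(s) = Σ_d P_S(s|d) P_D(d)` — never a power law;
- the spike-count ratio obeys
  `Q(x) = x(ln x + γ − Ei(x))/(1 − e^x)` with `x = r·Δt`; the Fano factor is 1
  at every bin size.

A slowly varying inhomogeneous Poisson process (IPP) superposes these
rate-conditional laws. If rates occur with density
`w(r) ∝ μ(r)^(β−1) / ((1−e^(−r)) e^(−r))` on `[r₁, r₂]`, the superposed
durations follow a windowed power law
`P_D(d) ∝ d^(−β) [γ(β, d·μ(r₁)) − γ(β, d·μ(r₂))]` (lower incomplete gamma
cutoffs). Even crude rate envelopes — four discrete rates, or a slow sinusoid
— produce convincing size/duration power laws with exponents near −1.5 / −2,
the signature values of the driven branching process
`A(t) = Σᵢ Y_{i,t−1} + h_t` at `σ → 1`, which the package also simulates.

Because avalanche distributions alone cannot settle the question, the package
computes the discriminating battery as a function of bin size: `s̄(d)` scaling,
IEI/IAI distributions, count distribution, Fano factor, spike-count ratio
`Q(Δt)`, power spectrum, and the bin-size sensitivity of `P_S`/`P_D`.

## Worked example

```python
import avapoiss as ap
from avapoiss import analytics

# four-rate IPP: epochs of 250,000 bins at rates {1,2,5,10}/4.5 (mean 1)
env = ap.RateEnvelope.piecewise([1, 2, 5, 10], 250_000, mean_rate=1.0)
series = ap.simulate_ipp(env, 10**6, seed=1)
catalog = ap.extract_avalanches(series)
print(f"{catalog.n_avalanches} avalanches in {series.n_bins} bins")

size_fit = ap.fit_discrete_powerlaw(catalog.sizes, xmin=1, xmax=50)
print(f"size exponent: {size_fit.exponent:.2f}")
cmp = ap.compare_models(catalog.sizes, 1, 50)
print(f"preferred model: {cmp.preferred} (margin {cmp.margin:.3f} nats/sample)")

shuffled = ap.shuffle_events(series, seed=2)
cmp_sh = ap.compare_models(ap.extract_avalanches(shuffled).durations)
print(f"after shuffling: {cmp_sh.preferred} (margin {cmp_sh.margin:.3f} nats/sample)")

rep = ap.criticality_report(series, factors=(1, 2, 4),
                            size_range=(1, 50), duration_range=(1, 20))
print(f"sbar exponent: {rep.sbar_exponent:.2f}  q_max: {rep.q_max:.2f}"
      f"  fano(dt=1): {rep.fano_by_factor[1]:.2f}")
print(f"Q(x=1) analytic: {analytics.q_analytic(1.0):.3f}")
```

Output:

```
176632 avalanches in 1000000 bins
size exponent: -1.54
preferred model: powerlaw (margin 0.190 nats/sample)
after shuffling: exponential (margin -0.021 nats/sample)
sbar exponent: 1.12  q_max: 1.10  fano(dt=1): 1.61
Q(x=1) analytic: 0.767
```

Reading: the drive alone manufactures a −1.5 size power law over the fitted
range, and shuffling (which destroys the rate envelope) flips the preferred
model to exponential — yet the diagnostics give the game away: `s̄(d)` scales
with the trivial exponent ≈ 1, and `Q` stays near 1 at every bin size instead
of showing the large maximum of a near-critical branching process.

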