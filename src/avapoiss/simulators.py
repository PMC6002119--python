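"""Stochastic generators of binned population activity.

Three processes are covered:

* a homogeneous Poisson process (HPP) with constant rate ``r`` events/bin,
* an inhomogeneous Poisson process (IPP) whose rate follows a slowly varying
  envelope ``r(t)`` (piecewise-constant, sinusoidal, or tabulated),
* a driven branching process ``A(t) = sum_i Y_i + h_t`` with branching
  parameter sigma and Bernoulli(h) drive, the standard mechanistic model of
  activity propagation at or near criticality.

All rates are expressed in events per bin; rescaling time (the bin size) and
rescaling the rate are interchangeable for Poisson statistics, so physical
units are metadata only.  Every simulator takes an integer seed and is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .series import BinnedSeries

__all__ = [
    "RateEnvelope",
    "BranchingConfig",
    "RateWeighting",
    "simulate_hpp",
    "simulate_ipp",
    "simulate_branching",
    "shuffle_events",
    "sample_rates_from_weighting",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RateEnvelope:
    """Time-varying rate r(t), in events per bin.

    ``kind`` is one of ``constant``, ``piecewise``, ``sinusoid``,
    ``tabulated``.  Use the class methods rather than the constructor.
    """

    kind: str
    rate: float | None = None
    segments: tuple[tuple[float, int], ...] | None = None
    offset: float | None = None
    amplitude: float | None = None
    time_constant: float | None = None
    table: np.ndarray | None = None

    @classmethod
    def constant(cls, rate: float) -> "RateEnvelope":
        if rate < 0:
            raise ValueError("rate must be non-negative")
        return cls(kind="constant", rate=float(rate))

    @classmethod
    def piecewise(
        cls,
        rates: Sequence[float],
        n_bins_each: int | Sequence[int],
        mean_rate: float | None = None,
    ) -> "RateEnvelope":
        """Piecewise-constant envelope: each rate held for a long epoch.

        If ``mean_rate`` is given, the raw rates are rescaled so that the
        time-averaged rate equals it (epoch lengths taken into account).
        """
        rates = np.asarray(rates, dtype=float)
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")
        if np.isscalar(n_bins_each):
            lengths = np.full(rates.size, int(n_bins_each))
        else:
            lengths = np.asarray(n_bins_each, dtype=int)
        if (lengths < 1).any():
            raise ValueError("segment lengths must be >= 1")
        if lengths.size != rates.size:
            raise ValueError("rates and segment lengths must align")
        if mean_rate is not None:
            current = float(np.dot(rates, lengths) / lengths.sum())
            if current <= 0:
                raise ValueError("cannot renormalize an all-zero envelope")
            rates = rates * (mean_rate / current)
        segs = tuple((float(r), int(n)) for r, n in zip(rates, lengths))
        return cls(kind="piecewise", segments=segs)

    @classmethod
    def sinusoid(
        cls, offset: float = 1.0, amplitude: float = 1.0, time_constant: float = 250_000.0
    ) -> "RateEnvelope":
        """r(t) = offset + amplitude * sin(t / T), T in bins.

        The default is the slowly modulated drive ``sin(t/T) + 1`` with
        T = 250,000 bins: mean rate 1, full period 2*pi*T bins.
        """
        if offset - abs(amplitude) < 0:
            raise ValueError("envelope must be non-negative everywhere")
        if time_constant <= 0:
            raise ValueError("time_constant must be positive")
        return cls(
            kind="sinusoid",
            offset=float(offset),
            amplitude=float(amplitude),
            time_constant=float(time_constant),
        )

    @classmethod
    def tabulated(cls, rates: Sequence[float]) -> "RateEnvelope":
        rates = np.asarray(rates, dtype=float)
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")
        return cls(kind="tabulated", table=rates)

    def rates(self, n_bins: int) -> np.ndarray:
        """Materialize r(t) for bins 0..n_bins-1."""
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.kind == "constant":
            return np.full(n_bins, self.rate)
        if self.kind == "piecewise":
            vec = np.concatenate([np.full(n, r) for r, n in self.segments])
            if vec.size < n_bins:
                raise ValueError(
                    f"piecewise envelope covers {vec.size} bins < requested {n_bins}"
                )
            return vec[:n_bins]
        if self.kind == "sinusoid":
            t = np.arange(n_bins)
            return self.offset + self.amplitude * np.sin(t / self.time_constant)
        if self.kind == "tabulated":
            if self.table.size < n_bins:
                raise ValueError(
                    f"tabulated envelope covers {self.table.size} bins < {n_bins}"
                )
            return self.table[:n_bins]
        raise ValueError(f"unknown envelope kind {self.kind!r}")


@dataclass(frozen=True)
class BranchingConfig:
    """Driven branching process parameters.

    Each unit active at step t-1 activates each of ``k`` target units with
    probability ``q = sigma/k`` (default k=2), so the mean offspring count is
    sigma.  An external drive adds one seed event per step with probability
    ``h``.  For sigma < 1 the process is stationary with mean rate
    h / (1 - sigma) events per step.
    """

    sigma: float
    h: float
    n_steps: int
    k: int = 2
    step_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.k < 1 or self.sigma / self.k > 1:
            raise ValueError("offspring probability sigma/k must be <= 1")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")


@dataclass(frozen=True)
class RateWeighting:
    """Rate density w(r) ∝ mu(r)^(beta-1) / ((1-e^-r) e^-r) on [r1, r2].

    ``w(r)`` is the fraction of time an inhomogeneous Poisson process must
    spend at each rate r so that the superposition of the rate-conditional
    exponential avalanche-duration distributions approximates the power law
    d^-beta.  With mu(r) = -ln(1 - e^-r) it behaves like (1/r) ln(1/r) for
    r << 1 and is approximately constant for r > 1; it is not normalizable on
    (0, inf), hence the mandatory finite support [r1, r2].
    """

    beta: float = 2.0
    r1: float = 0.01
    r2: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.r1 < self.r2 < np.inf):
            raise ValueError(
                "need 0 < r1 < r2 < inf: w(r) ~ r^-1 ln(1/r) near 0 and is "
                "asymptotically constant, so it is not normalizable on an "
                "unbounded rate range"
            )

    def density(self, r) -> np.ndarray:
        """Unnormalized w(r); zero outside [r1, r2]."""
        from .analytics import rate_weight

        r = np.asarray(r, dtype=float)
        out = np.zeros(r.shape)
        ok = (r >= self.r1) & (r <= self.r2)
        out[ok] = rate_weight(r[ok], self.beta)
        return out

    def normalization(self) -> float:
        z, _ = quad(lambda r: float(self.density(r)), self.r1, self.r2, limit=200)
        return z


# ---------------------------------------------------------------------------
# simulators


def simulate_hpp(rate: float, n_bins: int, seed: int) -> BinnedSeries:
    """Homogeneous Poisson process: independent Poisson(rate) counts per bin."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    return BinnedSeries(rng.poisson(rate, n_bins))


def simulate_ipp(envelope: RateEnvelope, n_bins: int, seed: int) -> BinnedSeries:
    """Inhomogeneous Poisson process: bin t draws Poisson(r(t)).

    A constant envelope reproduces :func:`simulate_hpp` bit-for-bit under the
    same seed.
    """
    rates = envelope.rates(n_bins)
    if (rates < 0).any():
        raise ValueError("envelope yields negative rates")
    rng = np.random.default_rng(seed)
    return BinnedSeries(rng.poisson(rates))


def simulate_branching(config: BranchingConfig, seed: int) -> BinnedSeries:
    """Driven branching process, one count per time step.

    A(t) = Binomial(k * A(t-1), sigma/k) + h_t with h_t ~ Bernoulli(h): the
    offspring of the A(t-1) active units are independent Binomial(k, sigma/k)
    draws, whose sum is a single binomial draw.
    """
    rng = np.random.default_rng(seed)
    q = config.sigma / config.k
    n = config.n_steps
    drive = rng.random(n) < config.h
    counts = np.empty(n, dtype=np.int64)
    binomial = rng.binomial
    a = 0
    k = config.k
    for t in range(n):
        a = (binomial(k * a, q) if a else 0) + (1 if drive[t] else 0)
        counts[t] = a
    return BinnedSeries(counts, bin_size=config.step_duration)


def shuffle_events(series: BinnedSeries, seed: int) -> BinnedSeries:
    """Redistribute every event into a uniformly random bin.

    Total event count is conserved exactly; all rate correlations are
    destroyed, so a shuffled inhomogeneous Poisson process becomes (a
    conditioned version of) a homogeneous one.
    """
    rng = np.random.default_rng(seed)
    n = series.n_bins
    counts = rng.multinomial(series.total_events, np.full(n, 1.0 / n))
    return BinnedSeries(counts, series.bin_size, series.origin)


def sample_rates_from_weighting(
    weighting: RateWeighting, n: int, seed: int, grid_size: int = 4096
) -> np.ndarray:
    """Draw rates from the normalized w(r) by numeric inverse-CDF.

    The CDF is accumulated by the trapezoid rule on a log-spaced grid over
    [r1, r2] (w varies as 1/r near the lower bound, so log spacing keeps the
    quadrature error uniform), then inverted by interpolation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.geomspace(weighting.r1, weighting.r2, grid_size)
    if grid[-1] - grid[0] < 1e-12 * grid[0]:
        return np.full(n, weighting.r1)
    dens = weighting.density(grid)
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)
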