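"""Closed-form avalanche statistics for Poisson processes.

For a homogeneous Poisson process (HPP) with rate ``r`` events per bin, the
probability that a bin is empty is ``p0 = exp(-r)``.  Avalanches — maximal
runs of non-empty bins — then have

* geometric durations, ``P_D(d) = exp(-r d) (e^r - 1)^(d-1)``, with decay
  constant ``mu(r) = -ln(1 - e^-r)``;
* per-bin counts from a zero-truncated Poisson,
  ``P_A(a | a >= 1) = r^a / ((e^r - 1) a!)``;
* sizes distributed as a d-fold sum of truncated-Poisson counts, which brings
  in Stirling numbers of the second kind (the number of surjections of s
  events onto d non-empty bins).

The size distribution is *not* exponential: its tail decays like
``exp(-lambda s)`` with ``lambda = -ln r - 1 + B(s_c)`` where the doubly
logarithmic correction ``B(s) = s ln ln s - (s+1) ln ln(s+1)`` drifts so
slowly that it is treated as a constant over any decade of sizes.

Mixing HPP closed forms over a rate density ``w(r)`` gives the avalanche
statistics of a slowly varying inhomogeneous Poisson process; the particular
density ``w(r) ∝ mu(r)^(beta-1) / ((1-e^-r) e^-r)`` turns the superposed
exponential duration distributions into the power law ``d^-beta``, windowed
by lower-incomplete-gamma cutoffs when the rate support is bounded.

All PMF evaluation is done in log space; Stirling numbers come from the
additive recurrence with log-sum-exp accumulation (every term positive), not
from the alternating inclusion–exclusion sum, which cancels catastrophically
beyond s of a few tens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import expi, gammainc, gammaln, gamma as gamma_fn

from .series import DiscreteDistribution

EULER_GAMMA = float(np.euler_gamma)

__all__ = [
    "HppParams",
    "TailApprox",
    "HppSummaries",
    "MixtureResult",
    "mu_decay",
    "hpp_duration_pmf",
    "hpp_duration_pmf_at_iei_bin",
    "truncated_poisson_pmf",
    "log_stirling2",
    "hpp_size_given_duration_pmf",
    "hpp_size_pmf",
    "hpp_log_size_pmf",
    "slow_correction_b",
    "hpp_tail_decay",
    "hpp_summaries",
    "q_analytic",
    "rate_weight",
    "windowed_duration_pmf",
    "ipp_mixture",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class HppParams:
    """Rate of an HPP plus the derived bin-occupancy constants."""

    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("rate must be positive")

    @property
    def p_empty(self) -> float:
        return float(np.exp(-self.r))

    @property
    def p_occupied(self) -> float:
        return float(-np.expm1(-self.r))

    @property
    def mu(self) -> float:
        """Exponential decay constant of the duration distribution."""
        return mu_decay(self.r)


def mu_decay(r) -> np.ndarray | float:
    """mu(r) = -ln(1 - e^-r), strictly decreasing in r."""
    r = np.asarray(r, dtype=float)
    out = -np.log(-np.expm1(-r))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# HPP closed forms


def _check_positive_rate(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("rate must be positive")
    return r


def hpp_duration_pmf(d, r) -> np.ndarray | float:
    """P_D(d) = e^(-r d) (e^r - 1)^(d-1): geometric with ratio 1 - e^-r."""
    r = _check_positive_rate(r)
    d = np.asarray(d)
    if (d < 1).any():
        raise ValueError("duration must be >= 1")
    # log form: -r + (d-1) ln(1 - e^-r)
    out = np.exp(-r + (d - 1) * np.log(-np.expm1(-r)))
    return float(out) if out.ndim == 0 else out


def hpp_duration_pmf_at_iei_bin(d) -> np.ndarray | float:
    """Duration PMF at the canonical bin size Δt = <IEI> = 1/r (rate-free).

    Equals :func:`hpp_duration_pmf` at r = 1: (1/(e-1)) ((e-1)/e)^d.
    """
    return hpp_duration_pmf(d, 1.0)


def truncated_poisson_pmf(a, r) -> np.ndarray | float:
    """Zero-truncated Poisson: P(a | a >= 1) = r^a / ((e^r - 1) a!)."""
    r = _check_positive_rate(r)
    a = np.asarray(a)
    if (a < 1).any():
        raise ValueError("count must be >= 1")
    log_p = a * np.log(r) - np.log(np.expm1(r)) - gammaln(a + 1)
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Stirling numbers of the second kind, log space

_LOG_STIRLING: np.ndarray | None = None  # row s, column d -> ln {s d}


def log_stirling2(max_s: int) -> np.ndarray:
    """Table of ln {s d} for 0 <= d <= s <= max_s (-inf where {s d} = 0).

    Built by the additive recurrence {s d} = d {s-1 d} + {s-1 d-1} with
    logaddexp accumulation; cached and grown on demand.
    """
    global _LOG_STIRLING
    if _LOG_STIRLING is None or _LOG_STIRLING.shape[0] <= max_s:
        size = max_s + 1
        table = np.full((size, size), -np.inf)
        table[0, 0] = 0.0
        logd = np.log(np.arange(1, size))
        for s in range(1, size):
            prev = table[s - 1]
            table[s, 1:s + 1] = np.logaddexp(
                logd[: s] + prev[1 : s + 1], prev[0:s]
            )
        _LOG_STIRLING = table
    return _LOG_STIRLING


def hpp_size_given_duration_pmf(s, d, r: float) -> np.ndarray | float:
    """P_S(s | d) = r^s d! {s d} / (s! (e^r - 1)^d).

    The distribution of the sum of d independent zero-truncated Poisson
    counts; 0 for s < d (every bin holds at least one event).
    """
    r = float(_check_positive_rate(r))
    s = np.asarray(s)
    d = np.asarray(d)
    if (d < 1).any():
        raise ValueError("duration must be >= 1")
    if (s < 1).any():
        raise ValueError("size must be >= 1")
    s_b, d_b = np.broadcast_arrays(s, d)
    table = log_stirling2(int(s_b.max()))
    log_p = (
        s_b * np.log(r)
        + gammaln(d_b + 1)
        + table[s_b, d_b]
        - gammaln(s_b + 1)
        - d_b * np.log(np.expm1(r))
    )
    out = np.where(s_b >= d_b, np.exp(log_p), 0.0)
    return float(out) if out.ndim == 0 else out


def hpp_log_size_pmf(s, r: float) -> np.ndarray:
    """ln P_S(s) for the HPP, s scalar or array.

    P_S(s) = sum_{d=1..s} P_S(s|d) P_D(d)
           = (r^s / (s! (e^r - 1))) * sum_d d! {s d} e^(-r d).
    """
    r = float(_check_positive_rate(r))
    s = np.atleast_1d(np.asarray(s, dtype=np.int64))
    if (s < 1).any():
        raise ValueError("size must be >= 1")
    smax = int(s.max())
    table = log_stirling2(smax)
    dd = np.arange(smax + 1)
    inner = gammaln(dd + 1) - r * dd  # ln d! - r d
    out = np.empty(s.shape)
    from scipy.special import logsumexp

    for i, si in enumerate(s):
        terms = table[si, 1 : si + 1] + inner[1 : si + 1]
        out[i] = (
            si * np.log(r)
            - gammaln(si + 1)
            - np.log(np.expm1(r))
            + logsumexp(terms)
        )
    return out


def hpp_size_pmf(s, r: float) -> np.ndarray | float:
    """P_S(s) = sum_d P_S(s|d) P_D(d); non-monotonic for r > 2."""
    scalar = np.isscalar(s) or np.asarray(s).ndim == 0
    out = np.exp(hpp_log_size_pmf(s, r))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# exponential tail approximation


def slow_correction_b(s) -> np.ndarray | float:
    """B(s) = s ln ln s - (s+1) ln ln(s+1): the slowly drifting tail term."""
    s = np.asarray(s, dtype=float)
    if (s < 3).any():
        raise ValueError("s must be >= 3 for ln ln s to be positive")
    out = s * np.log(np.log(s)) - (s + 1) * np.log(np.log(s + 1))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TailApprox:
    """Exponential approximation P_S(s) ≈ lambda e^(-lambda s) of the size tail."""

    rate: float
    s_c: int
    b_value: float
    decay: float

    @property
    def valid(self) -> bool:
        """True iff lambda > 0, i.e. r < e^(B-1); only small rates qualify."""
        return self.decay > 0

    @property
    def rate_bound(self) -> float:
        """Largest rate for which the approximation is normalizable."""
        return float(np.exp(self.b_value - 1.0))


def hpp_tail_decay(r: float, s_c: int) -> TailApprox:
    """Tail decay lambda(r, s_c) = -ln r - 1 + B(s_c) of the HPP size PMF."""
    r = float(_check_positive_rate(r))
    if s_c < 3:
        raise ValueError("s_c must be >= 3")
    b = slow_correction_b(s_c)
    return TailApprox(rate=r, s_c=int(s_c), b_value=b, decay=-np.log(r) - 1.0 + b)


# ---------------------------------------------------------------------------
# summary moments


@dataclass(frozen=True)
class HppSummaries:
    mean_duration: float          # d-bar = e^r
    mean_size: float              # s-bar = r / ((1 - e^-r) e^-r)
    size_by_duration_slope: float # s-bar(d) / d = r / (1 - e^-r)
    avalanche_rate: float         # rho(r) = (1 - e^-r) e^-r avalanches per bin


def hpp_summaries(r: float) -> HppSummaries:
    """Mean duration, mean size, s̄(d) slope and avalanche rate of an HPP.

    The identity rho(r) * s-bar = r (events are conserved) holds exactly.
    """
    r = float(_check_positive_rate(r))
    p = -np.expm1(-r)
    rho = p * np.exp(-r)
    return HppSummaries(
        mean_duration=float(np.exp(r)),
        mean_size=r / rho,
        size_by_duration_slope=r / p,
        avalanche_rate=float(rho),
    )


# ---------------------------------------------------------------------------
# spike count ratio Q


def q_analytic(x) -> np.ndarray | float:
    """Q(x) = x (ln x + gamma - Ei(x)) / (1 - e^x) for x = r * Δt.

    The expected ratio of consecutive bin counts (previous bin non-empty) of
    an HPP.  Q rises from 0, crosses 1 near x ≈ 1.5, peaks near x ≈ 3.75 and
    returns to 1 from above as x -> inf.
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("x must be positive")
    out = np.empty(x.shape)
    small = x < 700.0
    xs = x[small]
    out[small] = xs * (np.log(xs) + EULER_GAMMA - expi(xs)) / (-np.expm1(xs))
    xl = x[~small]
    # Ei(x) ~ e^x/x (1 + 1/x + 2/x^2 + ...): Q -> 1 + 1/x + 2/x^2 + 6/x^3
    out[~small] = 1.0 + 1.0 / xl + 2.0 / xl**2 + 6.0 / xl**3
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# superposition of exponentials


def rate_weight(r, beta: float) -> np.ndarray | float:
    """Unnormalized rate density w(r) = mu(r)^(beta-1) / ((1-e^-r) e^-r).

    The fraction of time an IPP must spend at rate r for the superposed
    geometric duration distributions to follow d^-beta.  Behaves as
    (1/r) ln(1/r)^(beta-1) for r << 1 and (for beta = 2) tends to the
    constant 1 for r >> 1; either regime forbids normalization on an
    unbounded rate range.
    """
    r = _check_positive_rate(r)
    p = -np.expm1(-r)
    out = mu_decay(r) ** (beta - 1.0) / (p * np.exp(-r))
    return float(out) if np.ndim(out) == 0 else out


def windowed_duration_pmf(d, beta: float, r1: float, r2: float) -> np.ndarray | float:
    """Windowed power law d^-beta [gamma(beta, d mu(r1)) - gamma(beta, d mu(r2))].

    Unnormalized duration mass of an IPP whose rates follow w(r) on [r1, r2];
    the lower-incomplete-gamma factors impose smooth cutoffs on both ends of
    the d^-beta power law (the low rates cut the right tail, the high rates
    the small-d end).
    """
    if not 0 < r1 < r2:
        raise ValueError("need 0 < r1 < r2")
    d = np.asarray(d, dtype=float)
    if (d < 1).any():
        raise ValueError("duration must be >= 1")
    g = gamma_fn(beta)
    # gammainc is the regularized lower incomplete gamma P(beta, x)
    window = g * (gammainc(beta, d * mu_decay(r1)) - gammainc(beta, d * mu_decay(r2)))
    out = d ** (-beta) * window
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rate mixtures (IPP closed forms)


@dataclass(frozen=True)
class MixtureResult:
    """Avalanche statistics of a slowly varying IPP as a rate mixture of HPPs.

    ``size_pmf`` / ``duration_pmf`` are exact values on 1..max; they sum to
    slightly less than 1 because the support is truncated.
    """

    sizes: np.ndarray
    size_pmf: np.ndarray
    durations: np.ndarray
    duration_pmf: np.ndarray
    mean_size_by_duration: np.ndarray
    fano: float

    def size_distribution(self) -> DiscreteDistribution:
        return DiscreteDistribution.from_weights(self.sizes, self.size_pmf)

    def duration_distribution(self) -> DiscreteDistribution:
        return DiscreteDistribution.from_weights(self.durations, self.duration_pmf)


def _mixture_nodes(weighting, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a weighting to (rates, weights) quadrature nodes.

    Accepts a (rates, weights) tuple for a discrete mixture, or a
    RateWeighting, integrated by Gauss-Legendre in the mu = -ln(1-e^-r)
    coordinate, where the integrand is smooth (mu is an involution:
    r(mu) = -ln(1-e^-mu)).
    """
    if isinstance(weighting, tuple):
        rates, weights = (np.asarray(a, dtype=float) for a in weighting)
        if rates.shape != weights.shape:
            raise ValueError("rates and weights must align")
        if (rates <= 0).any() or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("rates must be positive and weights non-negative")
        return rates, weights / weights.sum()
    mu_lo, mu_hi = mu_decay(weighting.r2), mu_decay(weighting.r1)
    x, gw = np.polynomial.legendre.leggauss(n_nodes)
    mu = 0.5 * (mu_hi - mu_lo) * x + 0.5 * (mu_hi + mu_lo)
    gw = gw * 0.5 * (mu_hi - mu_lo)
    rates = mu_decay(mu)  # involution
    jac = -np.expm1(-rates) / np.exp(-rates)  # |dr/dmu|
    weights = gw * rate_weight(rates, weighting.beta) * jac
    return rates, weights / weights.sum()


def ipp_mixture(
    weighting,
    max_s: int = 200,
    max_d: int = 100,
    n_nodes: int = 256,
) -> MixtureResult:
    """Avalanche-rate-weighted mixture of HPP closed forms.

    ``weighting`` is either a ``(rates, weights)`` pair (discrete mixture of
    epochs, e.g. the four-rate IPP) or a :class:`~avapoiss.simulators.RateWeighting`
    (continuous density, integrated on ``n_nodes`` Gauss-Legendre nodes in mu).

    Avalanche distributions weight each rate by w(r) * rho(r) — epochs at
    higher rates contribute proportionally more avalanches — whereas the Fano
    factor of the bin counts is time-weighted:
    F = (<r> + <r^2> - <r>^2) / <r> under w alone.
    """
    rates, w = _mixture_nodes(weighting, n_nodes)
    rho = np.array([hpp_summaries(r).avalanche_rate for r in rates])
    u = w * rho
    u = u / u.sum()

    sizes = np.arange(1, max_s + 1)
    durations = np.arange(1, max_d + 1)

    size_pmf = np.zeros(max_s)
    dur_pmf = np.zeros(max_d)
    num_sbar = np.zeros(max_d)
    for ui, r in zip(u, rates):
        size_pmf += ui * np.exp(hpp_log_size_pmf(sizes, r))
        pd = hpp_duration_pmf(durations, r)
        dur_pmf += ui * pd
        num_sbar += ui * pd * durations * (r / -np.expm1(-r))
    mean_size_by_duration = num_sbar / dur_pmf

    r_mean = float(np.dot(w, rates))
    r_sq = float(np.dot(w, rates**2))
    fano = (r_mean + r_sq - r_mean**2) / r_mean
    return MixtureResult(
        sizes=sizes,
        size_pmf=size_pmf,
        durations=durations,
        duration_pmf=dur_pmf,
        mean_size_by_duration=mean_size_by_duration,
        fano=fano,
    )
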