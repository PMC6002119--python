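"""Empirical avalanche extraction and time-series measures.

An avalanche is a maximal run of consecutive non-empty bins, preceded and
followed by at least one empty bin.  Its duration ``d`` is the number of bins
in the run and its size ``s`` the total event count, so ``s >= d``.  Runs
touching the first or last bin lack a bounding empty bin and are discarded
(their number is reported).

Everything here is a function of the bin size Δt: :func:`rebin` coarsens a
series by an integer factor, and :func:`binsize_battery` repeats the whole
measure battery across factors, which is the empirical counterpart of the
rate/bin-size equivalence of Poisson statistics (r·Δt is the only relevant
product, so doubling Δt is the same as doubling r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .series import BinnedSeries, DiscreteDistribution, EMPTY_DISTRIBUTION

__all__ = [
    "Avalanche",
    "AvalancheCatalog",
    "AvalancheStats",
    "CountStats",
    "IntervalStats",
    "SpectrumSummary",
    "BinsizeDiagnostics",
    "DiagnosticsReport",
    "rebin",
    "extract_avalanches",
    "avalanche_distributions",
    "interval_distributions",
    "count_stats",
    "q_empirical",
    "power_spectrum",
    "binsize_battery",
]


@dataclass(frozen=True)
class Avalanche:
    """One avalanche: start bin index, duration in bins, size in events."""

    start_bin: int
    duration: int
    size: int
    profile: np.ndarray

    def __post_init__(self) -> None:
        profile = np.asarray(self.profile)
        if profile.size != self.duration or (profile < 1).any():
            raise ValueError("profile must have one >=1 entry per bin")
        if int(profile.sum()) != self.size:
            raise ValueError("profile must sum to size")


@dataclass(frozen=True)
class AvalancheCatalog:
    """Avalanches of one series at one bin size, as parallel arrays.

    ``starts``/``durations``/``sizes`` are aligned; profiles are recovered
    on demand from the source counts (kept by reference) to stay light for
    catalogs with millions of avalanches.
    """

    starts: np.ndarray
    durations: np.ndarray
    sizes: np.ndarray
    bin_size: float
    n_bins: int
    n_empty_bins: int
    n_discarded_boundary: int
    _counts: np.ndarray

    @property
    def n_avalanches(self) -> int:
        return int(self.starts.size)

    def __len__(self) -> int:
        return self.n_avalanches

    def profile(self, i: int) -> np.ndarray:
        s = int(self.starts[i])
        return self._counts[s : s + int(self.durations[i])]

    def __iter__(self):
        for i in range(self.n_avalanches):
            yield Avalanche(
                start_bin=int(self.starts[i]),
                duration=int(self.durations[i]),
                size=int(self.sizes[i]),
                profile=self.profile(i),
            )


def rebin(series: BinnedSeries, factor: int) -> BinnedSeries:
    """Merge ``factor`` adjacent bins; a trailing partial window is dropped."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return series
    n = (series.n_bins // factor) * factor
    if n == 0:
        raise ValueError("series shorter than one rebinned window")
    counts = series.counts[:n].reshape(-1, factor).sum(axis=1)
    return BinnedSeries(counts, series.bin_size * factor, series.origin)


def extract_avalanches(series: BinnedSeries) -> AvalancheCatalog:
    """Partition a series into avalanches (maximal non-empty runs)."""
    counts = series.counts
    occupied = counts > 0
    padded = np.concatenate([[False], occupied, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # one past the last bin of the run

    interior = (starts > 0) & (ends < series.n_bins)
    n_discarded = int((~interior).sum())
    starts, ends = starts[interior], ends[interior]

    cum = np.concatenate([[0], np.cumsum(counts)])
    return AvalancheCatalog(
        starts=starts,
        durations=ends - starts,
        sizes=cum[ends] - cum[starts],
        bin_size=series.bin_size,
        n_bins=series.n_bins,
        n_empty_bins=int((~occupied).sum()),
        n_discarded_boundary=n_discarded,
        _counts=counts,
    )


@dataclass(frozen=True)
class AvalancheStats:
    """Size/duration distributions, s̄(d), and mean temporal profiles."""

    size: DiscreteDistribution
    duration: DiscreteDistribution
    mean_size_by_duration: dict[int, float]
    mean_shape: dict[int, np.ndarray]


def avalanche_distributions(
    catalog: AvalancheCatalog, min_shape_count: int = 20
) -> AvalancheStats:
    """Empirical P_S(s), P_D(d), s̄(d) and mean shapes from a catalog.

    Mean shapes are reported only for durations observed at least
    ``min_shape_count`` times (below that the average profile is noise).
    An empty catalog yields empty distributions, not an exception.
    """
    if catalog.n_avalanches == 0:
        return AvalancheStats(EMPTY_DISTRIBUTION, EMPTY_DISTRIBUTION, {}, {})
    size = DiscreteDistribution.from_samples(catalog.sizes)
    duration = DiscreteDistribution.from_samples(catalog.durations)

    dur_values, inverse, dur_counts = np.unique(
        catalog.durations, return_inverse=True, return_counts=True
    )
    size_sums = np.bincount(inverse, weights=catalog.sizes)
    sbar = {int(d): float(t / c) for d, t, c in zip(dur_values, size_sums, dur_counts)}

    mean_shape: dict[int, np.ndarray] = {}
    for d, c in zip(dur_values, dur_counts):
        if c < min_shape_count:
            continue
        idx = np.flatnonzero(catalog.durations == d)
        offsets = catalog.starts[idx][:, None] + np.arange(d)[None, :]
        mean_shape[int(d)] = catalog._counts[offsets].mean(axis=0)
    return AvalancheStats(size, duration, sbar, mean_shape)


@dataclass(frozen=True)
class IntervalStats:
    """Inter-event (IEI) and inter-avalanche (IAI) interval distributions.

    Intervals are in time units (multiples of Δt).  Events inside one bin
    have no sub-bin timing: a bin with a events contributes a-1 zero IEIs.
    For any interval > 2Δt the IEI and IAI counts agree exactly — the IAI
    distribution is a left-truncated IEI distribution.
    """

    iei: DiscreteDistribution
    iai: DiscreteDistribution


def interval_distributions(
    series: BinnedSeries, catalog: AvalancheCatalog | None = None
) -> IntervalStats:
    if catalog is None:
        catalog = extract_avalanches(series)
    event_bins = np.repeat(np.arange(series.n_bins), series.counts)
    if event_bins.size >= 2:
        iei = DiscreteDistribution.from_samples(np.diff(event_bins) * series.bin_size)
    else:
        iei = EMPTY_DISTRIBUTION
    if catalog.n_avalanches >= 2:
        end_bins = catalog.starts[:-1] + catalog.durations[:-1] - 1
        gaps = (catalog.starts[1:] - end_bins) * series.bin_size
        iai = DiscreteDistribution.from_samples(gaps)
    else:
        iai = EMPTY_DISTRIBUTION
    return IntervalStats(iei=iei, iai=iai)


@dataclass(frozen=True)
class CountStats:
    """Per-bin count distribution P_A(a), Fano factor, and spike count ratio Q.

    Fano is the population variance of the counts over their mean (NaN for an
    all-zero series).  Q averages A(i)/A(i-1) over all consecutive pairs whose
    previous count is >= 1, including pairs whose current count is zero (NaN
    when no pair qualifies).
    """

    count_dist: DiscreteDistribution
    fano: float
    q: float


def q_empirical(series: BinnedSeries) -> float:
    """Spike count ratio Q = < A(i)/A(i-1) | A(i-1) >= 1 >."""
    c = series.counts
    prev, cur = c[:-1], c[1:]
    ok = prev >= 1
    if not ok.any():
        return float("nan")
    return float(np.mean(cur[ok] / prev[ok]))


def count_stats(series: BinnedSeries) -> CountStats:
    c = series.counts
    mean = c.mean()
    fano = float(c.var() / mean) if mean > 0 else float("nan")
    return CountStats(
        count_dist=DiscreteDistribution.from_samples(c),
        fano=fano,
        q=q_empirical(series),
    )


def power_spectrum(
    series: BinnedSeries, n_segments: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged periodogram of the mean-subtracted counts.

    Welch's method with non-overlapping rectangular windows; the DC bin is
    dropped so that flatness metrics can be taken directly on the result.
    Returns (frequencies in cycles per time unit, power).
    """
    if n_segments < 1 or series.n_bins < 2 * n_segments:
        raise ValueError("series must be at least twice n_segments long")
    nperseg = series.n_bins // n_segments
    freq, power = sp_signal.welch(
        series.counts.astype(float),
        fs=1.0 / series.bin_size,
        window="boxcar",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
    )
    return freq[1:], power[1:]


@dataclass(frozen=True)
class SpectrumSummary:
    """Low- vs high-frequency power contrast of the averaged periodogram."""

    freq: np.ndarray
    power: np.ndarray

    @property
    def low_high_ratio(self) -> float:
        """Mean power in the lowest decade over mean power in the highest.

        ~1 for a flat (Poisson) spectrum; >> 1 for a low-frequency-dominated
        (near-critical branching) spectrum.
        """
        f = self.freq
        low = f <= f[0] * 10
        high = f >= f[-1] / 10
        return float(self.power[low].mean() / self.power[high].mean())


@dataclass(frozen=True)
class BinsizeDiagnostics:
    """All measures of one series at one bin size Δt."""

    factor: int
    bin_size: float
    avalanche: AvalancheStats
    intervals: IntervalStats
    counts: CountStats
    spectrum: SpectrumSummary
    n_avalanches: int


@dataclass(frozen=True)
class DiagnosticsReport:
    """Measures per rebin factor; every entry is tagged with its Δt."""

    base_bin_size: float
    entries: dict[int, BinsizeDiagnostics]

    def __getitem__(self, factor: int) -> BinsizeDiagnostics:
        return self.entries[factor]


def _diagnose(series: BinnedSeries, factor: int, n_segments: int) -> BinsizeDiagnostics:
    catalog = extract_avalanches(series)
    return BinsizeDiagnostics(
        factor=factor,
        bin_size=series.bin_size,
        avalanche=avalanche_distributions(catalog),
        intervals=interval_distributions(series, catalog),
        counts=count_stats(series),
        spectrum=SpectrumSummary(*power_spectrum(series, n_segments)),
        n_avalanches=catalog.n_avalanches,
    )


def binsize_battery(
    series: BinnedSeries, factors, n_segments: int = 64
) -> DiagnosticsReport:
    """Run every measure at each rebin factor."""
    factors = [int(f) for f in factors]
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    entries = {
        f: _diagnose(rebin(series, f), f, n_segments) for f in factors
    }
    return DiagnosticsReport(base_bin_size=series.bin_size, entries=entries)
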