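"""Core containers: binned event series and discrete distributions.

The population activity of a set of recorded units is collapsed into a single
vector of event counts per time bin, ``A(t | Δt)``.  Every simulator and every
measure in this package produces or consumes such a :class:`BinnedSeries`;
probability mass functions over integer (or Δt-gridded) support are carried by
:class:`DiscreteDistribution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BinnedSeries:
    """Event counts per time bin.

    Parameters
    ----------
    counts
        Non-negative integer events per bin, one entry per bin.
    bin_size
        Width Δt of each bin in (arbitrary) time units.  Bins are half-open,
        ``[origin + i*bin_size, origin + (i+1)*bin_size)``.
    origin
        Start time of the first bin.
    """

    counts: np.ndarray
    bin_size: float = 1.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.bin_size > 0:
            raise ValueError("bin_size must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_rate(self) -> float:
        """Mean events per bin."""
        return float(self.counts.mean())

    def event_times(self) -> np.ndarray:
        """Event times, one per event, placed at the left edge of their bin.

        Binned data carry no sub-bin timing; events sharing a bin share a time.
        """
        idx = np.repeat(np.arange(self.n_bins), self.counts)
        return self.origin + idx * self.bin_size


@dataclass(frozen=True)
class DiscreteDistribution:
    """Normalized PMF over a strictly increasing support."""

    support: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support)
        probability = np.asarray(self.probability, dtype=float)
        if support.shape != probability.shape or support.ndim != 1:
            raise ValueError("support and probability must be 1-D and equal length")
        if support.size and (np.diff(support) <= 0).any():
            raise ValueError("support must be strictly increasing")
        if (probability < 0).any():
            raise ValueError("probabilities must be non-negative")
        if support.size and abs(probability.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probability", probability)

    @classmethod
    def from_samples(cls, samples) -> "DiscreteDistribution":
        values, counts = np.unique(np.asarray(samples), return_counts=True)
        return cls(values, counts / counts.sum())

    @classmethod
    def from_weights(cls, support, weights) -> "DiscreteDistribution":
        weights = np.asarray(weights, dtype=float)
        return cls(np.asarray(support), weights / weights.sum())

    @property
    def is_empty(self) -> bool:
        return self.support.size == 0

    def mean(self) -> float:
        return float(np.dot(self.support, self.probability))

    def pmf(self, x) -> np.ndarray:
        """Probability at the given support points (0 off support)."""
        x = np.atleast_1d(x)
        out = np.zeros(x.shape, dtype=float)
        idx = np.searchsorted(self.support, x)
        ok = (idx < self.support.size) & (np.take(self.support, idx, mode="clip") == x)
        out[ok] = self.probability[idx[ok]]
        return out

    def tv_distance(self, other: "DiscreteDistribution") -> float:
        """Total-variation distance, support union."""
        joint = np.union1d(self.support, other.support)
        return 0.5 * float(np.abs(self.pmf(joint) - other.pmf(joint)).sum())


EMPTY_DISTRIBUTION = DiscreteDistribution(np.array([]), np.array([]))
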