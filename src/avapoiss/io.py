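"""Plain-text readers and writers.

Formats
-------
* event times: one real per line, ``#`` comments; binned on read (half-open
  bins, origin 0).
* binned series: TSV ``bin_start<TAB>count`` with a ``# bin_size=`` header.
* distribution: TSV ``value<TAB>probability`` (also fits external two-column
  avalanche-distribution exports).
* report: a directory of distribution TSVs plus one JSON summary.

Every writer emits ``#``-prefixed metadata (tool version, seed if given, Δt)
so each file is self-describing.  Times are unitless reals; physical units
(ms, kHz, ...) are cosmetic metadata only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .series import BinnedSeries, DiscreteDistribution


class EmptyInputError(ValueError):
    """The input file contains no usable rows."""


class FormatError(ValueError):
    """A line could not be parsed; the message carries the line number."""


def _data_lines(path):
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def read_events(path, format: str = "binned-tsv", bin_size: float | None = None) -> BinnedSeries:
    """Read a series from disk.

    ``format='event-times'`` expects one event time per line and requires
    ``bin_size``; times are binned half-open from origin 0.
    ``format='binned-tsv'`` expects ``bin_start<TAB>count`` rows and honours a
    ``# bin_size=`` header (argument overrides header; default 1).
    """
    if format == "event-times":
        if bin_size is None or bin_size <= 0:
            raise ValueError("event-times format requires a positive bin_size")
        times = []
        for lineno, line in _data_lines(path):
            try:
                t = float(line)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not a number: {line!r}") from exc
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative event time {t}")
            times.append(t)
        if not times:
            raise EmptyInputError(f"{path}: no events")
        idx = np.floor(np.asarray(times) / bin_size).astype(np.int64)
        return BinnedSeries(np.bincount(idx), bin_size=bin_size)

    if format == "binned-tsv":
        header_bin = _header_value(path, "bin_size")
        counts = []
        for lineno, line in _data_lines(path):
            parts = line.split()
            try:
                counts.append(int(float(parts[-1])))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: bad row: {line!r}") from exc
        if not counts:
            raise EmptyInputError(f"{path}: no bins")
        return BinnedSeries(np.asarray(counts), bin_size=bin_size or header_bin or 1.0)

    raise ValueError(f"unknown format {format!r}")


def _header_value(path, key: str) -> float | None:
    for raw in Path(path).read_text().splitlines():
        if not raw.startswith("#"):
            break
        body = raw.lstrip("# ").strip()
        if body.startswith(f"{key}="):
            return float(body.split("=", 1)[1])
    return None


def _metadata_header(metadata: dict | None) -> str:
    from . import __version__

    meta = {"tool": f"avapoiss {__version__}"}
    meta.update(metadata or {})
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_series(series: BinnedSeries, path, metadata: dict | None = None) -> None:
    """Write a series as ``bin_start<TAB>count`` TSV with metadata header."""
    meta = {"bin_size": series.bin_size, "origin": series.origin}
    meta.update(metadata or {})
    starts = series.origin + np.arange(series.n_bins) * series.bin_size
    body = "".join(f"{t:.12g}\t{c}\n" for t, c in zip(starts, series.counts))
    Path(path).write_text(_metadata_header(meta) + body)


def write_event_times(series: BinnedSeries, path, metadata: dict | None = None) -> None:
    """Write one event time per line (left bin edge per event)."""
    body = "".join(f"{t:.12g}\n" for t in series.event_times())
    Path(path).write_text(_metadata_header(metadata) + body)


def write_table(records, path, metadata: dict | None = None) -> None:
    """Write a list of mappings as TSV with a ``#`` metadata header.

    Field order follows the first record; all records must share its keys.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    keys = list(records[0])
    lines = ["\t".join(keys)]
    for rec in records:
        lines.append("\t".join(_fmt(rec[k]) for k in keys))
    Path(path).write_text(_metadata_header(metadata) + "\n".join(lines) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.12g}"
    return str(v)


def write_distribution(dist: DiscreteDistribution, path, metadata: dict | None = None) -> None:
    write_table(
        [{"value": _num(v), "probability": float(p)} for v, p in zip(dist.support, dist.probability)],
        path,
        metadata,
    )


def _num(v):
    f = float(v)
    return int(f) if f.is_integer() else f


def read_distribution(path) -> DiscreteDistribution:
    """Generic two-column (value, probability-or-count) reader; renormalizes."""
    values, weights = [], []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns: {line!r}")
        if not values and _is_header(parts):
            continue  # column-name header row
        try:
            values.append(float(parts[0]))
            weights.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad row: {line!r}") from exc
    if not values:
        raise EmptyInputError(f"{path}: no rows")
    order = np.argsort(values)
    return DiscreteDistribution.from_weights(
        np.asarray(values)[order], np.asarray(weights)[order]
    )


def _is_header(parts) -> bool:
    try:
        float(parts[0])
        return False
    except ValueError:
        return True


def write_report(report, out_dir, metadata: dict | None = None) -> None:
    """Serialize a DiagnosticsReport as a directory of TSVs + JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"base_bin_size": report.base_bin_size, "factors": {}}
    for factor, entry in report.entries.items():
        tag = f"factor{factor}"
        meta = {"bin_size": entry.bin_size, "rebin_factor": factor}
        meta.update(metadata or {})
        av = entry.avalanche
        if not av.size.is_empty:
            write_distribution(av.size, out / f"size_{tag}.tsv", meta)
            write_distribution(av.duration, out / f"duration_{tag}.tsv", meta)
            write_table(
                [{"duration": d, "mean_size": s}
                 for d, s in sorted(av.mean_size_by_duration.items())],
                out / f"mean_size_by_duration_{tag}.tsv",
                meta,
            )
        if not entry.intervals.iei.is_empty:
            write_distribution(entry.intervals.iei, out / f"iei_{tag}.tsv", meta)
        if not entry.intervals.iai.is_empty:
            write_distribution(entry.intervals.iai, out / f"iai_{tag}.tsv", meta)
        write_distribution(entry.counts.count_dist, out / f"counts_{tag}.tsv", meta)
        write_table(
            [{"frequency": f, "power": p}
             for f, p in zip(entry.spectrum.freq, entry.spectrum.power)],
            out / f"spectrum_{tag}.tsv",
            meta,
        )
        summary["factors"][str(factor)] = {
            "bin_size": entry.bin_size,
            "n_avalanches": entry.n_avalanches,
            "fano": entry.counts.fano,
            "q": entry.counts.q,
            "spectrum_low_high_ratio": entry.spectrum.low_high_ratio,
        }
    if metadata:
        summary["metadata"] = {k: str(v) for k, v in metadata.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
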