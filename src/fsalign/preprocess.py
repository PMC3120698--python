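"""Model-dependent raw transform, per-channel normalisation and trimming.

Fragment-analysis runs with strong and weak signal must be brought onto
a common intensity scale before they can be aligned scan-by-scan.  Each
dye channel is normalised individually: the channel mean (``avg_all``)
is computed, the noise level is estimated as the mean of all points
strictly below that mean, points below the noise level are zeroed, and
the remaining signal points are divided by ``(avg_all - noise) /
optimal_value`` so the average data signal lands on the user-chosen
optimum.  Blank trace is then removed: the start is the first qualifying
peak of channel 1 (or, in 25-plex mode, the first occurrence of the
configured leading-peak pattern), and trailing scans where every data
channel is below the end threshold are dropped.  The reference trace
guides the target's start search by bounding it to a window past the
reference start, which keeps spurious noise spikes ahead of the real
data from hijacking the start point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .trace_io import TraceRecord

#: Optimal-value choices offered at the CLI surface; the library accepts any positive value.
STANDARD_OPTIMAL_VALUES = (50, 100, 200, 400, 800)


@dataclass(frozen=True)
class ChannelStats:
    """Noise and scaling statistics of one dye channel (intensity units)."""

    avg_all: float
    noise: float
    avg_signal: float
    scale_factor: float


@dataclass
class PreprocessConfig:
    optimal_value: float = 200.0
    multiplex25: bool = False
    end_trim_threshold: float = 50.0
    start_search_window: int = 200

    def __post_init__(self) -> None:
        if self.optimal_value <= 0:
            raise ValueError("optimal_value must be positive")
        if self.end_trim_threshold < 0 or self.start_search_window < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class PatternEntry:
    channel: int  # 1-based dye channel index
    min_height: float  # minimum normalised peak height
    max_gap: int | None = None  # maximum scans to the next entry's peak


@dataclass
class PeakPattern:
    """Expected leading peaks of a multiplex system, in scan order."""

    entries: list[PatternEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pattern must have at least one entry")
        for e in self.entries:
            if not 1 <= e.channel <= 4:
                raise ValueError(f"pattern channel {e.channel} outside 1-4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeakPattern":
        doc = yaml.safe_load(Path(path).read_text())
        entries = [
            PatternEntry(int(e["channel"]), float(e["min_height"]), e.get("max_gap"))
            for e in doc["entries"]
        ]
        return cls(entries)

    @classmethod
    def default_25plex(cls) -> "PeakPattern":
        ref = resources.files("fsalign").joinpath("data/pattern_25plex.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def channel_stats(channel: Sequence[float], optimal_value: float) -> ChannelStats:
    """Per-channel mean, noise estimate, average data signal and scale factor.

    Noise is the mean of all points strictly below the channel mean;
    for a flat channel that subset is empty and noise is 0.
    """
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0:
        raise ValueError("empty channel")
    avg_all = float(arr.mean())
    below = arr[arr < avg_all]
    noise = float(below.mean()) if below.size else 0.0
    avg_signal = avg_all - noise
    return ChannelStats(avg_all, noise, avg_signal, avg_signal / optimal_value)


def normalise_channel(channel: Sequence[float], stats: ChannelStats) -> np.ndarray:
    """Zero sub-noise points, scale the rest so mean signal hits the optimum."""
    arr = np.asarray(channel, dtype=float)
    if stats.scale_factor == 0:
        warnings.warn("flat channel: scale factor zero, returning zeros", stacklevel=2)
        return np.zeros_like(arr)
    return np.where(arr < stats.noise, 0.0, arr / stats.scale_factor)


def normalise_record(
    record: TraceRecord, config: PreprocessConfig
) -> tuple[TraceRecord, list[ChannelStats]]:
    """Normalise the four data channels; channel 5 (raw ladder) is untouched."""
    channels = list(record.channels)
    stats = []
    for i in range(4):
        st = channel_stats(channels[i], config.optimal_value)
        channels[i] = normalise_channel(channels[i], st)
        stats.append(st)
    return replace(record, channels=channels), stats


# Hooks for instrument models whose raw stream embeds control values; the
# concrete layout is vendor-internal, so the default is a pass-through.
CONTROL_NUMBER_HOOKS: dict[str, Callable[[TraceRecord], TraceRecord]] = {}


def raw_transform(record: TraceRecord) -> TraceRecord:
    """Model-dependent raw-data correction.

    The 310 model stores spectrally mixed dye signals; its channels are
    unmixed by multiplying each scan's channel vector by the file's
    matrix (identity with a warning when no matrix is stored), clamping
    negative results to zero.  Other known models pass through a
    pluggable control-number hook (no-op by default); an unknown model
    passes through unchanged with a warning.
    """
    model = (record.model or "unknown").strip()
    if model == "unknown":
        warnings.warn("unknown instrument model: raw data passed through unchanged", stacklevel=2)
        return record
    if model == "310":
        mat = record.matrix
        if mat is None:
            warnings.warn("310 trace without spectral matrix: identity assumed", stacklevel=2)
            return record
        k = mat.shape[0]
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or k > len(record.channels) or k < 4:
            raise ValueError(f"bad matrix: shape {mat.shape} for {len(record.channels)} channels")
        stacked = np.stack([np.asarray(c, dtype=float) for c in record.channels[:k]])
        unmixed = np.clip(mat @ stacked, 0.0, None)
        channels = [np.rint(row).astype(np.int32) for row in unmixed] + list(record.channels[k:])
        return replace(record, channels=channels)
    hook = CONTROL_NUMBER_HOOKS.get(model)
    if hook is not None:
        return hook(record)
    return record


def local_peaks(values: Sequence[float], min_height: float) -> np.ndarray:
    """Scan indices of local maxima with value >= min_height.

    A peak is a scan whose value is >= both neighbours; a plateau counts
    once, at its first scan.  Edge scans are compared against their one
    existing neighbour.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.array([], dtype=int)
    left = np.concatenate(([-np.inf], v[:-1]))
    right = np.concatenate((v[1:], [-np.inf]))
    return np.flatnonzero((v >= min_height) & (v > left) & (v >= right))


def find_start_generic(record: TraceRecord, config: PreprocessConfig | None = None) -> int:
    """First qualifying peak of channel 1 = the data starting point."""
    config = config or PreprocessConfig()
    peaks = local_peaks(record.channels[0], config.end_trim_threshold)
    if peaks.size == 0:
        raise ValueError("no start peak found")
    return int(peaks[0])


def find_start_25plex(record: TraceRecord, pattern: PeakPattern) -> int:
    """Scan position of the earliest occurrence of the leading-peak pattern.

    Each pattern entry must be matched by a peak on its channel, in
    order, each at most ``max_gap`` scans after the previous match.
    """
    entry_peaks = [
        local_peaks(record.channels[e.channel - 1], e.min_height) for e in pattern.entries
    ]
    for p0 in entry_peaks[0]:
        pos = int(p0)
        ok = True
        for j in range(len(pattern.entries) - 1):
            gap = pattern.entries[j].max_gap
            candidates = entry_peaks[j + 1]
            nxt = candidates[(candidates > pos) & ((candidates - pos <= gap) if gap is not None else True)]
            if nxt.size == 0:
                ok = False
                break
            pos = int(nxt[0])
        if ok:
            return int(p0)
    raise ValueError("pattern not found")


def find_start_target(
    reference_start: int,
    target: TraceRecord,
    config: PreprocessConfig,
    pattern: PeakPattern | None = None,
) -> int:
    """Start search on the target, bounded by the reference start.

    Only scans up to ``reference_start + start_search_window`` are
    examined, so noise peaks far ahead of the real data cannot win.
    """
    limit = reference_start + config.start_search_window
    windowed = replace(target, channels=[c[: limit + 1] for c in target.channels])
    try:
        if pattern is not None:
            return find_start_25plex(windowed, pattern)
        return find_start_generic(windowed, config)
    except ValueError:
        raise ValueError("no start peak in window") from None


def trim(record: TraceRecord, start: int, config: PreprocessConfig | None = None) -> TraceRecord:
    """Drop scans before ``start`` and the trailing all-blank suffix.

    A scan belongs to the blank suffix when every data channel (1-4) is
    strictly below ``end_trim_threshold``; a scan with any channel at or
    above the threshold stops the trimming.  Channel 5, when present, is
    sliced identically so channels stay in register.  The removed span
    is recorded in ``trim_span`` (original coordinates).
    """
    config = config or PreprocessConfig()
    n = record.n_scans
    if not 0 <= start < n:
        raise ValueError(f"start {start} outside trace of {n} scans")
    data = np.stack([np.asarray(c, dtype=float) for c in record.channels[:4]])
    blank = np.all(data < config.end_trim_threshold, axis=0)
    loud = np.flatnonzero(~blank)
    end = int(loud[-1]) + 1 if loud.size else 0
    if end <= start:
        raise ValueError("trace entirely blank")
    return replace(
        record,
        channels=[c[start:end] for c in record.channels],
        trim_span=(start, end),
    )
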