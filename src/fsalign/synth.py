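"""Synthetic electropherogram generator with known ground truth.

Real primer-extension multiplex traces are dense rows of partially
overlapping Gaussian-shaped peaks over a low noise floor, with a ladder
of size-standard peaks in a fifth channel and, occasionally, a voltage
spike ahead of the real data.  This module builds such traces
declaratively so every processing stage can be tested without sequencer
data: a :class:`SyntheticSpec` lists per-channel peaks, baseline noise,
the ladder, an optional leading artifact spike, and a list of local
time-warp distortions (duplicated or dropped scans) used to derive a
target trace from a reference.

What the generator does NOT emulate: microsatellite stutter (such traces
are unsuitable input for this alignment in the first place), dye
spectral bleed-through, and smooth continuous mobility drift -- warps
here are discrete single-scan events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .trace_io import DEFAULT_DYE_NAMES, TraceRecord

Peak = tuple[float, float, float]  # (apex scan, height, width in scans)


@dataclass
class SyntheticSpec:
    """Declarative description of a reference/target trace pair."""

    length: int = 1600
    peaks: dict[int, list[Peak]] = field(default_factory=dict)  # 1-based channel -> peaks
    noise_sd: float = 2.0
    ladder: list[tuple[float, float]] = field(default_factory=list)  # (apex scan, height)
    ladder_width: float = 2.5
    artifact: Peak | None = None  # leading voltage-spike (apex, height, width)
    warp: list[tuple[int, str]] = field(default_factory=list)  # (scan, "duplicate"|"drop")
    seed: int = 0
    model: str = "3100"
    dye_names: tuple[str, ...] = DEFAULT_DYE_NAMES

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for ch, plist in self.peaks.items():
            if not 1 <= ch <= 4:
                raise ValueError(f"peak channel {ch} outside 1-4")
            for pos, height, _w in plist:
                if not 0 <= pos < self.length:
                    raise ValueError(f"peak apex {pos} outside [0, {self.length})")
                if height < 0:
                    raise ValueError("peak heights must be >= 0")
        for pos, height in self.ladder:
            if not 0 <= pos < self.length:
                raise ValueError(f"ladder apex {pos} outside [0, {self.length})")
            if height < 0:
                raise ValueError("ladder heights must be >= 0")
        for kind in {k for _, k in self.warp}:
            if kind not in ("duplicate", "drop"):
                raise ValueError(f"unknown warp kind {kind!r}")


def _gaussians(length: int, peaks: list[Peak]) -> np.ndarray:
    x = np.arange(length, dtype=float)
    y = np.zeros(length)
    for pos, height, width in peaks:
        y += height * np.exp(-0.5 * ((x - pos) / max(width, 1e-6)) ** 2)
    return y


def _finish(clean: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, clean.shape)
    return np.rint(np.clip(clean, 0.0, None)).astype(np.int32)


def synth_trace(spec: SyntheticSpec) -> TraceRecord:
    """One trace from a spec: Gaussian peaks + noise, ladder in channel 5."""
    rng = np.random.default_rng(spec.seed)
    channels = [
        _finish(_gaussians(spec.length, spec.peaks.get(c, [])), rng, spec.noise_sd)
        for c in range(1, 5)
    ]
    n_dyes = 4
    if spec.ladder:
        ladder_peaks = [(pos, h, spec.ladder_width) for pos, h in spec.ladder]
        channels.append(_finish(_gaussians(spec.length, ladder_peaks), rng, spec.noise_sd))
        n_dyes = 5
    return TraceRecord(
        channels=channels,
        model=spec.model,
        dye_names=list(spec.dye_names[:n_dyes]),
        is_raw=True,
    )


def _apply_warp(channels: list[np.ndarray], warp: list[tuple[int, str]]) -> list[np.ndarray]:
    for pos, kind in warp:
        if not 0 <= pos < len(channels[0]):
            raise ValueError(f"bad warp: position {pos} outside trace of {len(channels[0])} scans")
        if kind == "duplicate":
            channels = [np.insert(c, pos, c[pos]) for c in channels]
        else:  # drop
            channels = [np.delete(c, pos) for c in channels]
    return channels


def synth_pair(spec: SyntheticSpec) -> tuple[TraceRecord, TraceRecord, dict]:
    """Reference (with ladder) and distorted target, plus ground truth.

    The target shares the reference's clean peak signal but draws its
    own noise, applies the warp distortions in order, omits channel 5,
    and adds the leading artifact spike (across all four channels, as a
    voltage transient would) when one is specified.
    """
    reference = synth_trace(spec)
    rng = np.random.default_rng(spec.seed + 1)
    clean = [_gaussians(spec.length, spec.peaks.get(c, [])) for c in range(1, 5)]
    if spec.artifact is not None:
        spike = _gaussians(spec.length, [spec.artifact])
        clean = [y + spike for y in clean]
    target_channels = [_finish(y, rng, spec.noise_sd) for y in clean]
    target_channels = _apply_warp(target_channels, spec.warp)
    target = TraceRecord(
        channels=target_channels,
        model=spec.model,
        dye_names=list(spec.dye_names[:4]),
        is_raw=True,
    )
    truth = {"warp": list(spec.warp), "ladder": list(spec.ladder), "artifact": spec.artifact}
    return reference, target, truth


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from a small YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    peaks = {
        int(ch): [tuple(float(v) for v in p) for p in plist]
        for ch, plist in (doc.get("peaks") or {}).items()
    }
    return SyntheticSpec(
        length=int(doc.get("length", 1600)),
        peaks=peaks,
        noise_sd=float(doc.get("noise_sd", 2.0)),
        ladder=[(float(p), float(h)) for p, h in (doc.get("ladder") or [])],
        ladder_width=float(doc.get("ladder_width", 2.5)),
        artifact=tuple(doc["artifact"]) if doc.get("artifact") else None,
        warp=[(int(p), str(k)) for p, k in (doc.get("warp") or [])],
        seed=int(doc.get("seed", 0)),
        model=str(doc.get("model", "3100")),
    )


def example_25plex_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The bundled 25-peak layout: 25 markers cycling the four dye
    channels over a compact scan range, with a 9-step ladder in channel 5."""
    ref = resources.files("fsalign").joinpath("data/example_25plex.yaml")
    with resources.as_file(ref) as path:
        spec = spec_from_yaml(path)
    spec.seed = seed
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec
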