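"""Behavioural probes that measure the pipeline's effective constants.

Each probe treats the implementation as a black box and recovers one of
its operating constants by sweeping inputs: the end-trim retention
threshold, the guided start-search window, the alignment test-position
stride and score-window length, the number of rendered panels, the
warp-recovery residual and the peak-position agreement of the modified
trace.  They back both the reproducibility script and the test suite.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .align import AlignmentParams, align_traces, project_channels, window_score
from .cli import run
from .preprocess import (
    PreprocessConfig,
    find_start_generic,
    find_start_target,
    normalise_record,
    trim,
)
from .synth import example_25plex_spec, synth_pair
from .trace_io import TraceRecord, write_trace


def _triangle(length: int, apex: int, height: float, half_width: int = 5) -> np.ndarray:
    x = np.arange(length, dtype=float)
    return height * np.clip(1 - np.abs(x - apex) / half_width, 0, None)


def _record(*channels: np.ndarray) -> TraceRecord:
    chans = [np.asarray(c, dtype=float) for c in channels]
    while len(chans) < 4:
        chans.append(np.zeros_like(chans[0]))
    return TraceRecord(channels=chans, model="3100")


def probe_end_trim_threshold(values=range(0, 101)) -> int:
    """Smallest uniform tail value that survives end trimming.

    Builds traces whose scans 400-599 all hold value v (with a loud scan
    at 399 to anchor the signal region) and sweeps v: tails strictly
    below the trimming constant are removed, the rest retained.
    """
    boundary = None
    for v in values:
        ch1 = np.zeros(600)
        ch1[100] = 300.0  # a start peak so the trace is not blank
        ch1[399] = 60.0
        ch1[400:] = float(v)
        out = trim(_record(ch1), 0)
        retained = out.n_scans == 600
        if retained and boundary is None:
            boundary = v
        if not retained and boundary is not None:
            raise AssertionError("retention is not monotone in the tail value")
    if boundary is None:
        raise AssertionError("no tail value was retained")
    return boundary


def probe_start_search_window(offsets=range(150, 260)) -> int:
    """Largest offset past the reference start at which the target's only
    qualifying peak is still found by the guided start search."""
    config = PreprocessConfig()
    ref_start = 300
    found_max = None
    for offset in offsets:
        rec = _record(_triangle(1200, ref_start + offset, 300.0))
        try:
            found = find_start_target(ref_start, rec, config)
            ok = found == ref_start + offset
        except ValueError:
            ok = False
        if ok:
            found_max = offset
    if found_max is None:
        raise AssertionError("no offset was detected")
    return found_max


def _trimmed_reference(seed: int) -> list[np.ndarray]:
    spec = example_25plex_spec(seed=seed, noise_sd=0.0)
    ref, _, _ = synth_pair(spec)
    cfg = PreprocessConfig()
    refn, _ = normalise_record(ref, cfg)
    reft = trim(refn, find_start_generic(refn, cfg), cfg)
    return [np.asarray(c, dtype=float) for c in reft.channels[:4]]


def probe_alignment_stride(seed: int = 0, scan_range=range(600, 640)) -> int:
    """Period of the alignment test positions.

    A single duplicated scan is slid scan-by-scan through the trace; the
    positions at which the corrective deletion is applied all fall on
    the test-position lattice, whose period is their pairwise GCD.
    """
    ref4 = _trimmed_reference(seed)
    applied = set()
    for pos in scan_range:
        target = [np.insert(c, pos, c[pos]) for c in ref4]
        result = align_traces(ref4, target)
        deletes = [p for p, k in result.edits if k == "delete"]
        if deletes:
            applied.add(deletes[0])
    points = sorted(applied)
    if len(points) < 2:
        raise AssertionError("too few distinct edit positions to infer a stride")
    return int(np.gcd.reduce(np.diff(points)))


def probe_score_window(max_reach: int = 40) -> int:
    """Length of the alignment score window, from its perturbation reach.

    An impulse placed d scans after a test position contributes to the
    window score iff d < window; the largest contributing d + 1 is the
    window length.
    """
    p0 = 50
    reach = None
    for d in range(max_reach + 1):
        ref = [np.zeros(200) for _ in range(4)]
        ref[0][p0 + d] = 100.0
        score = window_score(ref, [np.zeros(200)] * 4, p0)
        if score > 0:
            reach = d
    if reach is None:
        raise AssertionError("impulse never reached the score window")
    return reach + 1


def probe_panel_count(seed: int = 0, out_dir: str | Path | None = None) -> int:
    """Number of aligned electropherogram images a successful run emits."""
    spec = example_25plex_spec(seed=seed, warp=[(500, "duplicate")])
    ref, tgt, _ = synth_pair(spec)
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(out_dir) if out_dir is not None else Path(tmp)
        ref_path, tgt_path = base / "ref.fsa", base / "tgt.fsa"
        write_trace(ref, ref_path)
        write_trace(tgt, tgt_path)
        report = run(ref_path, tgt_path, out_dir=base / "out", config=PreprocessConfig(multiplex25=True))
        images = [p for p in report.outputs if p.suffix == ".png"]
        return len(images)


def probe_warp_recovery(seed: int = 0, k: int = 10) -> tuple[float, int]:
    """(post/pre residual ratio, n scans) for k random warps spaced >= 45.

    The target is the preprocessed reference itself with k single-point
    duplications/deletions applied, so the residual measures alignment
    quality alone.
    """
    ref4 = _trimmed_reference(seed)
    rng = np.random.default_rng(seed + 1)
    n = len(ref4[0])
    positions = []
    pos = int(rng.integers(40, 90))
    while len(positions) < k and pos < n - 60:
        positions.append(pos)
        pos += int(rng.integers(45, 130))
    target = [c.copy() for c in ref4]
    for p in positions:
        if rng.random() < 0.5:
            target = [np.insert(c, p, c[p]) for c in target]
        else:
            target = [np.delete(c, p) for c in target]

    def total(channels):
        proj = project_channels(channels, n)
        return sum(float(np.abs(a - b).sum()) for a, b in zip(ref4, proj))

    pre = total(target)
    result = align_traces(ref4, target)
    post = total(result.aligned_channels)
    return post / pre, n


def probe_apex_shift(seed: int = 0) -> tuple[int, int]:
    """(max apex shift in scans, n peaks checked) between the modified
    target trace and the reference coordinate system.

    Runs the full pipeline on a warped, independently-noised synthetic
    pair, reads the written modified trace back, and compares each known
    peak apex against its expected reference-frame position.
    """
    from .preprocess import PeakPattern, find_start_25plex, raw_transform
    from .trace_io import read_trace

    spec = example_25plex_spec(
        seed=seed,
        warp=[(400, "duplicate"), (600, "drop"), (760, "duplicate"), (950, "drop")],
        artifact=(10, 2000.0, 1.5),
    )
    ref, tgt, _ = synth_pair(spec)
    cfg = PreprocessConfig(multiplex25=True)
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(tmp)
        write_trace(ref, base / "ref.fsa")
        write_trace(tgt, base / "tgt.fsa")
        run(base / "ref.fsa", base / "tgt.fsa", out_dir=base / "out", config=cfg)
        modified = read_trace(base / "out" / "modified_target.fsa")
        refn, _ = normalise_record(raw_transform(read_trace(base / "ref.fsa")), cfg)
        reft = trim(refn, find_start_25plex(refn, PeakPattern.default_25plex()), cfg)
    start = reft.trim_span[0]
    max_shift = 0
    n_peaks = 0
    for channel, peaks in spec.peaks.items():
        for pos, _height, _width in peaks:
            expected = int(pos) - start
            if not 0 <= expected < modified.n_scans:
                continue
            lo = max(0, expected - 10)
            apex = lo + int(np.argmax(modified.channels[channel - 1][lo : expected + 11]))
            max_shift = max(max_shift, abs(apex - expected))
            n_peaks += 1
    return max_shift, n_peaks
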