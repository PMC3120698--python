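"""Greedy single-point insertion/deletion alignment of trace signals.

Capillary runs of the same fragments drift slightly in migration time,
so two electropherograms differ by small local stretches rather than a
global shift.  The aligner walks test positions along the reference at a
fixed stride; at each position it computes a local difference score over
the next ``window`` scans and checks whether duplicating or removing the
target's data point at that position reduces the score.  The strictly
best adjustment is applied (all four channels together, so they stay in
register) and later positions operate on the adjusted target.  Larger
shifts are absorbed one point at a time over successive positions.

Peaks in primer-extension multiplex traces are dense and overlapping, so
the defaults sample every 3 data points and score the subsequent 15 --
finer than the 5/30 used for long sequencing traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_io import TraceRecord


@dataclass
class AlignmentParams:
    stride: int = 3  # scans between successive test positions
    window: int = 15  # scans scored after each test position

    def __post_init__(self) -> None:
        if self.stride < 1 or self.window < 1:
            raise ValueError("stride and window must be >= 1")


@dataclass
class AlignmentResult:
    aligned_channels: list[np.ndarray]
    edits: list[tuple[int, str]] = field(default_factory=list)  # (position, "insert"|"delete")
    final_length: int = 0


def _channels4(obj: TraceRecord | Sequence) -> list[np.ndarray]:
    chans = obj.channels[:4] if isinstance(obj, TraceRecord) else list(obj)[:4]
    return [np.asarray(c, dtype=float) for c in chans]


def _score(ref4: list[np.ndarray], tgt4: list[np.ndarray], position: int, window: int) -> float:
    total = 0.0
    for r, t in zip(ref4, tgt4):
        rseg = r[position : position + window]
        tseg = t[position : position + window]
        m = max(len(rseg), len(tseg))
        if m == 0:
            continue
        a = np.zeros(m)
        a[: len(rseg)] = rseg
        b = np.zeros(m)
        b[: len(tseg)] = tseg
        total += float(np.abs(a - b).sum())
    return total


def window_score(
    reference: TraceRecord | Sequence,
    target_channels: TraceRecord | Sequence,
    position: int,
    params: AlignmentParams | None = None,
) -> float:
    """Sum of absolute per-scan channel differences over the score window.

    Scans past either trace's end count the other trace's value against
    zero, so overhangs are penalised rather than ignored.
    """
    params = params or AlignmentParams()
    if position < 0:
        raise ValueError("position must be >= 0")
    return _score(_channels4(reference), _channels4(target_channels), position, params.window)


def align_traces(
    reference: TraceRecord | Sequence,
    target: TraceRecord | Sequence,
    params: AlignmentParams | None = None,
) -> AlignmentResult:
    """Align the target's four channels to the reference.

    Test positions run 0, stride, 2*stride, ... through the reference's
    end.  At each, the no-adjustment score is compared against the score
    after duplicating and after deleting the target point there; the
    strictly best option is applied (ties with the baseline leave the
    target untouched; an insert/delete tie below baseline deletes).
    """
    params = params or AlignmentParams()
    ref4 = _channels4(reference)
    tgt4 = [np.array(c, dtype=float) for c in _channels4(target)]
    if len(tgt4) < 4 or len(ref4) < 4:
        raise ValueError("nothing to align: four data channels required")
    if len(tgt4[0]) == 0:
        raise ValueError("nothing to align: empty target")
    original_len = len(tgt4[0])
    ref_len = len(ref4[0])
    edits: list[tuple[int, str]] = []

    for p in range(0, ref_len, params.stride):
        if p >= len(tgt4[0]):
            continue
        base = _score(ref4, tgt4, p, params.window)
        inserted = [np.insert(c, p, c[p]) for c in tgt4]
        deleted = [np.delete(c, p) for c in tgt4]
        s_ins = _score(ref4, inserted, p, params.window)
        s_del = _score(ref4, deleted, p, params.window)
        if min(s_ins, s_del) < base:
            if s_del <= s_ins:
                tgt4, applied = deleted, ("delete", s_del)
            else:
                tgt4, applied = inserted, ("insert", s_ins)
            # local non-worsening: the applied choice never scores above baseline
            assert applied[1] <= base
            edits.append((p, applied[0]))

    n_ins = sum(1 for _, k in edits if k == "insert")
    n_del = len(edits) - n_ins
    result = AlignmentResult(tgt4, edits, len(tgt4[0]))
    assert result.final_length == original_len + n_ins - n_del
    return result


def project_channels(channels: Sequence[np.ndarray], length: int) -> list[np.ndarray]:
    """Truncate or zero-pad channels to ``length`` (the reference frame)."""
    out = []
    for c in channels:
        c = np.asarray(c, dtype=float)
        if len(c) >= length:
            out.append(c[:length].copy())
        else:
            out.append(np.concatenate([c, np.zeros(length - len(c))]))
    return out
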