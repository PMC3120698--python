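"""Build the modified target trace with embedded size standards.

After alignment the target's peaks sit at scan positions that agree with
the size-standard peaks recorded in the reference's fifth channel.
Copying that raw fifth channel into the target file therefore yields a
trace "as if" the target fragments had been co-electrophoresed with the
standards, and ordinary fragment-sizing software can genotype it.  The
output file is the original target file patched in place: channels 1-4
replaced by the aligned, normalised values, channel 5 overwritten with
the reference ladder, every other vendor tag preserved byte-for-byte.
For the 310 instrument the spectral matrix is additionally replaced by
the identity, since the written channels already represent pure dyes.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from .align import AlignmentResult, project_channels
from .trace_io import INT16_MAX, TraceRecord, write_trace

logger = logging.getLogger(__name__)


def build_modified_trace(
    target: TraceRecord, aligned: AlignmentResult, reference: TraceRecord
) -> TraceRecord:
    """TraceRecord for the modified target file.

    ``reference`` must be the trimmed reference whose raw channel 5 is on
    the shared coordinate system; ``target`` is the original, unmodified
    target record (its ``source_bytes`` drive the patch-mode write).  If
    the reference has no fifth channel the embedding is skipped and the
    output keeps four channels.
    """
    ref_len = reference.n_scans
    channels = [
        np.rint(np.clip(c, 0, INT16_MAX)).astype(np.int32)
        for c in project_channels(aligned.aligned_channels, ref_len)
    ]
    dye_names = list(target.dye_names) or list(reference.dye_names[:4])

    ladder = reference.ladder
    if ladder is not None:
        if len(ladder) != ref_len:
            raise ValueError(
                f"coordinate mismatch: aligned length {ref_len}, reference channel 5 {len(ladder)}"
            )
        channels.append(np.asarray(ladder, dtype=np.int32).copy())
        if len(dye_names) < 5:
            fifth_dye = reference.dye_names[4] if len(reference.dye_names) >= 5 else "LIZ"
            dye_names = (dye_names + [""] * 4)[:4] + [fifth_dye]
    else:
        logger.info("reference has no fifth channel; size-standard embedding skipped")

    matrix = target.matrix
    if (target.model or "").strip() == "310":
        dim = matrix.shape[0] if matrix is not None else len(channels)
        matrix = np.eye(dim)  # channels now represent pure dyes

    return replace(
        target,
        channels=channels,
        dye_names=dye_names,
        matrix=matrix,
        trim_span=None,
    )


def write_modified_trace(record: TraceRecord, path: str | Path) -> None:
    """Patch-write the modified trace next to its original metadata."""
    write_trace(record, path)
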