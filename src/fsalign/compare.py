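"""Per-scan difference profile between aligned traces.

A genotype difference between two fragment-analysis runs shows up as a
drop in one dye channel mirrored by a rise in another at the same scan.
The difference profile amplifies exactly that signature: for each scan
and channel the signed reference-minus-target difference is squared and
weighted by the square root of the summed opposite-direction differences
of the other channels.  A change confined to a single channel (a peak
simply present or absent) gets weight zero, so the profile is most
sensitive to base substitutions and deliberately muted for
presence/absence differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import _channels4
from .trace_io import TraceRecord


@dataclass
class DifferenceProfile:
    """Signed highlighted-difference arrays, one row per dye channel."""

    values: np.ndarray  # shape (4, n_scans)

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]


def difference_profile(
    reference: TraceRecord | Sequence, aligned_target: TraceRecord | Sequence
) -> DifferenceProfile:
    """Highlighted difference profile of two aligned traces.

    For scan i and channel c with d_c = ref_c[i] - tgt_c[i], the profile
    value is sign(d_c) * d_c^2 * sqrt(sum of |d_c'| over the other
    channels whose difference has the opposite sign).  Swapping the two
    traces negates every value; identical traces give all zeros.
    """
    ref = np.stack(_channels4(reference))
    tgt = np.stack(_channels4(aligned_target))
    if ref.shape != tgt.shape:
        raise ValueError(f"unaligned inputs: shapes {ref.shape} vs {tgt.shape}")
    d = ref - tgt
    sign = np.sign(d)
    absd = np.abs(d)
    values = np.zeros_like(d)
    for c in range(4):
        opposite = np.zeros(d.shape[1])
        for c2 in range(4):
            if c2 == c:
                continue
            opposite += absd[c2] * (sign[c2] == -sign[c])
        values[c] = sign[c] * d[c] ** 2 * np.sqrt(opposite)
    # d == 0 scans are exactly zero already (sign 0 annihilates the term)
    return DifferenceProfile(values)
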