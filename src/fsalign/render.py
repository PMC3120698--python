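"""Render the three aligned electropherogram panels.

The visual check of an alignment is three stacked images on one scan
axis: the reference (with the size-standard channel overlaid in orange),
the bidirectional difference profile around a zero line, and the aligned
target.  Channels 1-4 default to green/black/blue/red; no claim is made
that this order maps to particular nucleotides on every instrument.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless raster output
import matplotlib.pyplot as plt
import numpy as np

from .align import _channels4
from .compare import DifferenceProfile
from .trace_io import TraceRecord

DEFAULT_CHANNEL_COLORS = ("green", "black", "blue", "red")
LADDER_COLOR = "orange"
PANEL_NAMES = ("reference", "difference", "target")


def render_panels(
    reference: TraceRecord,
    profile: DifferenceProfile,
    aligned_target: Sequence[np.ndarray],
    out_dir: str | Path,
    *,
    width: int = 1000,
    height: int = 250,
    dpi: int = 100,
    colors: Sequence[str] = DEFAULT_CHANNEL_COLORS,
    ladder_color: str = LADDER_COLOR,
    fmt: str = "png",
    composite: bool = False,
) -> list[Path]:
    """Write the reference / difference / target panels; return their paths.

    All three images share pixel width and x-range.  When ``composite``
    is true an additional stacked page is written after them.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot write images: {exc}") from exc

    ref4 = _channels4(reference)
    tgt4 = _channels4(aligned_target)
    n = len(ref4[0])
    x = np.arange(n)
    xlim = (0, max(n - 1, 1))

    def draw_reference(ax):
        for c, color in zip(ref4, colors):
            ax.plot(x, c, color=color, lw=0.8)
        if reference.ladder is not None:
            ax.plot(x, reference.ladder, color=ladder_color, lw=1.2)
        ax.set_ylabel("reference")

    def draw_difference(ax):
        for row, color in zip(profile.values, colors):
            ax.plot(x[: len(row)], row, color=color, lw=0.8)
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_ylabel("difference")

    def draw_target(ax):
        for c, color in zip(tgt4, colors):
            ax.plot(x[: len(c)], c, color=color, lw=0.8)
        ax.set_ylabel("target")

    drawers = (draw_reference, draw_difference, draw_target)
    paths: list[Path] = []
    try:
        for name, draw in zip(PANEL_NAMES, drawers):
            fig, ax = plt.subplots(figsize=(width / dpi, height / dpi), dpi=dpi)
            draw(ax)
            ax.set_xlim(*xlim)
            ax.set_xlabel("scan")
            path = out_dir / f"{name}.{fmt}"
            fig.savefig(path)
            plt.close(fig)
            paths.append(path)
        if composite:
            fig, axes = plt.subplots(
                3, 1, figsize=(width / dpi, 3 * height / dpi), dpi=dpi, sharex=True
            )
            for ax, draw in zip(axes, drawers):
                draw(ax)
                ax.set_xlim(*xlim)
            axes[-1].set_xlabel("scan")
            fig.savefig(out_dir / f"composite.{fmt}")
            plt.close(fig)
    except OSError as exc:
        raise OSError(f"cannot write images: {exc}") from exc
    return paths
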