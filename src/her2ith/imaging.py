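"""Controlled histogram bar-chart rendering and exact pixel-level extraction.

The study setting recovers copy-number histograms from rendered bar charts in
diagnostic reports.  Real scanned-report OCR is out of scope here; instead a
fully specified renderer draws a histogram as a bar chart with fixed geometry,
and the extractor inverts it exactly.  ``extract_histogram_from_image`` is a
strict inverse of ``render_histogram_image`` under the same :class:`RenderSpec`.

Geometry (all units pixels, black bars on white, grayscale mode "L"):

* bins ``0 .. max(bins)`` are drawn left to right;
* bin ``b`` occupies columns ``margin + b*(bar_width+gap) .. +bar_width-1``;
* a count ``c`` is a bar of height ``c * px_per_count`` standing on the
  baseline row ``height - margin - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .histogram import SignalHistogram

__all__ = ["RenderSpec", "ExtractionError", "render_histogram_image",
           "extract_histogram_from_image"]

_WHITE, _BLACK = 255, 0


class ExtractionError(ValueError):
    """Raised when an image does not match the expected bar-chart geometry."""


@dataclass(frozen=True)
class RenderSpec:
    """Fixed bar-chart geometry shared by renderer and extractor."""

    bar_width: int = 8
    gap: int = 2
    px_per_count: int = 2
    margin: int = 10

    def __post_init__(self):
        for name in ("bar_width", "gap", "px_per_count", "margin"):
            v = getattr(self, name)
            if int(v) != v or (v <= 0 and name != "gap") or v < 0:
                raise ValueError(f"{name} must be a positive integer (gap >= 0)")


def render_histogram_image(hist: SignalHistogram, spec: RenderSpec = RenderSpec()) -> Image.Image:
    """Render a histogram as a deterministic bar chart.

    Every bin from 0 up to the largest occupied bin gets a slot (empty bins
    draw no bar), so bin identity is recoverable from horizontal position.
    """
    n_slots = max(hist.bins) + 1
    width = 2 * spec.margin + n_slots * spec.bar_width + (n_slots - 1) * spec.gap
    max_count = max(hist.bins.values())
    height = 2 * spec.margin + max_count * spec.px_per_count
    arr = np.full((height, width), _WHITE, dtype=np.uint8)
    baseline = height - spec.margin - 1
    for b in range(n_slots):
        count = hist.bins.get(b, 0)
        if count == 0:
            continue
        h = count * spec.px_per_count
        x0 = spec.margin + b * (spec.bar_width + spec.gap)
        arr[baseline - h + 1 : baseline + 1, x0 : x0 + spec.bar_width] = _BLACK
    return Image.fromarray(arr, mode="L")


def extract_histogram_from_image(image: Image.Image, spec: RenderSpec = RenderSpec()) -> SignalHistogram:
    """Recover the exact bin counts from a rendered bar chart.

    Raises
    ------
    ExtractionError
        If the image width does not fit the slot grid, a bar has ragged or
        non-divisible height, ink appears outside the slot grid, or the image
        contains no bars at all.
    """
    arr = np.asarray(image.convert("L"))
    height, width = arr.shape
    slot = spec.bar_width + spec.gap
    inner = width - 2 * spec.margin + spec.gap
    if inner <= 0 or inner % slot != 0:
        raise ExtractionError(f"image width {width} does not fit the slot grid")
    n_slots = inner // slot
    baseline = height - spec.margin - 1
    ink = arr < 128
    bins: dict[int, int] = {}
    for b in range(n_slots):
        x0 = spec.margin + b * slot
        cols = ink[: baseline + 1, x0 : x0 + spec.bar_width]
        heights = cols.sum(axis=0)
        if not (heights == heights[0]).all():
            raise ExtractionError(f"ragged bar in slot {b}")
        h = int(heights[0])
        if h == 0:
            continue
        # bar must be contiguous and anchored on the baseline
        if not cols[baseline - h + 1 :, :].all() or cols[: baseline - h + 1, :].any():
            raise ExtractionError(f"bar in slot {b} not anchored on the baseline")
        if h % spec.px_per_count != 0:
            raise ExtractionError(f"bar height {h} not a multiple of px_per_count")
        bins[b] = h // spec.px_per_count
    if not bins:
        raise ExtractionError("no bars found in image")
    return SignalHistogram(bins)
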