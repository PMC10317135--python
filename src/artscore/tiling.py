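"""Chop layouts: smallest-overlap covering grids and sliding windows.

Well images (nominally 2452 x 2056 px) are far larger than the ~256 px
inputs the classifiers accept, so they are cut into fixed-size square
"chops".  Two layouts are used:

* ``smallest_overlap_grid`` -- the minimal number of chops that covers
  the whole image, with the leftover spread as near-equal overlaps
  (training-set preparation).
* ``sliding_grid`` -- a window shifted in steps of ``s`` pixels with a
  final clamped position (the scoring sweep).

All coordinates are 0-based, half-open, origin at the top-left,
(row, col) = (y, x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np


@dataclass(frozen=True)
class Window:
    """A rectangular crop covering [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("window origin must be non-negative")
        if self.width < 1 or self.height < 1:
            raise ValueError("window dims must be >= 1")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def contains(self, x: int, y: int) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class ChopGrid:
    """An ordered, row-major set of windows laid over one image."""

    image_height: int
    image_width: int
    chop_height: int
    chop_width: int
    windows: tuple[Window, ...]
    layout: Literal["smallest_overlap", "sliding"]
    x_starts: tuple[int, ...] = field(default=())
    y_starts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.x1 > self.image_width or w.y1 > self.image_height:
                raise ValueError(f"window {w} exceeds the image")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def to_tsv(self, well_id: str = "") -> str:
        """BED-like TSV dump (well_id, x0, y0, width, height, layout)."""
        lines = [
            f"{well_id}\t{w.x0}\t{w.y0}\t{w.width}\t{w.height}\t{self.layout}"
            for w in self.windows
        ]
        return "\n".join(lines) + "\n"


def _check_dims(image_len: int, chop_len: int, axis: str) -> None:
    if chop_len < 1:
        raise ValueError(f"chop {axis} must be >= 1")
    if chop_len > image_len:
        raise ValueError(
            f"chop {axis} {chop_len} exceeds image {axis} {image_len}"
        )


def _smallest_overlap_starts(image_len: int, chop_len: int) -> list[int]:
    """Start positions of the minimal covering along one axis.

    Uses k = ceil(L/c) chops; the first starts at 0, the last ends at L,
    and intermediate starts are rounded linear interpolation so that
    consecutive overlaps differ by at most one pixel.
    """
    _check_dims(image_len, chop_len, "length")
    k = math.ceil(image_len / chop_len)
    if k == 1:
        return [0]
    d = image_len - chop_len
    return [round(i * d / (k - 1)) for i in range(k)]


def smallest_overlap_grid(
    image_height: int, image_width: int, chop_height: int, chop_width: int
) -> ChopGrid:
    """Minimal covering of the image by fixed-size chops, row-major order."""
    ys = _smallest_overlap_starts(image_height, chop_height)
    xs = _smallest_overlap_starts(image_width, chop_width)
    windows = tuple(
        Window(x0=x, y0=y, width=chop_width, height=chop_height)
        for y in ys
        for x in xs
    )
    return ChopGrid(
        image_height=image_height,
        image_width=image_width,
        chop_height=chop_height,
        chop_width=chop_width,
        windows=windows,
        layout="smallest_overlap",
        x_starts=tuple(xs),
        y_starts=tuple(ys),
    )


def _sliding_starts(image_len: int, chop_len: int, step: int) -> list[int]:
    _check_dims(image_len, chop_len, "length")
    if step < 1:
        raise ValueError("step must be >= 1")
    last = image_len - chop_len
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)  # clamp so the far border is always covered
    return starts


def sliding_grid(
    image_height: int,
    image_width: int,
    chop_height: int,
    chop_width: int,
    step: int,
) -> ChopGrid:
    """Sliding-window layout: positions 0, s, 2s, ... plus a clamped last."""
    ys = _sliding_starts(image_height, chop_height, step)
    xs = _sliding_starts(image_width, chop_width, step)
    windows = tuple(
        Window(x0=x, y0=y, width=chop_width, height=chop_height)
        for y in ys
        for x in xs
    )
    return ChopGrid(
        image_height=image_height,
        image_width=image_width,
        chop_height=chop_height,
        chop_width=chop_width,
        windows=windows,
        layout="sliding",
        x_starts=tuple(xs),
        y_starts=tuple(ys),
    )


def crop(image: np.ndarray, window: Window) -> np.ndarray:
    """Return the half-open sub-image selected by ``window``.

    Works on (H, W) and (H, W, C) arrays; the result is a view.
    """
    h, w = image.shape[:2]
    if window.x1 > w or window.y1 > h:
        raise ValueError(f"window {window} out of bounds for image {h}x{w}")
    return image[window.y0 : window.y1, window.x0 : window.x1]


def is_border_window(window: Window, grid: ChopGrid) -> bool:
    """True iff the window sits in the first/last row or column band."""
    if window not in grid.windows:
        raise ValueError("window does not belong to the grid")
    return (
        window.y0 == grid.y_starts[0]
        or window.y0 == grid.y_starts[-1]
        or window.x0 == grid.x_starts[0]
        or window.x0 == grid.x_starts[-1]
    )
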