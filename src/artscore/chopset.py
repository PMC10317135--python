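"""Training-set construction: contour filters, UV vetting, rim chops.

Chops inherit the human score of their well, but raw inheritance would
flood the set with featureless chops and mislabel salt.  Three filters
are applied:

* crystal chops (scores 21-23) must show contour structure in **both**
  the visible chop and its UV mate (protein fluoresces under UV, salt
  does not);
* precipitate (11-13) and other (31-34) chops must exceed a contour
  threshold, so empty regions of a precipitate well are not labeled
  precipitate;
* clear chops are always accepted, and the border chops of clear wells
  whose contour measure exceeds a threshold become the ``rim`` class --
  droplet-edge arcs that would otherwise be misread as crystals.

The contour measure is the total marching-squares iso-contour length
after light Gaussian smoothing.  Accepted chops are packed into a
simple length-prefixed record file with a CSV manifest.
"""

from __future__ import annotations

import io
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .classes import ClassDef, ClassScheme, group_of
from .synthgen import SyntheticWell, to_uint8
from .tiling import ChopGrid, Window, crop, is_border_window, smallest_overlap_grid

_MAGIC = b"ARTR"
_VERSION = 1


@dataclass(frozen=True)
class FilterConfig:
    """Contour-filter thresholds, given in pixels of total contour
    length at the 256-px reference chop and scaled linearly with chop
    size.  ``border_threshold_boost`` (optional, off by default)
    multiplies thresholds for border chops -- the abandoned first
    attempt at suppressing rim misreads, kept as an option."""

    contour_level: float | None = None  # None: image mean + 0.1
    t_crystal_vis: float = 40.0
    t_crystal_uv: float = 40.0
    t_texture: float = 40.0
    t_rim: float = 40.0
    border_threshold_boost: float | None = None
    require_uv: bool = True
    reference_chop: int = 256

    def __post_init__(self) -> None:
        for name in ("t_crystal_vis", "t_crystal_uv", "t_texture", "t_rim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, threshold: float, chop_size: int, border: bool = False) -> float:
        t = threshold * chop_size / self.reference_chop
        if border and self.border_threshold_boost:
            t *= self.border_threshold_boost
        return t


def contour_measure(chop: np.ndarray, contour_level: float | None = None) -> float:
    """Total iso-contour polyline length (pixels) inside a chop.

    The chop is smoothed (Gaussian, sigma 1) and marching-squares
    contours are extracted at ``contour_level``.  By default the
    measure is taken at both mean + 0.1 and mean - 0.1 and the larger
    total is returned: the 0.1 offset keeps the level clear of the
    sensor-noise band, and probing both sides catches bright and dark
    structure alike.  Constant images measure 0.
    """
    chop = np.asarray(chop, dtype=float)
    smoothed = ndimage.gaussian_filter(chop, 1.0)

    def at_level(level: float) -> float:
        if not smoothed.min() < level < smoothed.max():
            return 0.0
        return float(
            sum(
                np.hypot(*np.diff(c, axis=0).T).sum()
                for c in measure.find_contours(smoothed, level)
            )
        )

    if contour_level is None:
        m = smoothed.mean()
        return max(at_level(m + 0.1), at_level(m - 0.1))
    return at_level(contour_level)


@dataclass(frozen=True)
class ChopRecord:
    """One accepted training chop (8-bit grayscale) with its label."""

    chop: np.ndarray  # uint8 (S, S)
    score_no: int
    is_rim: bool
    well_id: str

    def __post_init__(self) -> None:
        if self.chop.dtype != np.uint8:
            raise ValueError("records store 8-bit chops")


@dataclass
class TrainingSet:
    records: list[ChopRecord] = field(default_factory=list)
    chop_size: int = 256
    missing_classes: list[str] = field(default_factory=list)

    def counts(self, scheme: ClassScheme) -> dict[str, int]:
        out = {c.name: 0 for c in scheme.classes}
        for r in self.records:
            out[scheme_class(scheme, r.score_no, r.is_rim).name] += 1
        return out

    def arrays(self, scheme: ClassScheme) -> tuple[np.ndarray, np.ndarray]:
        """(chops in [0,1], integer labels) for classifier training."""
        x = np.stack([r.chop for r in self.records]).astype(float) / 255.0
        y = np.array(
            [scheme.index_of(scheme_class(scheme, r.score_no, r.is_rim))
             for r in self.records]
        )
        return x, y


def scheme_class(scheme: ClassScheme, score_no: int, is_rim: bool) -> ClassDef:
    """Resolve a (score, rim) label against a full or merged scheme."""
    if scheme.mode == "full13":
        return scheme.by_score(score_no, is_rim=is_rim)
    if is_rim:
        return scheme.by_name("rim")
    return scheme.by_name(group_of(score_no))


# ---------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------

def accept_chop(
    chop: np.ndarray,
    uv_chop: np.ndarray | None,
    score_no: int,
    config: FilterConfig,
    is_border: bool = False,
) -> bool:
    """Apply the class-dependent acceptance rule to one candidate chop."""
    size = min(chop.shape)
    group = group_of(score_no)
    level = config.contour_level
    if group == "crystal":
        if uv_chop is None:
            if config.require_uv:
                raise ValueError(
                    f"crystal chop (score {score_no}) has no UV mate"
                )
            return contour_measure(chop, level) > config.scaled(
                config.t_crystal_vis, size, is_border
            )
        return (
            contour_measure(chop, level)
            > config.scaled(config.t_crystal_vis, size, is_border)
            and contour_measure(uv_chop, level)
            > config.scaled(config.t_crystal_uv, size, is_border)
        )
    if group in ("precipitate", "other"):
        return contour_measure(chop, level) > config.scaled(
            config.t_texture, size, is_border
        )
    return True  # clear chops are always accepted


def extract_rim_chops(
    well: SyntheticWell | tuple[np.ndarray, int],
    grid: ChopGrid,
    config: FilterConfig,
    well_id: str = "",
) -> list[tuple[np.ndarray, Window]]:
    """Rim chops of a clear well: border windows with contour structure.

    The well must be scored clear (score 1); anything else is misuse --
    rim chops come only from drops the users called empty.
    """
    if isinstance(well, SyntheticWell):
        image = well.visible
        score = well.well_label.score_no
        if well.well_label.is_rim:
            raise ValueError("wells are never labeled rim")
    else:
        image, score = well
    if score != 1:
        raise ValueError(f"rim extraction needs a clear well, got score {score}")
    out = []
    for window in grid:
        if not is_border_window(window, grid):
            continue
        piece = crop(image, window)
        t = config.scaled(config.t_rim, min(piece.shape))
        if contour_measure(piece, config.contour_level) > t:
            out.append((piece, window))
    return out


# ---------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------

def _droplet_crop(well: SyntheticWell, chop_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Crop visible + UV to the droplet bbox (>= one chop per side)."""
    ys, xs = np.nonzero(well.droplet_mask)
    if len(ys) == 0:  # dried drop: keep the full image
        return well.visible, well.uv
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    h, w = well.visible.shape
    from .dropseg import _pad_span

    y0, y1 = _pad_span(int(y0), int(y1), chop_size, h)
    x0, x1 = _pad_span(int(x0), int(x1), chop_size, w)
    return well.visible[y0:y1, x0:x1], well.uv[y0:y1, x0:x1]


def build_training_set(
    wells: list[SyntheticWell],
    scheme: ClassScheme,
    chop_size: int,
    config: FilterConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> TrainingSet:
    """Chop, filter and pack a labeled well collection.

    Wells are cropped to their droplet, laid out with the
    smallest-overlap grid, and filtered with :func:`accept_chop`;
    clear wells additionally contribute rim chops.  When ``out_dir``
    is given, a packed record file and CSV manifest are written.
    """
    config = config or FilterConfig()
    records: list[ChopRecord] = []
    for i, well in enumerate(wells):
        wid = f"well_{i:04d}"
        vis, uv = _droplet_crop(well, chop_size)
        grid = smallest_overlap_grid(*vis.shape, chop_size, chop_size)
        score = well.well_label.score_no
        if score == 1 and not well.well_label.is_rim:
            for piece, window in extract_rim_chops((vis, score), grid, config, wid):
                records.append(
                    ChopRecord(to_uint8(piece), 1, True, wid)
                )
            for window in grid:
                if is_border_window(window, grid):
                    continue
                records.append(
                    ChopRecord(to_uint8(crop(vis, window)), 1, False, wid)
                )
        else:
            needs_uv = group_of(score) == "crystal"
            for window in grid:
                piece = crop(vis, window)
                mate = crop(uv, window) if needs_uv else None
                if accept_chop(piece, mate, score, config,
                               is_border=is_border_window(window, grid)):
                    records.append(
                        ChopRecord(to_uint8(piece), score, False, wid)
                    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    ts = TrainingSet(records=[records[j] for j in order], chop_size=chop_size)
    counts = ts.counts(scheme)
    ts.missing_classes = [name for name, n in counts.items() if n == 0]
    if ts.missing_classes:
        warnings.warn(
            f"no accepted chops for classes: {', '.join(ts.missing_classes)}",
            stacklevel=2,
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_record_file(out / "chops.rec", ts)
        write_manifest(out / "chops.csv", ts, scheme)
    return ts


# ---------------------------------------------------------------------
# packed record file
# ---------------------------------------------------------------------

def write_record_file(path: str | Path, ts: TrainingSet) -> None:
    """magic, version, count, then length-prefixed PNG + label bytes."""
    from PIL import Image

    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<BI", _VERSION, len(ts.records)))
        f.write(struct.pack("<H", ts.chop_size))
        for r in ts.records:
            buf = io.BytesIO()
            Image.fromarray(r.chop, mode="L").save(buf, format="PNG")
            png = buf.getvalue()
            wid = r.well_id.encode()
            f.write(struct.pack("<IBBH", len(png), r.score_no, int(r.is_rim), len(wid)))
            f.write(png)
            f.write(wid)


def read_record_file(path: str | Path) -> TrainingSet:
    from PIL import Image

    with open(path, "rb") as f:
        if f.read(4) != _MAGIC:
            raise ValueError(f"{path} is not a chop record file")
        version, count = struct.unpack("<BI", f.read(5))
        if version != _VERSION:
            raise ValueError(f"unsupported record version {version}")
        (chop_size,) = struct.unpack("<H", f.read(2))
        records = []
        for _ in range(count):
            png_len, score, rim, wid_len = struct.unpack("<IBBH", f.read(8))
            png = f.read(png_len)
            wid = f.read(wid_len).decode()
            chop = np.asarray(Image.open(io.BytesIO(png)))
            records.append(ChopRecord(chop, score, bool(rim), wid))
    return TrainingSet(records=records, chop_size=chop_size)


def write_manifest(path: str | Path, ts: TrainingSet, scheme: ClassScheme) -> None:
    rows = ["index,well_id,score_no,is_rim,class_name"]
    for i, r in enumerate(ts.records):
        name = scheme_class(scheme, r.score_no, r.is_rim).name
        rows.append(f"{i},{r.well_id},{r.score_no},{int(r.is_rim)},{name}")
    Path(path).write_text("\n".join(rows) + "\n")
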