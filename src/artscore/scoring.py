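"""Per-well scoring: sliding-window classification, priority aggregation
and rendered evidence frames (the ARTscore).

A well is scored by (1) locating the droplet with the segmentation
model, (2) sliding a chop-sized window in steps of ``s`` pixels across
the droplet crop, (3) classifying every window, and (4) aggregating:
among windows whose top probability reaches the confidence threshold
``c``, the highest-priority class wins the well (crystal classes first,
then precipitate and other, clear last; a rim window only ever makes a
well clear).  The defaults s = 50 px and c = 0.85 are the operating
point of the production pipeline.  Wells where nothing reaches ``c``
are reported unscored rather than guessed, to avoid false positives.

Evidence is rendered as colored 3-px frames around the top-``n``
windows plus an image border tinted in the winning group's color
(red crystal, blue precipitate, magenta other, gray clear, white rim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .classes import ClassDef, ClassScheme
from .dropseg import locate_droplet
from .nets import predict_proba
from .synthgen import SceneSpec, ground_truth_label, scaled_min_overlap, to_uint8
from .tiling import Window, crop, sliding_grid

#: Fig-style colors; classes without an explicit entry use their group color.
GROUP_COLORS: dict[str, tuple[int, int, int]] = {
    "crystal": (255, 0, 0),      # red
    "precipitate": (0, 0, 255),  # blue
    "other": (255, 0, 255),      # magenta (as for the null experiment)
    "clear": (128, 128, 128),    # gray
}
RIM_COLOR: tuple[int, int, int] = (255, 255, 255)  # white


def class_color(
    class_def: ClassDef,
    color_map: dict[str, tuple[int, int, int]] | None = None,
) -> tuple[int, int, int]:
    if color_map and class_def.name in color_map:
        return color_map[class_def.name]
    if class_def.is_rim:
        return RIM_COLOR
    return GROUP_COLORS[class_def.group]


@dataclass(frozen=True)
class ChopScore:
    """One classified window (droplet-crop coordinates)."""

    window: Window
    class_def: ClassDef
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class WellScore:
    """Aggregated outcome of one well."""

    well_id: str
    score_no: int | None
    class_def: ClassDef | None
    probability: float | None
    top_chops: list[ChopScore] = field(default_factory=list)
    source: str = "ARTscore"
    inspection_time: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )
    annotated_image: np.ndarray | None = None
    unscored_reason: str | None = None

    @property
    def scored(self) -> bool:
        return self.score_no is not None


# ---------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------

def aggregate_well_score(
    chop_scores: list[ChopScore], scheme: ClassScheme, c: float = 0.85
) -> int | None:
    """Highest-priority class among chops with probability >= c.

    Returns the winning score number, with rim reported as clear
    (score 1), or ``None`` (unscored) when no chop qualifies.
    """
    qualifying = [cs for cs in chop_scores if cs.probability >= c]
    if not qualifying:
        return None
    best = min(qualifying, key=lambda cs: cs.class_def.priority_rank)
    if best.class_def.is_rim:
        return 1
    return best.class_def.score_no


def _winning_class(
    chop_scores: list[ChopScore], scheme: ClassScheme, c: float
) -> tuple[ClassDef | None, float | None]:
    qualifying = [cs for cs in chop_scores if cs.probability >= c]
    if not qualifying:
        return None, None
    best = min(qualifying, key=lambda cs: cs.class_def.priority_rank)
    winner = (
        scheme.by_score(1, is_rim=False) if best.class_def.is_rim else best.class_def
    )
    support = max(
        cs.probability for cs in qualifying if cs.class_def == best.class_def
    )
    return winner, support


def select_top_chops(
    chop_scores: list[ChopScore], c: float, n: int
) -> list[ChopScore]:
    """Evidence chops: qualifying windows first by class priority then
    probability; if nothing qualifies, the overall most confident."""
    qualifying = [cs for cs in chop_scores if cs.probability >= c]
    pool = qualifying or chop_scores
    ranked = sorted(
        pool, key=lambda cs: (cs.class_def.priority_rank, -cs.probability)
    )
    return ranked[:n]


# ---------------------------------------------------------------------
# chop classifiers (model-backed and mocks)
# ---------------------------------------------------------------------

class ModelChopClassifier:
    """Adapter: a trained network scores pixel chops; windows ignored."""

    def __init__(self, model, scheme: ClassScheme, batch_size: int = 64):
        if model.spec.num_classes != len(scheme):
            raise ValueError(
                f"model has {model.spec.num_classes} outputs, "
                f"scheme has {len(scheme)} classes"
            )
        self.model = model
        self.scheme = scheme
        self.batch_size = batch_size

    def predict_windows(
        self, chops: np.ndarray, windows: list[Window]
    ) -> np.ndarray:
        return predict_proba(self.model, chops, self.batch_size)


class OracleChopClassifier:
    """Ground-truth mock: emits the scene's true chop label one-hot.

    Used to test aggregation and rendering independently of training.
    Windows must be given in original-image coordinates.
    """

    def __init__(
        self,
        scene: SceneSpec,
        scheme: ClassScheme,
        confidence: float = 0.99,
        min_overlap_px: int | None = None,
    ):
        self.scene = scene
        self.scheme = scheme
        self.confidence = confidence
        self.min_overlap_px = min_overlap_px

    def predict_windows(
        self, chops: np.ndarray, windows: list[Window]
    ) -> np.ndarray:
        k = len(self.scheme)
        out = np.full((len(windows), k), (1.0 - self.confidence) / (k - 1))
        for i, win in enumerate(windows):
            label = ground_truth_label(
                self.scene, win, self.min_overlap_px, self.scheme
            )
            out[i, self.scheme.index_of(label)] = self.confidence
        return out


class ConfusionChopClassifier:
    """Mock that pushes the oracle's truth through a fixed confusion
    matrix: row = true class, emitted as the probability vector."""

    def __init__(self, oracle: OracleChopClassifier, confusion: np.ndarray):
        confusion = np.asarray(confusion, dtype=float)
        k = len(oracle.scheme)
        if confusion.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if not np.allclose(confusion.sum(axis=1), 1.0):
            raise ValueError("confusion rows must sum to 1")
        self.oracle = oracle
        self.scheme = oracle.scheme
        self.confusion = confusion

    def predict_windows(
        self, chops: np.ndarray, windows: list[Window]
    ) -> np.ndarray:
        truth = self.oracle.predict_windows(chops, windows).argmax(axis=1)
        return self.confusion[truth]


# ---------------------------------------------------------------------
# the evaluation program
# ---------------------------------------------------------------------

def score_well(
    image: np.ndarray,
    uv_image: np.ndarray | None,
    seg_model,
    classifier,
    scheme: ClassScheme,
    s: int = 50,
    c: float = 0.85,
    n: int = 5,
    chop_size: int = 256,
    prob_threshold: float = 0.5,
    well_id: str = "well",
    render: bool = True,
) -> WellScore:
    """Locate the droplet, classify sliding windows, aggregate, render."""
    if s < 1:
        raise ValueError("step s must be >= 1")
    if not 0.0 < c <= 1.0:
        raise ValueError("threshold c must be in (0, 1]")
    region = locate_droplet(seg_model, image, prob_threshold, min_bbox=chop_size)
    if region is None:
        return WellScore(
            well_id=well_id, score_no=None, class_def=None, probability=None,
            unscored_reason="droplet not found",
        )
    droplet = crop(image, region.bbox)
    grid = sliding_grid(*droplet.shape, chop_size, chop_size, s)
    windows = list(grid)
    chops = np.stack([crop(droplet, w) for w in windows])
    # classifiers that consult scene geometry need original coordinates
    originals = [
        Window(w.x0 + region.bbox.x0, w.y0 + region.bbox.y0, w.width, w.height)
        for w in windows
    ]
    probs = classifier.predict_windows(chops, originals)
    if probs.shape != (len(windows), len(scheme)):
        raise ValueError("classifier output does not match the scheme")
    chop_scores = [
        ChopScore(
            window=w,
            class_def=scheme.classes[int(p.argmax())],
            probability=float(p.max()),
        )
        for w, p in zip(windows, probs)
    ]
    winner, support = _winning_class(chop_scores, scheme, c)
    top = select_top_chops(chop_scores, c, n)
    score = WellScore(
        well_id=well_id,
        score_no=None if winner is None else winner.score_no,
        class_def=winner,
        probability=support,
        top_chops=top,
        unscored_reason=None if winner is not None else "no chop above threshold",
    )
    if render:
        score.annotated_image = render_annotations(
            droplet, top, winner=winner
        )
    return score


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def _draw_frame(
    img: np.ndarray, win: Window, color: tuple[int, int, int], thickness: int = 3
) -> None:
    h, w = img.shape[:2]
    x0, y0 = max(win.x0, 0), max(win.y0, 0)
    x1, y1 = min(win.x1, w), min(win.y1, h)
    t = thickness
    col = np.array(color, dtype=np.uint8)
    img[y0 : min(y0 + t, y1), x0:x1] = col
    img[max(y1 - t, y0) : y1, x0:x1] = col
    img[y0:y1, x0 : min(x0 + t, x1)] = col
    img[y0:y1, max(x1 - t, x0) : x1] = col


def render_annotations(
    droplet_image: np.ndarray,
    top_chops: list[ChopScore],
    color_map: dict[str, tuple[int, int, int]] | None = None,
    winner: ClassDef | None = None,
    border: int = 6,
) -> np.ndarray:
    """RGB evidence image: 3-px frames per top chop (highest probability
    painted last, i.e. on top) plus a border tinted in the winning
    group's color.  Pixels outside frames and border are unchanged."""
    rgb = np.repeat(to_uint8(droplet_image)[:, :, None], 3, axis=2)
    for cs in sorted(top_chops, key=lambda cs: cs.probability):
        _draw_frame(rgb, cs.window, class_color(cs.class_def, color_map))
    if winner is not None:
        h, w = rgb.shape[:2]
        _draw_frame(
            rgb, Window(0, 0, w, h), class_color(winner, color_map), border
        )
    return rgb
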