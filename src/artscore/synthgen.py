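"""Synthetic crystallization-well generator.

Produces visible/UV image pairs of a plate well containing a roughly
circular droplet with a dark rim ring, plus planted outcome objects:
straight-edged crystal polygons (UV-fluorescent when protein, not when
salt), granular precipitate at three densities, spherolites,
phase-separation blobs, fibers and scratches, or a dried "null
experiment" drop.  Every well carries a per-pixel droplet mask and
exact per-chop ground-truth labels, so the whole scoring pipeline is
testable end to end without any imaging hardware.

Geometry is analytic: each object has a deterministic support mask
derived from the scene description alone, which defines what a chop
"contains".  Pixel noise is seeded per scene.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .classes import ClassDef, ClassScheme, full_scheme
from .tiling import ChopGrid, Window, crop, smallest_overlap_grid

#: object kinds and the score number their class carries
KIND_SCORES = {
    "protein_crystal": (23, 22, 21),
    "salt_crystal": (23, 22, 21),
    "precipitate": (13, 12, 11),
    "null_experiment": (34,),
    "other_blob": (33,),
    "spherolite": (32,),
    "phase_separation": (31,),
    "fiber": (2,),
    "scratch": (2,),
}

#: chops are only labeled with an object when at least this many of its
#: pixels fall inside a 256-px chop (scaled proportionally for other sizes)
MIN_OVERLAP_PX_AT_256 = 200


def scaled_min_overlap(chop_size: int) -> int:
    return max(1, round(MIN_OVERLAP_PX_AT_256 * (chop_size / 256) ** 2))


@dataclass(frozen=True)
class SceneObject:
    """One planted object; ``vertices`` for polygons, disc otherwise."""

    kind: str
    score_no: int
    center_y: float
    center_x: float
    radius: float = 0.0
    vertices: tuple[tuple[float, float], ...] = ()
    contrast: float = -0.3
    density: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in KIND_SCORES:
            raise ValueError(f"unknown object kind {self.kind!r}")
        if self.score_no not in KIND_SCORES[self.kind]:
            raise ValueError(
                f"{self.kind} cannot carry score {self.score_no}"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Deterministic description of one synthetic well."""

    image_height: int = 2056
    image_width: int = 2452
    droplet_center: tuple[float, float] | None = None  # (y, x); default image center
    droplet_radius: float | None = None  # default 0.4 * min dimension
    rim_width: float | None = None  # default 2% of min dimension
    objects: tuple[SceneObject, ...] = ()
    background_level: float = 0.48
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cy, cx = self.center
        r = self.radius
        h, w = self.image_height, self.image_width
        if cy - r < 0 or cx - r < 0 or cy + r > h or cx + r > w:
            raise ValueError("droplet disc must lie fully inside the image")
        for obj in self.objects:
            d = np.hypot(obj.center_y - cy, obj.center_x - cx)
            if d > r:
                raise ValueError(f"object {obj.kind} lies outside the droplet")

    @property
    def center(self) -> tuple[float, float]:
        if self.droplet_center is not None:
            return self.droplet_center
        return (self.image_height / 2.0, self.image_width / 2.0)

    @property
    def radius(self) -> float:
        if self.droplet_radius is not None:
            return self.droplet_radius
        return 0.4 * min(self.image_height, self.image_width)

    @property
    def rim(self) -> float:
        if self.rim_width is not None:
            return self.rim_width
        return max(2.0, 0.02 * min(self.image_height, self.image_width))


@dataclass
class SyntheticWell:
    """Rendered well: images, mask, ground-truth labels."""

    spec: SceneSpec
    visible: np.ndarray
    uv: np.ndarray
    droplet_mask: np.ndarray
    well_label: ClassDef
    chop_labels: dict[Window, ClassDef] = field(default_factory=dict)


# ---------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------

def _distance_map(h: int, w: int, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return np.hypot(yy - cy, xx - cx)


def _object_support(obj: SceneObject, h: int, w: int) -> np.ndarray:
    """Deterministic boolean mask of the pixels an object occupies."""
    mask = np.zeros((h, w), dtype=bool)
    if obj.vertices:
        ys = [v[0] for v in obj.vertices]
        xs = [v[1] for v in obj.vertices]
        rr, cc = draw_polygon(ys, xs, shape=(h, w))
        mask[rr, cc] = True
    elif obj.kind in ("fiber", "scratch"):
        # thin polyline through the object center
        length = max(4.0, obj.radius * 2)
        ang = (obj.center_y * 7 + obj.center_x * 13) % np.pi  # fixed by geometry
        y0 = int(round(obj.center_y - np.sin(ang) * length / 2))
        x0 = int(round(obj.center_x - np.cos(ang) * length / 2))
        y1 = int(round(obj.center_y + np.sin(ang) * length / 2))
        x1 = int(round(obj.center_x + np.cos(ang) * length / 2))
        y0, y1 = np.clip([y0, y1], 0, h - 1)
        x0, x1 = np.clip([x0, x1], 0, w - 1)
        rr, cc = draw_line(y0, x0, y1, x1)
        mask[rr, cc] = True
        mask = ndimage.binary_dilation(mask, iterations=2)
    elif obj.kind == "other_blob":
        d = _distance_map(h, w, obj.center_y, obj.center_x)
        mask = d <= obj.radius
        d2 = _distance_map(
            h, w, obj.center_y + obj.radius * 0.7, obj.center_x + obj.radius * 0.5
        )
        mask |= d2 <= obj.radius * 0.6
    else:
        d = _distance_map(h, w, obj.center_y, obj.center_x)
        mask = d <= obj.radius
    return mask


@functools.lru_cache(maxsize=16)
def _scene_raster(spec: SceneSpec):
    """Cached geometry: droplet mask, rim annulus, per-object supports."""
    h, w = spec.image_height, spec.image_width
    cy, cx = spec.center
    dist = _distance_map(h, w, cy, cx)
    droplet = dist <= spec.radius
    rim = (dist >= spec.radius - spec.rim) & (dist <= spec.radius + spec.rim / 2)
    supports = tuple(
        (obj, _object_support(obj, h, w)) for obj in spec.objects
    )
    return droplet, rim, dist, supports


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def _render(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = spec.image_height, spec.image_width
    droplet, rim_ring, dist, supports = _scene_raster(spec)
    rng = np.random.default_rng(spec.seed)
    dried = any(o.kind == "null_experiment" for o in spec.objects)

    vis = np.full((h, w), spec.background_level)
    uv = np.full((h, w), 0.05)
    if not dried:
        vis[droplet] += 0.10
        vis[rim_ring] -= 0.28
        uv[droplet] += 0.05
    else:
        # dried/empty drop: faint outline only, mottled interior
        vis[rim_ring] -= 0.06
        mottle = ndimage.gaussian_filter(rng.normal(size=(h, w)), 6)
        mottle /= max(np.abs(mottle).max(), 1e-9)
        vis[droplet] += 0.12 * mottle[droplet]

    for obj, support in supports:
        if obj.kind in ("protein_crystal", "salt_crystal"):
            vis[support] += obj.contrast
            edge = support ^ ndimage.binary_erosion(support)
            vis[edge] = np.clip(vis[edge] - 0.25, 0, 1)
            if obj.kind == "protein_crystal":
                uv[support] += 0.55
        elif obj.kind == "precipitate":
            grains = (rng.random((h, w)) < obj.density) & support
            layer = ndimage.gaussian_filter(grains.astype(float), 1.0)
            layer /= max(layer.max(), 1e-9)
            vis += obj.contrast * layer * support
        elif obj.kind == "spherolite":
            grad = np.clip(1.0 - _distance_map(h, w, obj.center_y, obj.center_x)
                           / max(obj.radius, 1e-9), 0, 1)
            vis += obj.contrast * grad * support
        elif obj.kind == "phase_separation":
            d = _distance_map(h, w, obj.center_y, obj.center_x)
            blob = np.exp(-2.0 * (d / max(obj.radius, 1e-9)) ** 2)
            vis += obj.contrast * blob * support
        elif obj.kind == "other_blob":
            vis[support] += obj.contrast
            vis[support] = ndimage.gaussian_filter(vis, 1.5)[support]
        elif obj.kind in ("fiber", "scratch"):
            vis[support] += obj.contrast

    if spec.noise_sd > 0:
        vis = vis + rng.normal(0.0, spec.noise_sd, size=(h, w))
        uv = uv + rng.normal(0.0, spec.noise_sd / 2, size=(h, w))
    return np.clip(vis, 0, 1), np.clip(uv, 0, 1), droplet


# ---------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------

def _class_for_score(scheme: ClassScheme, score_no: int) -> ClassDef:
    """Scheme class for a planted score number (merged schemes fold groups)."""
    from .classes import group_of

    if scheme.mode == "full13":
        return scheme.by_score(score_no)
    return scheme.by_name(group_of(score_no))


def ground_truth_label(
    spec: SceneSpec,
    window: Window,
    min_overlap_px: int | None = None,
    scheme: ClassScheme | None = None,
) -> ClassDef:
    """What a chop at ``window`` contains.

    The label is the highest-priority planted object with at least
    ``min_overlap_px`` support pixels inside the window; failing that,
    rim if the window overlaps the rim annulus by that much; clear
    otherwise.
    """
    scheme = scheme or full_scheme()
    if min_overlap_px is None:
        min_overlap_px = scaled_min_overlap(min(window.width, window.height))
    if window.x1 > spec.image_width or window.y1 > spec.image_height:
        raise ValueError("window outside the image")
    _, rim_ring, _, supports = _scene_raster(spec)
    sl = np.s_[window.y0 : window.y1, window.x0 : window.x1]

    candidates: list[ClassDef] = []
    for obj, support in supports:
        if support[sl].sum() >= min_overlap_px:
            candidates.append(_class_for_score(scheme, obj.score_no))
    if candidates:
        return min(candidates, key=lambda c: c.priority_rank)
    if rim_ring[sl].sum() >= min_overlap_px:
        return scheme.by_score(1, is_rim=True)
    return scheme.by_score(1, is_rim=False)


def _well_label(spec: SceneSpec, scheme: ClassScheme) -> ClassDef:
    labels = [_class_for_score(scheme, o.score_no) for o in spec.objects]
    if not labels:
        return scheme.by_score(1, is_rim=False)
    return min(labels, key=lambda c: c.priority_rank)


def generate_well(
    spec: SceneSpec,
    scheme: ClassScheme | None = None,
    chop_size: int | None = None,
) -> SyntheticWell:
    """Render one well; deterministic for a fixed spec (incl. seed).

    When ``chop_size`` is given, per-chop ground-truth labels are
    attached for the smallest-overlap grid at that size.
    """
    scheme = scheme or full_scheme()
    vis, uv, droplet = _render(spec)
    well = SyntheticWell(
        spec=spec,
        visible=vis,
        uv=uv,
        droplet_mask=droplet,
        well_label=_well_label(spec, scheme),
    )
    if chop_size is not None:
        grid = smallest_overlap_grid(
            spec.image_height, spec.image_width, chop_size, chop_size
        )
        overlap = scaled_min_overlap(chop_size)
        well.chop_labels = {
            w: ground_truth_label(spec, w, overlap, scheme) for w in grid
        }
    return well


# ---------------------------------------------------------------------
# scene construction for requested classes
# ---------------------------------------------------------------------

def _random_polygon(rng, cy: float, cx: float, size: float,
                    irregular: bool = False) -> tuple[tuple[float, float], ...]:
    n = int(rng.integers(3, 9))
    # jittered evenly spaced angles: never degenerate, straight edges
    base = np.linspace(0, 2 * np.pi, n, endpoint=False)
    angles = base + rng.uniform(-0.35, 0.35, size=n) * (2 * np.pi / n)
    radii = rng.uniform(0.6, 1.0, size=n) * size
    if irregular:  # concave "bad form" shape
        radii[::2] *= 0.4
    return tuple(
        (cy + r * np.sin(a), cx + r * np.cos(a)) for r, a in zip(radii, angles)
    )


def _objects_for_score(score_no: int, spec_stub: SceneSpec, rng,
                       salt: bool = False) -> tuple[SceneObject, ...]:
    """Plant objects realizing one scored class inside the droplet."""
    cy, cx = spec_stub.center
    r = spec_stub.radius
    inner = r * 0.55
    kind = "salt_crystal" if salt else "protein_crystal"

    def spot(frac=0.5):
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0, inner * frac)
        return cy + d * np.sin(ang), cx + d * np.cos(ang)

    if score_no == 23:  # single harvestable crystal
        oy, ox = spot()
        verts = _random_polygon(rng, oy, ox, r * 0.30)
        return (SceneObject(kind, 23, oy, ox, vertices=verts, contrast=-0.30),)
    if score_no == 22:  # bad form: concave/irregular
        oy, ox = spot()
        verts = _random_polygon(rng, oy, ox, r * 0.28, irregular=True)
        return (SceneObject(kind, 22, oy, ox, vertices=verts, contrast=-0.30),)
    if score_no == 21:  # overnucleated: many small polygons
        objs = []
        for _ in range(int(rng.integers(8, 13))):
            oy, ox = spot(0.9)
            verts = _random_polygon(rng, oy, ox, r * 0.07)
            objs.append(SceneObject(kind, 21, oy, ox, vertices=verts, contrast=-0.28))
        return tuple(objs)
    if score_no in (13, 12, 11):
        density = {13: 0.45, 12: 0.22, 11: 0.10}[score_no]
        oy, ox = spot(0.4)
        return (SceneObject("precipitate", score_no, oy, ox,
                            radius=r * 0.55, contrast=-0.35, density=density),)
    if score_no == 34:
        return (SceneObject("null_experiment", 34, cy, cx, radius=r),)
    if score_no == 33:
        oy, ox = spot()
        return (SceneObject("other_blob", 33, oy, ox, radius=r * 0.25,
                            contrast=-0.22),)
    if score_no == 32:
        oy, ox = spot()
        return (SceneObject("spherolite", 32, oy, ox, radius=r * 0.22,
                            contrast=-0.30),)
    if score_no == 31:
        oy, ox = spot()
        return (SceneObject("phase_separation", 31, oy, ox, radius=r * 0.30,
                            contrast=-0.12),)
    if score_no == 2:
        oy, ox = spot()
        kind2 = "fiber" if rng.random() < 0.5 else "scratch"
        return (SceneObject(kind2, 2, oy, ox, radius=r * 0.35, contrast=-0.30),)
    if score_no == 1:
        return ()
    raise ValueError(f"no scene recipe for score {score_no}")


def scene_for_class(
    class_def: ClassDef,
    image_height: int,
    image_width: int,
    seed: int,
    salt: bool = False,
) -> SceneSpec:
    """A random scene whose well label is the requested class.

    For the preprocessing-only rim class the scene is a clear drop (rim
    chops are taken from its droplet edge).  Merged-scheme classes are
    realized by a uniformly drawn member of the group.
    """
    rng = np.random.default_rng(seed)
    stub = SceneSpec(image_height=image_height, image_width=image_width, seed=seed)
    if class_def.is_rim or class_def.score_no == 1:
        score = 1
    elif class_def.name in ("crystal", "precipitate", "other", "clear"):
        members = {
            "crystal": (23, 22, 21),
            "precipitate": (13, 12, 11),
            "other": (34, 33, 32, 31),
            "clear": (1, 2),
        }[class_def.name]
        score = int(rng.choice(members))
    else:
        score = class_def.score_no
    objects = _objects_for_score(score, stub, rng, salt=salt)
    return replace(stub, objects=objects)


# ---------------------------------------------------------------------
# labeled chop sets
# ---------------------------------------------------------------------

@dataclass
class ChopDataset:
    """Balanced, labeled chops with aligned UV mates."""

    chops: np.ndarray  # (N, S, S)
    uv_chops: np.ndarray  # (N, S, S)
    labels: np.ndarray  # (N,) indices into scheme.classes
    scheme: ClassScheme

    def class_of(self, i: int) -> ClassDef:
        return self.scheme.classes[int(self.labels[i])]


def _window_for_class(spec: SceneSpec, class_def: ClassDef, chop: int,
                      scheme: ClassScheme, rng) -> Window:
    """A window whose ground-truth label is the requested class."""
    h, w = spec.image_height, spec.image_width
    cy, cx = spec.center
    r = spec.radius

    def clamp(y, x):
        return Window(
            x0=int(np.clip(x - chop // 2, 0, w - chop)),
            y0=int(np.clip(y - chop // 2, 0, h - chop)),
            width=chop, height=chop,
        )

    if class_def.is_rim:
        ang = rng.uniform(0, 2 * np.pi)
        cand = clamp(cy + r * np.sin(ang), cx + r * np.cos(ang))
    elif class_def.score_no == 1 and not spec.objects:
        cand = clamp(cy, cx)  # droplet center, away from the rim
    else:
        obj = spec.objects[int(rng.integers(len(spec.objects)))]
        cand = clamp(obj.center_y, obj.center_x)
    got = ground_truth_label(spec, cand, scheme=scheme)
    if (got.name, got.is_rim) != (class_def.name, class_def.is_rim):
        raise RuntimeError(
            f"scene recipe failed: wanted {class_def.name}, window contains {got.name}"
        )
    return cand


def generate_chop_dataset(
    n_per_class: int,
    scheme: ClassScheme,
    chop_size: int = 64,
    seed: int = 0,
    image_size: int | None = None,
) -> ChopDataset:
    """A balanced labeled chop set, ``n_per_class`` chops per scheme class.

    Each chop is cut from its own small synthetic well; rim chops
    straddle the droplet-edge arc of a clear drop.  Reproducible by seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if chop_size < 32:
        raise ValueError("chop_size must be >= 32")
    size = image_size or chop_size * 3
    rng = np.random.default_rng(seed)
    chops, uvs, labels = [], [], []
    for idx, cdef in enumerate(scheme.classes):
        for _ in range(n_per_class):
            spec = scene_for_class(cdef, size, size, seed=int(rng.integers(2**31)))
            win = _window_for_class(spec, cdef, chop_size, scheme, rng)
            well = generate_well(spec, scheme=scheme)
            chops.append(crop(well.visible, win).copy())
            uvs.append(crop(well.uv, win).copy())
            labels.append(idx)
    order = rng.permutation(len(labels))
    return ChopDataset(
        chops=np.stack(chops)[order],
        uv_chops=np.stack(uvs)[order],
        labels=np.asarray(labels)[order],
        scheme=scheme,
    )


# ---------------------------------------------------------------------
# PNG / CSV export
# ---------------------------------------------------------------------

def to_uint8(image: np.ndarray) -> np.ndarray:
    return (np.clip(image, 0, 1) * 255).round().astype(np.uint8)


def export_wells(wells: list[SyntheticWell], out_dir: str | Path) -> Path:
    """Write 8-bit PNGs plus a CSV manifest; returns the manifest path."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["well_id,path,uv_path,mask_path,score_no"]
    for i, well in enumerate(wells):
        wid = f"well_{i:04d}"
        for suffix, img in (
            ("", well.visible), ("_uv", well.uv),
            ("_mask", well.droplet_mask.astype(float)),
        ):
            Image.fromarray(to_uint8(img)).save(out / f"{wid}{suffix}.png")
        rows.append(
            f"{wid},{wid}.png,{wid}_uv.png,{wid}_mask.png,{well.well_label.score_no}"
        )
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
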